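"""Simulation configuration: every tunable of the pipeline in one place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .optics import OpticsConfig

__all__ = [
    "GridConfig",
    "AxisConfig",
    "BaselineConfig",
    "NoiseConfig",
    "MaskConfig",
    "SimulationConfig",
]


@dataclass(frozen=True)
class GridConfig:
    """Spatial frame and phantom-field parameters."""

    rows: int = 128
    cols: int = 128
    core_radius_px: float = 56.0
    smoothness_px: float = 8.0
    lipid_smoothness_px: float = 4.0
    contrast: float = 3.0
    lipid_bias: float = -1.0

    def validate(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if not (0 < self.core_radius_px <= min(self.rows, self.cols) / 2):
            raise ValueError("core radius must be positive and fit the frame")


@dataclass(frozen=True)
class AxisConfig:
    max_wn: float = 3856.0
    min_wn: float = 800.0
    step: float = 4.0

    def validate(self) -> None:
        if self.step <= 0 or self.max_wn <= self.min_wn:
            raise ValueError("axis requires max_wn > min_wn and step > 0")


@dataclass(frozen=True)
class BaselineConfig:
    slope_range: tuple[float, float] = (0.15, 0.25)
    intercept_range: tuple[float, float] = (-0.00026, 0.0)
    background_divisor: float = 15.0

    def validate(self) -> None:
        if self.slope_range[0] > self.slope_range[1]:
            raise ValueError("slope range must be ordered")
        if self.intercept_range[0] > self.intercept_range[1]:
            raise ValueError("intercept range must be ordered")
        if self.background_divisor <= 0:
            raise ValueError("background divisor must be positive")


@dataclass(frozen=True)
class NoiseConfig:
    scans: tuple[int, ...] = (2, 4, 8, 16, 32, 64, 128, 256)
    snr_ref: float = 1000.0
    scans_ref: int = 256
    ratio_at_max: float = 1.4
    tol_rel: float = 0.01

    def validate(self) -> None:
        if not self.scans or any(s <= 0 for s in self.scans):
            raise ValueError("scan counts must be positive")
        if self.snr_ref <= 0 or self.scans_ref <= 0:
            raise ValueError("snr_ref and scans_ref must be positive")
        if self.ratio_at_max < 1:
            raise ValueError("ratio_at_max must be >= 1")


@dataclass(frozen=True)
class MaskConfig:
    threshold: float = 0.15
    band_wn: float = 1650.0


@dataclass(frozen=True)
class SimulationConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    grid: GridConfig = field(default_factory=GridConfig)
    axis: AxisConfig = field(default_factory=AxisConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    mask: MaskConfig = field(default_factory=MaskConfig)
    absorbance_scale: float = 10.0
    area_units: str = "points"
    co2_on_background: bool = True
    save_preblur: bool = False
    seed: int = 0
    band_table_path: str | None = None

    def validate(self) -> "SimulationConfig":
        self.grid.validate()
        self.axis.validate()
        self.baseline.validate()
        self.noise.validate()
        if self.absorbance_scale <= 0:
            raise ValueError("absorbance scale must be positive")
        if self.area_units not in ("points", "wavenumber"):
            raise ValueError("area_units must be 'points' or 'wavenumber'")
        return self

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        """Preset matching the reference datasets' 1180 x 1100 px frame.

        The resulting float64 cube is ~8 GB in memory (float32 on disk,
        ~4 GB per cube); use deliberately.
        """
        grid = GridConfig(rows=1180, cols=1100, core_radius_px=450.0,
                          smoothness_px=60.0, lipid_smoothness_px=30.0)
        return cls(grid=grid, **overrides)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def listify(x):
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            return x

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)

        def tup(x):
            return tuple(x) if isinstance(x, (list, tuple)) else x

        grid = GridConfig(**d.pop("grid", {}))
        axis = AxisConfig(**d.pop("axis", {}))
        optics = OpticsConfig(**d.pop("optics", {}))
        b = d.pop("baseline", {})
        baseline = BaselineConfig(
            slope_range=tup(b.get("slope_range", (0.15, 0.25))),
            intercept_range=tup(b.get("intercept_range", (-0.00026, 0.0))),
            background_divisor=b.get("background_divisor", 15.0),
        )
        n = d.pop("noise", {})
        noise = NoiseConfig(
            scans=tup(n.get("scans", (2, 4, 8, 16, 32, 64, 128, 256))),
            snr_ref=n.get("snr_ref", 1000.0),
            scans_ref=n.get("scans_ref", 256),
            ratio_at_max=n.get("ratio_at_max", 1.4),
            tol_rel=n.get("tol_rel", 0.01),
        )
        mask = MaskConfig(**d.pop("mask", {}))
        return cls(grid=grid, axis=axis, optics=optics, baseline=baseline,
                   noise=noise, mask=mask, **d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
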