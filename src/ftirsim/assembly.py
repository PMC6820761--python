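"""Cube assembly: per-pixel randomized profiles, absorbance scaling, baselines.

Each pixel of the hyperspectral cube receives freshly randomized Voigt
bands for every class, weighted by the pixel's class memberships, plus an
independently randomized CO2 band whose amplitude follows the spatially
white CO2 map.  The summed spectrum is multiplied by 10 to reach realistic
tissue absorbance values, and a randomized straight-line baseline models
wavenumber-proportional scattering (divided by 15 on background pixels,
where the absence of sample strongly reduces scattering).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.special import voigt_profile

from .spectral import (
    CLASS_IDS,
    CO2_CENTER,
    BandTable,
    SpectralAxis,
    _CLIP_FRACTION,
    _area_scale,
    voigt_component_widths,
)
from .spatial import ConcentrationMaps

__all__ = [
    "HyperCube",
    "BaselineParams",
    "sample_baseline",
    "baseline_vector",
    "build_clean_cube",
    "BACKGROUND_DIVISOR",
]

#: Factor by which background baselines are attenuated.
BACKGROUND_DIVISOR = 15.0

#: Nominal slope/intercept randomization ranges of the scattering baseline.
SLOPE_RANGE = (0.15, 0.25)
INTERCEPT_RANGE = (-0.00026, 0.0)


@dataclass
class HyperCube:
    """A rows x cols x n_points absorbance cube with its wavenumber axis.

    ``meta`` carries provenance: at minimum a ``stage`` tag (one of
    ``clean_preblur``, ``clean``, ``noisy``, ``denoised``) and the seed /
    configuration needed to regenerate the cube.
    """

    data: np.ndarray
    axis: SpectralAxis
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError("cube data must be 3-D (rows, cols, bands)")
        if d.shape[2] != self.axis.n_points:
            raise ValueError(
                f"third dimension {d.shape[2]} does not match axis length "
                f"{self.axis.n_points}"
            )
        self.data = d

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def stage(self) -> str:
        return self.meta.get("stage", "unknown")

    def with_data(self, data: np.ndarray, stage: str, **extra) -> "HyperCube":
        """New cube sharing this axis, with updated stage and meta."""
        meta = dict(self.meta)
        meta.update(extra)
        meta["stage"] = stage
        return HyperCube(data=data, axis=self.axis, meta=meta)


@dataclass(frozen=True)
class BaselineParams:
    """Straight-line baseline coefficients on the normalized axis."""

    slope: float
    intercept: float
    background_divisor: float = BACKGROUND_DIVISOR


def sample_baseline(rng: np.random.Generator) -> BaselineParams:
    """Draw one randomized baseline: slope ~ U(0.15, 0.25), intercept ~ U(-0.00026, 0)."""
    return BaselineParams(
        slope=float(rng.uniform(*SLOPE_RANGE)),
        intercept=float(rng.uniform(*INTERCEPT_RANGE)),
    )


def _normalized_position(axis: SpectralAxis) -> np.ndarray:
    # 0 at the lowest wavenumber, 1 at the highest: scattering grows with
    # wavenumber, so the baseline tilts up towards the high-wavenumber end.
    return (axis.wavenumbers - axis.wn_min) / (axis.wn_max - axis.wn_min)


def baseline_vector(
    axis: SpectralAxis, params: BaselineParams, is_background: bool = False
) -> np.ndarray:
    """Evaluate the straight-line baseline on the axis.

    The abscissa is the axis position normalized to [0, 1] from the lowest
    to the highest wavenumber; background baselines are divided by 15.
    """
    t = _normalized_position(axis)
    line = params.slope * t + params.intercept
    if is_background:
        line = line / params.background_divisor
    return line


def _batched_voigt_block(
    wn: np.ndarray,
    centers: np.ndarray,
    fwhms: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    """Per-row Voigt bands: block[i] = amp[i] * V(wn; c[i], f[i])."""
    sigma, gamma = voigt_component_widths(fwhms)
    return amplitudes[:, None] * voigt_profile(
        wn[None, :] - centers[:, None], sigma[:, None], gamma[:, None]
    )


def build_clean_cube(
    maps: ConcentrationMaps,
    table: BandTable,
    axis: SpectralAxis,
    rng: np.random.Generator,
    *,
    absorbance_scale: float = 10.0,
    include_baseline: bool = True,
    co2_on_background: bool = True,
    area_units: str = "points",
    slope_range: tuple[float, float] = SLOPE_RANGE,
    intercept_range: tuple[float, float] = INTERCEPT_RANGE,
    background_divisor: float = BACKGROUND_DIVISOR,
    chunk_pixels: int = 4096,
    meta: dict | None = None,
) -> HyperCube:
    """Assemble the pre-blur clean cube from concentration maps.

    Per tissue pixel: the sum over the three classes of
    ``weight * profile(class)`` with band parameters re-randomized for
    every pixel, plus ``co2_weight * co2_band``; the result is multiplied
    by ``absorbance_scale`` and a freshly drawn baseline is added.
    Background pixels carry only the attenuated baseline (and, by default,
    the sample-independent atmospheric CO2 band).

    Deterministic for a fixed ``rng`` state; band parameters are drawn in
    batches over pixels (class-major, then band) rather than pixel by
    pixel, which is distributionally identical and much faster.
    """
    rows, cols = maps.shape
    if rows <= 0 or cols <= 0:
        raise ValueError("maps must be non-empty")
    n_pix = rows * cols
    wn = axis.wavenumbers
    scale = _area_scale(area_units, axis)

    weights = maps.class_maps.reshape(n_pix, len(CLASS_IDS))
    co2_w = maps.co2_map.reshape(n_pix)
    tissue = maps.tissue_footprint.reshape(n_pix)
    tis_idx = np.flatnonzero(tissue)

    data = np.zeros((n_pix, axis.n_points))

    # class bands on tissue pixels, freshly randomized per pixel
    for ci, class_id in enumerate(CLASS_IDS):
        for spec in table.without_co2():
            nominal_area = spec.area(class_id)
            for start in range(0, tis_idx.size, chunk_pixels):
                sel = tis_idx[start : start + chunk_pixels]
                m = sel.size
                centers = rng.normal(
                    spec.center, spec.center_sd_pct / 100.0 * spec.center, m
                )
                if spec.fwhm_sd_pct is None:
                    fwhms = np.full(m, spec.fwhm)
                else:
                    fwhms = np.maximum(
                        rng.normal(
                            spec.fwhm, spec.fwhm_sd_pct / 100.0 * spec.fwhm, m
                        ),
                        _CLIP_FRACTION * spec.fwhm,
                    )
                areas = rng.normal(
                    nominal_area, spec.area_sd_pct / 100.0 * nominal_area, m
                )
                if nominal_area > 0:
                    areas = np.maximum(areas, _CLIP_FRACTION * nominal_area)
                amp = weights[sel, ci] * areas * scale
                data[sel] += _batched_voigt_block(wn, centers, fwhms, amp)

    # atmospheric CO2: spatially white amplitude, fixed width
    co2 = table.co2_band
    co2_idx = (
        np.arange(n_pix) if co2_on_background else tis_idx
    )
    co2_area = co2.area_by_class[CLASS_IDS[0]]  # identical for all classes
    for start in range(0, co2_idx.size, chunk_pixels):
        sel = co2_idx[start : start + chunk_pixels]
        m = sel.size
        centers = rng.normal(
            co2.center, co2.center_sd_pct / 100.0 * co2.center, m
        )
        fwhms = np.full(m, co2.fwhm)
        areas = np.maximum(
            rng.normal(co2_area, co2.area_sd_pct / 100.0 * co2_area, m),
            _CLIP_FRACTION * co2_area,
        )
        amp = co2_w[sel] * areas * scale
        data[sel] += _batched_voigt_block(wn, centers, fwhms, amp)

    data *= absorbance_scale

    if include_baseline:
        t = _normalized_position(axis)
        slopes = rng.uniform(*slope_range, size=n_pix)
        intercepts = rng.uniform(*intercept_range, size=n_pix)
        lines = slopes[:, None] * t[None, :] + intercepts[:, None]
        lines[~tissue] /= background_divisor
        data += lines

    meta = dict(meta or {})
    meta.setdefault("stage", "clean_preblur")
    meta["absorbance_scale"] = absorbance_scale
    meta["area_units"] = area_units
    return HyperCube(data=data.reshape(rows, cols, axis.n_points), axis=axis, meta=meta)
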