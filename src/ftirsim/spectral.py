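"""Wavenumber axes and Voigt-band spectral profile synthesis.

Mid-infrared absorption bands of condensed-phase biological material are
well approximated by Voigt profiles (the convolution of a Gaussian and a
Lorentzian line shape).  This module builds descending wavenumber grids,
evaluates area-normalised Voigt bands on them, and sums randomized bands
into per-class base spectra (DNA/RNA, protein, lipid) according to a band
parameter table.

The half-Gaussian/half-Lorentzian mixing is realised as equal Gaussian and
Lorentzian component FWHMs, sized through the Olivero-Longbothum
approximation so that the *total* Voigt FWHM equals the tabulated band
width.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
from scipy.special import voigt_profile

__all__ = [
    "SpectralAxis",
    "BandSpec",
    "BandTable",
    "Profile",
    "CLASS_IDS",
    "CO2_CENTER",
    "make_axis",
    "wavenumber_to_wavelength",
    "voigt_band",
    "voigt_component_widths",
    "randomize_band",
    "generate_profile",
    "load_band_table",
]

#: Fuzzy-class identifiers, in the column order of the packaged band table.
CLASS_IDS = ("dna_rna", "protein", "lipid")

#: Atmospheric CO2 asymmetric-stretch band position (cm^-1); this band is
#: spatially random and is handled separately during cube assembly.
CO2_CENTER = 2352.0

# Olivero-Longbothum: fwhm_voigt ~= 0.5346 fL + sqrt(0.2166 fL^2 + fG^2).
# With fG == fL == fc this gives fwhm_voigt = _OL_EQUAL_WIDTH_FACTOR * fc.
_OL_EQUAL_WIDTH_FACTOR = 0.5346 + np.sqrt(0.2166 + 1.0)
_GAUSS_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SpectralAxis:
    """A strictly descending, uniformly spaced wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray

    def __post_init__(self) -> None:
        wn = np.asarray(self.wavenumbers, dtype=float)
        if wn.ndim != 1 or wn.size < 2:
            raise ValueError("axis needs at least two wavenumber points")
        d = np.diff(wn)
        if np.any(d >= 0):
            raise ValueError("wavenumbers must be strictly descending")
        if np.ptp(d) > 1e-9:
            raise ValueError("wavenumber spacing must be uniform")
        object.__setattr__(self, "wavenumbers", wn)

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    @property
    def step(self) -> float:
        """Grid spacing in cm^-1 (positive)."""
        return float(self.wavenumbers[0] - self.wavenumbers[1])

    @property
    def wn_max(self) -> float:
        return float(self.wavenumbers[0])

    @property
    def wn_min(self) -> float:
        return float(self.wavenumbers[-1])

    def index_of(self, wn: float) -> int:
        """Index of the grid point nearest to ``wn`` (must lie in range)."""
        if not (self.wn_min <= wn <= self.wn_max):
            raise ValueError(
                f"wavenumber {wn} outside axis range "
                f"[{self.wn_min}, {self.wn_max}]"
            )
        return int(np.argmin(np.abs(self.wavenumbers - wn)))

    def window_indices(self, window: tuple[float, float]) -> np.ndarray:
        """Indices whose wavenumbers fall inside the closed ``window``."""
        lo, hi = sorted(window)
        if hi < self.wn_min or lo > self.wn_max:
            raise ValueError(f"window {window} outside axis range")
        idx = np.flatnonzero(
            (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        )
        return idx


def make_axis(
    max_wn: float = 3856.0, min_wn: float = 800.0, step: float = 4.0
) -> SpectralAxis:
    """Build a descending axis from ``max_wn`` stepping ``-step`` while >= ``min_wn``.

    The defaults reproduce the 765-point grid used for the reference
    datasets (3856 down to 800 cm^-1 at 4 cm^-1 spacing).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_wn <= min_wn:
        raise ValueError("max_wn must exceed min_wn")
    n = int(np.floor((max_wn - min_wn) / step)) + 1
    return SpectralAxis(max_wn - step * np.arange(n))


def wavenumber_to_wavelength(wn: float | np.ndarray) -> float | np.ndarray:
    """Convert wavenumber (cm^-1) to wavelength (um): lambda = 1e4 / nu."""
    wn = np.asarray(wn, dtype=float)
    if np.any(wn <= 0):
        raise ValueError("wavenumber must be positive")
    out = 1.0e4 / wn
    return float(out) if out.ndim == 0 else out


def voigt_component_widths(fwhm: float) -> tuple[float, float]:
    """Gaussian sigma and Lorentzian HWHM of the equal-width Voigt split.

    Both components share a common FWHM ``fc`` chosen so the total Voigt
    FWHM equals ``fwhm`` (Olivero-Longbothum approximation).
    """
    fc = fwhm / _OL_EQUAL_WIDTH_FACTOR
    return fc * _GAUSS_FWHM_TO_SIGMA, fc / 2.0


def voigt_band(
    axis: SpectralAxis,
    center: float,
    fwhm: float,
    area: float,
    *,
    gaussian_fwhm: float | None = None,
    lorentzian_fwhm: float | None = None,
) -> np.ndarray:
    """Evaluate an area-normalised Voigt band on ``axis``.

    The analytic integral of the returned line shape over (-inf, inf) in
    wavenumber equals ``area``.  By default the Gaussian and Lorentzian
    component widths are equal and sized so the total FWHM is ``fwhm``;
    passing ``gaussian_fwhm``/``lorentzian_fwhm`` overrides the split
    (useful for limit checks — a vanishing Lorentzian width recovers a
    pure Gaussian).
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if area < 0:
        raise ValueError("area must be non-negative")
    if gaussian_fwhm is None and lorentzian_fwhm is None:
        sigma, gamma = voigt_component_widths(fwhm)
    else:
        gf = fwhm if gaussian_fwhm is None else gaussian_fwhm
        lf = fwhm if lorentzian_fwhm is None else lorentzian_fwhm
        sigma = gf * _GAUSS_FWHM_TO_SIGMA
        gamma = lf / 2.0
    return area * voigt_profile(axis.wavenumbers - center, sigma, gamma)


@dataclass(frozen=True)
class BandSpec:
    """One Voigt band: nominal position/width plus randomization SDs.

    ``fwhm_sd_pct is None`` marks a band whose width is never randomized
    (the CO2 band).  ``area_sd_pct`` is the table-wide 5% area jitter.
    """

    center: float
    center_sd_pct: float
    fwhm: float
    fwhm_sd_pct: float | None
    area_by_class: dict[str, float]
    area_sd_pct: float = 5.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("band fwhm must be positive")
        if any(a < 0 for a in self.area_by_class.values()):
            raise ValueError("band areas must be non-negative")

    def area(self, class_id: str) -> float:
        try:
            return self.area_by_class[class_id]
        except KeyError:
            raise ValueError(
                f"unknown class {class_id!r}; expected one of {CLASS_IDS}"
            ) from None


# Band centers of the packaged 16-band table, used for validation.
_EXPECTED_CENTERS = (
    3300, 2962, 2920, 2850, 2352, 1754, 1650, 1550,
    1462, 1400, 1342, 1280, 1242, 1172, 1080, 1030,
)


@dataclass(frozen=True)
class BandTable:
    """Ordered collection of the 16 band specifications."""

    bands: tuple[BandSpec, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bands", tuple(self.bands))
        fixed = [b for b in self.bands if b.fwhm_sd_pct is None]
        if len(self.bands) == 16:
            centers = tuple(int(b.center) for b in self.bands)
            if centers != _EXPECTED_CENTERS:
                raise ValueError("16-band table centers do not match the "
                                 "canonical tissue band set")
            if len(fixed) != 1 or fixed[0].center != CO2_CENTER:
                raise ValueError("exactly the CO2 band must have fixed width")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def co2_band(self) -> BandSpec:
        for b in self.bands:
            if b.center == CO2_CENTER:
                return b
        raise ValueError("table has no CO2 band")

    def without_co2(self) -> "BandTable":
        return BandTable(tuple(b for b in self.bands if b.center != CO2_CENTER))

    def with_zero_randomization(self) -> "BandTable":
        """Copy with all randomization SDs set to zero (testing aid)."""
        return BandTable(tuple(
            replace(
                b,
                center_sd_pct=0.0,
                fwhm_sd_pct=None if b.fwhm_sd_pct is None else 0.0,
                area_sd_pct=0.0,
            )
            for b in self.bands
        ))


def load_band_table(path: str | None = None) -> BandTable:
    """Load a band table CSV (the packaged 16-band table by default)."""
    if path is None:
        ref = resources.files("ftirsim.data").joinpath("band_table.csv")
        with ref.open("r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    else:
        with open(path, "r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
    bands = []
    for r in rows:
        fwhm_sd = r["fwhm_sd_pct"].strip()
        bands.append(
            BandSpec(
                center=float(r["center_cm1"]),
                center_sd_pct=float(r["center_sd_pct"]),
                fwhm=float(r["fwhm_cm1"]),
                fwhm_sd_pct=None if fwhm_sd in ("", "fixed") else float(fwhm_sd),
                area_by_class={
                    "dna_rna": float(r["area_dna_rna"]),
                    "protein": float(r["area_protein"]),
                    "lipid": float(r["area_lipid"]),
                },
            )
        )
    return BandTable(tuple(bands))


@dataclass(frozen=True)
class Profile:
    """A synthesized base spectrum for one biochemical class."""

    class_id: str
    intensities: np.ndarray


# Widths and areas are clipped below at this fraction of nominal so a
# Gaussian draw can never produce a non-positive width or negative area.
_CLIP_FRACTION = 1e-6


def randomize_band(
    spec: BandSpec, class_id: str, rng: np.random.Generator
) -> tuple[float, float, float]:
    """Draw one realized (center, fwhm, area) for a band.

    Position and width are jittered by Gaussian noise with SD equal to the
    tabulated percentage of the nominal value; the area uses the global 5%
    SD.  A band with ``fwhm_sd_pct is None`` keeps its width exactly.
    """
    nominal_area = spec.area(class_id)
    center = rng.normal(spec.center, spec.center_sd_pct / 100.0 * spec.center)
    if spec.fwhm_sd_pct is None:
        fwhm = spec.fwhm
    else:
        fwhm = rng.normal(spec.fwhm, spec.fwhm_sd_pct / 100.0 * spec.fwhm)
        fwhm = max(fwhm, _CLIP_FRACTION * spec.fwhm)
    area = rng.normal(nominal_area, spec.area_sd_pct / 100.0 * nominal_area)
    if nominal_area > 0:
        area = max(area, _CLIP_FRACTION * nominal_area)
    else:
        area = 0.0
    return center, fwhm, area


def generate_profile(
    class_id: str,
    table: BandTable,
    axis: SpectralAxis,
    rng: np.random.Generator,
    *,
    area_units: str = "points",
    include_co2: bool = True,
) -> Profile:
    """Sum the table's randomized Voigt bands into one class spectrum.

    ``area_units`` fixes the meaning of the tabulated areas: ``"points"``
    (default) treats them as integrals over the spectral-point index, i.e.
    each band is additionally scaled by the axis step — this reproduces the
    absorbance scale of pipelines that convert positions and widths from
    wavenumbers into points; ``"wavenumber"`` treats them as integrals over
    cm^-1 directly.
    """
    if class_id not in CLASS_IDS:
        raise ValueError(
            f"unknown class {class_id!r}; expected one of {CLASS_IDS}"
        )
    scale = _area_scale(area_units, axis)
    out = np.zeros(axis.n_points)
    for spec in table:
        if not include_co2 and spec.center == CO2_CENTER:
            continue
        center, fwhm, area = randomize_band(spec, class_id, rng)
        if area > 0:
            out += voigt_band(axis, center, fwhm, scale * area)
    return Profile(class_id=class_id, intensities=out)


def _area_scale(area_units: str, axis: SpectralAxis) -> float:
    if area_units == "points":
        return axis.step
    if area_units == "wavenumber":
        return 1.0
    raise ValueError("area_units must be 'points' or 'wavenumber'")
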