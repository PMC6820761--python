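"""Noise estimation, absorbance-dependent injection, and SNR calibration.

FT-IR noise has a multiplicative component: pixels with higher absorbance
are noisier.  The model here is a Gaussian field whose per-point SD grows
linearly with the clean absorbance, from ``sigma_g`` at the cube's global
minimum to ``1.4 * sigma_g`` at its global maximum (the "40% rule").

Noise is *measured* the same way it is measured on real spectra: a
straight line is fitted to a band-free window (2150-2075 cm^-1 by
default), the absolute residuals are taken, and their sample standard
deviation is the noise value; SNR = 1/noise with unit signal.  An
iterative calibration adjusts ``sigma_g`` until the measured mean SNR over
tissue pixels matches a target, and a scan series applies the sqrt(N)
SNR law of interferogram co-addition to produce the 2-256-scan ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .assembly import HyperCube
from .spatial import TissueMask
from .spectral import SpectralAxis

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_SCANS",
    "NoiseSpec",
    "NoiseEstimate",
    "NoiseCalibration",
    "estimate_noise",
    "mean_snr",
    "noise_sd_field",
    "add_noise",
    "calibrate_sigma",
    "scan_series",
    "noise_excess_at_extremes",
]

logger = logging.getLogger(__name__)

#: Band-free wavenumber window used for noise estimation (cm^-1).
DEFAULT_WINDOW = (2150.0, 2075.0)

#: Scan counts of the standard noise ladder.
DEFAULT_SCANS = (2, 4, 8, 16, 32, 64, 128, 256)


@dataclass(frozen=True)
class NoiseSpec:
    """Parameters of the absorbance-dependent Gaussian noise generator."""

    sigma_g: float
    ratio_at_max: float = 1.4
    target_snr: float | None = None
    scans: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sigma_g < 0:
            raise ValueError("sigma_g must be non-negative")
        if self.ratio_at_max < 1:
            raise ValueError("ratio_at_max must be >= 1")


@dataclass(frozen=True)
class NoiseEstimate:
    """Result of band-free-window noise estimation for one spectrum."""

    noise: float
    snr: float
    window: tuple[float, float] = DEFAULT_WINDOW


@dataclass(frozen=True)
class NoiseCalibration:
    """Outcome of the iterative SNR matching."""

    sigma_g: float
    achieved_snr: float
    target_snr: float
    n_iter: int
    converged: bool


def _window_residual_matrix(axis: SpectralAxis, window) -> tuple[np.ndarray, np.ndarray]:
    """Window indices and the residual-maker matrix of the line fit."""
    idx = axis.window_indices(window)
    if idx.size < 3:
        raise ValueError("window must contain at least 3 axis points")
    t = axis.wavenumbers[idx]
    A = np.column_stack([t, np.ones_like(t)])
    # R = I - A (A^T A)^-1 A^T ; symmetric, applied from the right to row-spectra
    R = np.eye(idx.size) - A @ np.linalg.solve(A.T @ A, A.T)
    return idx, R


def _noise_of_rows(y: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Noise metric per row: sample SD of |line-fit residuals| (N-1 denom)."""
    x = np.abs(y @ R.T)
    return x.std(axis=-1, ddof=1)


def estimate_noise(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> NoiseEstimate:
    """Estimate the noise of a single spectrum from its band-free window.

    A straight line is least-squares fitted to the window, subtracted, and
    the absolute residuals' sample standard deviation is reported as the
    noise; SNR is its reciprocal (infinite for an exactly linear window).
    The estimate is invariant under adding any straight line to the
    spectrum, since the fit absorbs it.
    """
    idx, R = _window_residual_matrix(axis, window)
    y = np.asarray(spectrum, dtype=float)
    if y.shape[-1] != axis.n_points:
        raise ValueError("spectrum length does not match axis")
    noise = float(_noise_of_rows(y[idx][None, :], R)[0])
    snr = float("inf") if noise == 0 else 1.0 / noise
    return NoiseEstimate(noise=noise, snr=snr, window=window)


def mean_snr(
    cube: HyperCube,
    mask: TissueMask,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """Mean per-pixel SNR over tissue (mask == 0) pixels.

    Returns ``inf`` if any tissue pixel has an exactly linear window (e.g.
    a noise-free synthetic spectrum), mirroring the per-spectrum estimate.
    """
    if mask.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube")
    tissue = mask.tissue
    if not tissue.any():
        raise ValueError("mask contains no tissue pixels")
    idx, R = _window_residual_matrix(cube.axis, window)
    y = cube.data[tissue][:, idx]
    noise = _noise_of_rows(y, R)
    with np.errstate(divide="ignore"):
        snr = np.where(noise > 0, 1.0 / np.where(noise > 0, noise, 1.0), np.inf)
    return float(snr.mean())


def noise_sd_field(
    cube: HyperCube, sigma_g: float, ratio_at_max: float = 1.4
) -> np.ndarray:
    """Per-point noise SD, linear in absorbance between the cube extremes.

    sd(A) = sigma_g * (1 + (ratio_at_max - 1) * (A - MIN) / (MAX - MIN)),
    so sd(MIN) = sigma_g and sd(MAX) = ratio_at_max * sigma_g.  A constant
    cube (MAX == MIN) degenerates to a uniform field of ``sigma_g``.
    """
    a = cube.data
    lo, hi = float(a.min()), float(a.max())
    if hi == lo:
        return np.full_like(a, sigma_g)
    return sigma_g * (1.0 + (ratio_at_max - 1.0) * (a - lo) / (hi - lo))


def add_noise(
    cube: HyperCube,
    spec: NoiseSpec | float,
    rng: np.random.Generator | None = None,
) -> HyperCube:
    """Add absorbance-dependent Gaussian noise; returns a ``noisy`` cube."""
    if not isinstance(spec, NoiseSpec):
        spec = NoiseSpec(sigma_g=float(spec))
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if spec.sigma_g == 0:
        return cube.with_data(cube.data.copy(), stage="noisy", sigma_g=0.0)
    sd = noise_sd_field(cube, spec.sigma_g, spec.ratio_at_max)
    noisy = cube.data + rng.standard_normal(cube.shape) * sd
    return cube.with_data(
        noisy, stage="noisy", sigma_g=spec.sigma_g,
        ratio_at_max=spec.ratio_at_max, scans=spec.scans,
        target_snr=spec.target_snr,
    )


def noise_excess_at_extremes(clean: HyperCube, noisy: HyperCube) -> float:
    """Percent excess of the noise SD at the cube's maximum-absorbance
    points over its minimum-absorbance points, estimated empirically.

    Under the multiplicative model the SD of the injected noise is linear
    in the clean absorbance, so ``E|noisy - clean|`` is too
    (``E|e| = sqrt(2/pi) * sd`` for centred Gaussian ``e``).  An ordinary
    least-squares fit of ``|noisy - clean|`` against the clean absorbance
    over all points, evaluated at the cube's global minimum and maximum,
    therefore estimates the endpoint SD ratio without the bias a
    quantile-set comparison suffers when the high-absorbance tail is broad.
    Returns ``100 * (sd(MAX)/sd(MIN) - 1)`` — nominally 40 for the default
    generator.
    """
    if clean.shape != noisy.shape:
        raise ValueError("clean and noisy cubes must share shape")
    a = clean.data.ravel()
    r = np.abs(noisy.data.ravel() - a)
    design = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(design, r, rcond=None)
    lo, hi = float(a.min()), float(a.max())
    sd_lo = coef[0] + coef[1] * lo
    sd_hi = coef[0] + coef[1] * hi
    if sd_lo <= 0:
        raise ValueError("degenerate fit: non-positive SD at the minimum")
    return float(100.0 * (sd_hi / sd_lo - 1.0))


def calibrate_sigma(
    cube: HyperCube,
    mask: TissueMask,
    target_snr: float,
    tol_rel: float = 0.01,
    max_iter: int = 50,
    rng: np.random.Generator | None = None,
    *,
    ratio_at_max: float = 1.4,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bracket: tuple[float, float] = (1e-6, 10.0),
) -> NoiseCalibration:
    """Find ``sigma_g`` whose injected noise yields the target mean SNR.

    Bisection on log(sigma_g) against the measured mean SNR over tissue
    pixels, using one fixed Gaussian probe field (drawn once from ``rng``)
    so the search is deterministic.  Only the estimation window of the
    cube is perturbed during the search, which is exactly the region the
    SNR metric sees.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    rng = np.random.default_rng() if rng is None else rng
    tissue = mask.tissue
    if not tissue.any():
        raise ValueError("mask contains no tissue pixels")
    idx, R = _window_residual_matrix(cube.axis, window)
    clean_w = cube.data[tissue][:, idx]
    base_w = (
        noise_sd_field(cube, 1.0, ratio_at_max)[tissue][:, idx]
    )  # SD field per unit sigma_g
    probe = rng.standard_normal(clean_w.shape)

    def measured_snr(sigma: float) -> float:
        noise = _noise_of_rows(clean_w + sigma * base_w * probe, R)
        with np.errstate(divide="ignore"):
            return float(np.where(noise > 0, 1.0 / np.maximum(noise, 1e-300), np.inf).mean())

    lo, hi = bracket  # snr(lo) high, snr(hi) low: snr decreases with sigma
    best = (lo, measured_snr(lo))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        mid = float(np.sqrt(lo * hi))  # bisection in log space
        snr = measured_snr(mid)
        if abs(snr - target_snr) < abs(best[1] - target_snr):
            best = (mid, snr)
        if abs(snr - target_snr) <= tol_rel * target_snr:
            best = (mid, snr)
            converged = True
            break
        if snr > target_snr:
            lo = mid
        else:
            hi = mid
    if not converged:
        logger.warning(
            "SNR calibration did not converge in %d iterations "
            "(target %.4g, best achieved %.4g)", max_iter, target_snr, best[1]
        )
    return NoiseCalibration(
        sigma_g=best[0], achieved_snr=best[1], target_snr=target_snr,
        n_iter=n_iter, converged=converged,
    )


def scan_series(
    cube: HyperCube,
    mask: TissueMask,
    scans=DEFAULT_SCANS,
    snr_ref: float = 1000.0,
    scans_ref: int = 256,
    rng: np.random.Generator | None = None,
    *,
    ratio_at_max: float = 1.4,
    tol_rel: float = 0.01,
) -> list[HyperCube]:
    """Produce the noisy-cube ladder for a list of scan counts.

    Co-adding N scans improves SNR by sqrt(N), so each cube is calibrated
    to ``snr_ref * sqrt(N / scans_ref)`` and injected from the same clean
    parent.  ``snr_ref`` anchors the ladder to a measured SNR at
    ``scans_ref`` scans; the default (1000 at 256 scans) is a documented
    placeholder of realistic magnitude, not a measured value.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("scan list must not be empty")
    if snr_ref <= 0 or scans_ref <= 0:
        raise ValueError("snr_ref and scans_ref must be positive")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for n_scans in scans:
        target = snr_ref * np.sqrt(n_scans / scans_ref)
        cal = calibrate_sigma(
            cube, mask, target, tol_rel=tol_rel, rng=rng,
            ratio_at_max=ratio_at_max,
        )
        noisy = add_noise(
            cube,
            NoiseSpec(
                sigma_g=cal.sigma_g, ratio_at_max=ratio_at_max,
                target_snr=float(target), scans=n_scans,
            ),
            rng,
        )
        noisy.meta["achieved_snr_probe"] = cal.achieved_snr
        logger.info(
            "scan level %d: target SNR %.1f, sigma_g %.3e (probe SNR %.1f)",
            n_scans, target, cal.sigma_g, cal.achieved_snr,
        )
        out.append(noisy)
    return out
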