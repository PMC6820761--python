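"""Benchmark metrics for denoising against a known clean reference.

With a noise-free reference cube available, a denoiser can be judged not
only by how much noise it removes but by how much it *distorts* the
signal.  The Signal Distortion (SD) metric compares, point by point, the
original noise magnitude |noisy - clean| with the change the denoiser
applied |denoised - noisy|, and accumulates the excess wherever the
denoiser moved the data further than the noise had displaced it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import HyperCube
from .noise import mean_snr, DEFAULT_WINDOW
from .spatial import TissueMask

__all__ = ["DistortionReport", "signal_distortion", "snr_improvement"]


@dataclass(frozen=True)
class DistortionReport:
    """Summary of the Signal Distortion metric over a cube triplet.

    ``sd_total`` is the raw sum of the per-point distortions over flagged
    points (points where the denoiser's change exceeded the original
    noise); ``sd_mean`` divides by the total number of points so cubes of
    different sizes can be compared.
    """

    sd_total: float
    n_flagged: int
    n_total: int
    per_pixel_sd: np.ndarray | None = None

    @property
    def sd_mean(self) -> float:
        return self.sd_total / self.n_total

    def to_dict(self) -> dict:
        return {
            "sd_total": self.sd_total,
            "sd_mean": self.sd_mean,
            "n_flagged": self.n_flagged,
            "n_total": self.n_total,
        }


def signal_distortion(
    clean: HyperCube,
    noisy: HyperCube,
    denoised: HyperCube,
    *,
    per_pixel: bool = False,
) -> DistortionReport:
    """Signal Distortion of a denoised cube against clean and noisy parents.

    Per point: ``noise_abs = |noisy - clean|``, ``noise_absred =
    |denoised - noisy|``, and ``SD = |noise_absred - noise_abs|`` summed
    over the points where ``noise_absred > noise_abs`` (strictly).  The
    strict inequality means both a perfectly inert denoiser (returns the
    noisy data) and a perfect one (returns the clean data) score zero.
    """
    if not (clean.shape == noisy.shape == denoised.shape):
        raise ValueError("clean, noisy and denoised cubes must share shape")
    noise_abs = np.abs(noisy.data - clean.data)
    noise_absred = np.abs(denoised.data - noisy.data)
    flagged = noise_absred > noise_abs
    sd = np.where(flagged, np.abs(noise_absred - noise_abs), 0.0)
    report = DistortionReport(
        sd_total=float(sd.sum()),
        n_flagged=int(flagged.sum()),
        n_total=int(sd.size),
        per_pixel_sd=sd.sum(axis=2) if per_pixel else None,
    )
    return report


def snr_improvement(
    noisy: HyperCube,
    denoised: HyperCube,
    mask: TissueMask,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> tuple[float, float]:
    """Mean tissue SNR before and after denoising: (snr_before, snr_after)."""
    if noisy.shape != denoised.shape:
        raise ValueError("noisy and denoised cubes must share shape")
    return (
        mean_snr(noisy, mask, window=window),
        mean_snr(denoised, mask, window=window),
    )
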