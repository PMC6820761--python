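"""Synthetic spatial structure: class concentration maps, CO2 map, tissue mask.

The reference datasets derive three per-pixel class-membership maps
(DNA/RNA, protein, lipid) from fuzzy c-means clustering of a measured
tissue core.  Here a parametric phantom stands in for those maps: a
circular tissue core containing smooth, softmax-normalised Gaussian random
fields whose memberships sum to one per pixel.  That makes the ground
truth exact and removes any dependence on measured data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .spectral import CLASS_IDS

__all__ = [
    "ConcentrationMaps",
    "TissueMask",
    "synth_core_maps",
    "synth_co2_map",
    "build_mask",
]


@dataclass(frozen=True)
class ConcentrationMaps:
    """Per-pixel class weights plus the spatially random CO2 amplitude.

    ``class_maps`` is (rows, cols, 3) in the order of
    :data:`ftirsim.spectral.CLASS_IDS`; on tissue pixels the three weights
    sum to 1, outside the core all are 0.  ``co2_map`` is an i.i.d.
    Uniform(0, 1) field covering the whole frame.
    """

    class_maps: np.ndarray
    co2_map: np.ndarray

    def __post_init__(self) -> None:
        cm = np.asarray(self.class_maps, dtype=float)
        co2 = np.asarray(self.co2_map, dtype=float)
        if cm.ndim != 3 or cm.shape[2] != len(CLASS_IDS):
            raise ValueError("class_maps must have shape (rows, cols, 3)")
        if co2.shape != cm.shape[:2]:
            raise ValueError("co2_map shape must match class_maps")
        if cm.min() < 0 or cm.max() > 1 + 1e-9:
            raise ValueError("class weights must lie in [0, 1]")
        object.__setattr__(self, "class_maps", cm)
        object.__setattr__(self, "co2_map", co2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.class_maps.shape[:2]

    def class_map(self, class_id: str) -> np.ndarray:
        return self.class_maps[..., CLASS_IDS.index(class_id)]

    @property
    def tissue_footprint(self) -> np.ndarray:
        """Boolean map of pixels carrying any class weight (the core)."""
        return self.class_maps.sum(axis=2) > 0.5


@dataclass(frozen=True)
class TissueMask:
    """Binary sample/background map: 0 = tissue, 1 = background.

    The inverted coding (0 marks tissue) follows the convention of the
    reference datasets.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "mask", m.astype(np.uint8))

    @property
    def tissue(self) -> np.ndarray:
        """Boolean array, True on tissue pixels."""
        return self.mask == 0


def _smooth_standard_field(
    rng: np.random.Generator, rows: int, cols: int, smoothness_px: float
) -> np.ndarray:
    """Gaussian-smoothed white noise, re-standardised to mean 0 / SD 1."""
    f = gaussian_filter(
        rng.standard_normal((rows, cols)), smoothness_px, mode="wrap"
    )
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else f


def synth_core_maps(
    rows: int = 128,
    cols: int = 128,
    core_radius_px: float = 56.0,
    smoothness_px: float = 8.0,
    rng: np.random.Generator | None = None,
    *,
    contrast: float = 3.0,
    lipid_smoothness_px: float = 4.0,
    lipid_bias: float = -1.0,
) -> ConcentrationMaps:
    """Generate phantom fuzzy-membership maps over a circular tissue core.

    Three smooth random fields are passed through a softmax so that
    memberships sum to one per pixel.  ``contrast`` scales the fields before
    the softmax: larger values saturate memberships towards 0/1, mimicking
    the mostly-committed memberships fuzzy clustering yields on real tissue.
    The lipid field uses a shorter correlation length
    (``lipid_smoothness_px``) and a negative offset (``lipid_bias``) so that
    lipids form sparser, visibly finer-grained islands than the two
    spatially similar DNA/RNA and protein classes.

    Parameters
    ----------
    rows, cols : int
        Frame size in pixels; the desk-scale default is 128 x 128.
    core_radius_px : float
        Radius of the circular core, centred in the frame.
    smoothness_px : float
        Gaussian correlation scale (in pixels) of the DNA/RNA and protein
        fields.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("rows and cols must be positive")
    if not (0 < core_radius_px <= min(rows, cols) / 2):
        raise ValueError("core radius must be positive and fit in the frame")
    rng = np.random.default_rng() if rng is None else rng

    fields = np.stack(
        [
            contrast * _smooth_standard_field(rng, rows, cols, smoothness_px),
            contrast * _smooth_standard_field(rng, rows, cols, smoothness_px),
            contrast * _smooth_standard_field(rng, rows, cols, lipid_smoothness_px)
            + lipid_bias,
        ],
        axis=-1,
    )
    # softmax across the class axis
    fields -= fields.max(axis=-1, keepdims=True)
    w = np.exp(fields)
    w /= w.sum(axis=-1, keepdims=True)

    yy, xx = np.mgrid[0:rows, 0:cols]
    r2 = (yy - (rows - 1) / 2.0) ** 2 + (xx - (cols - 1) / 2.0) ** 2
    core = r2 <= core_radius_px**2
    w[~core] = 0.0

    co2 = synth_co2_map(rows, cols, rng)
    return ConcentrationMaps(class_maps=w, co2_map=co2)


def synth_co2_map(
    rows: int, cols: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Spatially uncorrelated Uniform(0, 1) CO2 amplitude field.

    Atmospheric CO2 absorption is unrelated to the sample, so its
    concentration map is white: i.i.d. per pixel, no masking, no smoothing.
    """
    if rows <= 0 or cols <= 0:
        raise ValueError("rows and cols must be positive")
    rng = np.random.default_rng() if rng is None else rng
    return rng.uniform(0.0, 1.0, size=(rows, cols))


def build_mask(cube, threshold: float = 0.15, band_wn: float = 1650.0) -> TissueMask:
    """Threshold the amide I image into a tissue/background mask.

    Pixels whose absorbance at the grid point nearest ``band_wn`` is
    strictly above ``threshold`` are marked 0 (tissue); all others 1
    (background).
    """
    k = cube.axis.index_of(band_wn)
    plane = cube.data[:, :, k]
    return TissueMask(np.where(plane > threshold, 0, 1).astype(np.uint8))
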