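"""Microscopy quantification: FRET inclusions and neurite length per nucleus.

Two bespoke measurements on two-channel 8-bit fluorescence images:

1. **Inclusion detection** on the FRET channel: threshold, morphological
   closing with a 10 px square element, connected-component labelling, then
   keep regions that are compact (eccentricity < 0.8) and of plausible size
   (area 4–1000 px, inclusive).  Region intensity is the sum of *raw* pixel
   values under the region mask.
2. **Neurite length per nucleus**: both channels pass through a tanh
   contrast filter; nuclei are found in the blue (DAPI) channel by erosion,
   thresholding and size filtering; the dilated nuclei are subtracted from
   the binarized red (TUJ1) channel before skeletonizing and measuring the
   remaining neurites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "TanhFilterParams",
    "InclusionParams",
    "RegionMetrics",
    "NeuriteResult",
    "tanh_contrast",
    "binarize",
    "detect_inclusions",
    "detect_nuclei",
    "measure_neurites",
    "skeleton_length",
    "percent_inclusion_positive_cells",
]


@dataclass(frozen=True)
class TanhFilterParams:
    """Slope/offset of the tanh contrast filter, y = m(x - b) + 0.5.

    Defaults m=2, b=0.4 are the red-channel (TUJ1) settings.
    """

    m: float = 2.0
    b: float = 0.4

    def __post_init__(self) -> None:
        if self.m <= 0:
            raise ValueError("m must be > 0")
        if not 0 <= self.b <= 1:
            raise ValueError("b must be in [0, 1]")


@dataclass(frozen=True)
class InclusionParams:
    """Inclusion-detection parameters.

    ``close_width``: side of the square structuring element for morphological
    closing.  ``ecc_max``: regions with eccentricity >= this are discarded as
    elongated (fiber-like) artifacts.  Area bounds are inclusive.
    ``level``: fixed binarization level; ``None`` selects Otsu's method.
    """

    close_width: int = 10
    ecc_max: float = 0.8
    area_min: int = 4
    area_max: int = 1000
    level: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.area_min <= self.area_max):
            raise ValueError("require 0 < area_min <= area_max")
        if not (0 < self.ecc_max <= 1):
            raise ValueError("require 0 < ecc_max <= 1")
        if self.close_width < 1:
            raise ValueError("close_width must be >= 1")


@dataclass(frozen=True)
class RegionMetrics:
    """Shape and intensity metrics of one kept region."""

    label: int
    area: int
    eccentricity: float
    summed_intensity: float
    centroid: tuple[float, float]


@dataclass(frozen=True)
class NeuriteResult:
    total_length: float
    nuclei_count: int
    length_per_nucleus: float


def _as_float(img) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D channel")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def tanh_contrast(img, params: TanhFilterParams = TanhFilterParams()) -> np.ndarray:
    """Nonlinear contrast enhancement used before segmentation.

    Pipeline: min–max rescale to [0,1]; linear map y = m(x - b) + 0.5;
    tanh; min–max renormalize to [0, 255].  Strictly monotone before the
    final renormalization, so pixel ordering is preserved.  A constant image
    has a degenerate min–max rescale and maps to all zeros with a warning.
    """
    img = _as_float(img)
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image: tanh contrast degenerate, returning zeros",
                      stacklevel=2)
        return np.zeros_like(img)
    x = (img - lo) / (hi - lo)
    z = np.tanh(params.m * (x - params.b) + 0.5)
    zlo, zhi = z.min(), z.max()
    return (z - zlo) / (zhi - zlo) * 255.0


def binarize(img, level: float | None = None) -> np.ndarray:
    """Threshold an image: fixed level if given, else Otsu."""
    img = _as_float(img)
    if level is None:
        if img.min() == img.max():
            return np.zeros(img.shape, dtype=bool)
        level = threshold_otsu(img)
    return img > level


def detect_inclusions(raw, params: InclusionParams = InclusionParams()
                      ) -> list[RegionMetrics]:
    """Detect inclusion regions in a raw FRET channel.

    Steps: binarize -> morphological closing (square element of side
    ``close_width``) -> 8-connected labelling -> keep regions with
    eccentricity < ``ecc_max`` and ``area_min`` <= area <= ``area_max``.
    ``summed_intensity`` is computed on the raw (pre-threshold) image.
    """
    raw = _as_float(raw)
    bw = binarize(raw, params.level)
    closed = morphology.closing(bw, morphology.footprint_rectangle(
        (params.close_width, params.close_width)))
    labels = measure.label(closed, connectivity=2)
    kept: list[RegionMetrics] = []
    for region in measure.regionprops(labels, intensity_image=raw):
        if region.eccentricity >= params.ecc_max:
            continue
        if not (params.area_min <= region.area <= params.area_max):
            continue
        kept.append(RegionMetrics(
            label=region.label,
            area=int(region.area),
            eccentricity=float(region.eccentricity),
            summed_intensity=float(region.image_intensity[region.image].sum()),
            centroid=tuple(map(float, region.centroid)),
        ))
    return kept


def detect_nuclei(blue, erode_width: int = 3, min_area: int = 50,
                  level: float | None = None) -> tuple[np.ndarray, int]:
    """Segment and count nuclei in the (contrast-filtered) blue channel.

    Erosion with a square element suppresses thin debris, then connected
    components above the threshold and of at least ``min_area`` pixels are
    counted as nuclei.  Touching nuclei merge into one component (no
    watershed splitting).

    Returns (mask, count) where the mask covers the kept components.
    """
    blue = _as_float(blue)
    eroded = ndimage.grey_erosion(blue, size=(erode_width, erode_width))
    bw = binarize(eroded, level)
    labels = measure.label(bw, connectivity=2)
    mask = np.zeros(blue.shape, dtype=bool)
    count = 0
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            mask[labels == region.label] = True
            count += 1
    return mask, count


def skeleton_length(skeleton: np.ndarray, mode: str = "pixel") -> float:
    """Length of a skeletonized binary mask.

    ``mode='pixel'`` counts skeleton pixels (one unit each), the plain
    summation convention.  ``mode='geodesic'`` counts inter-pixel steps,
    weighting diagonal steps by sqrt(2), which is direction-independent:
    a 45-degree line measures its Euclidean length instead of ~71% of it.
    """
    sk = np.asarray(skeleton, dtype=bool)
    if mode == "pixel":
        return float(sk.sum())
    if mode != "geodesic":
        raise ValueError("mode must be 'pixel' or 'geodesic'")
    orth = np.count_nonzero(sk[:, :-1] & sk[:, 1:]) + \
        np.count_nonzero(sk[:-1, :] & sk[1:, :])
    diag = np.count_nonzero(sk[:-1, :-1] & sk[1:, 1:]) + \
        np.count_nonzero(sk[:-1, 1:] & sk[1:, :-1])
    if orth == 0 and diag == 0:
        return float(sk.sum())  # isolated pixels only
    return float(orth + np.sqrt(2.0) * diag)


def measure_neurites(red, nuclei_mask, nuclei_count: int,
                     dilate_width: int = 5, level: float | None = None,
                     length_mode: str = "pixel") -> NeuriteResult:
    """Neurite length per nucleus from the (contrast-filtered) red channel.

    The nuclei mask is dilated and subtracted from the binarized neurite
    channel, the remainder is skeletonized, and the skeleton length is
    divided by the nucleus count.  With zero nuclei the ratio is undefined:
    the image is skipped (NaN) with a warning.
    """
    red = _as_float(red)
    bw = binarize(red, level)
    dilated = morphology.dilation(
        np.asarray(nuclei_mask, dtype=bool),
        morphology.footprint_rectangle((dilate_width, dilate_width)))
    neurites = bw & ~dilated
    skel = morphology.skeletonize(neurites)
    total = skeleton_length(skel, mode=length_mode)
    if nuclei_count < 1:
        warnings.warn("zero nuclei: neurite length per nucleus undefined",
                      stacklevel=2)
        return NeuriteResult(total, 0, float("nan"))
    return NeuriteResult(total, nuclei_count, total / nuclei_count)


def percent_inclusion_positive_cells(inclusions: list[RegionMetrics],
                                     nuclei_centroids,
                                     radius: float = 20.0) -> float:
    """Percent of cells (nuclei) with at least one inclusion nearby.

    A nucleus is inclusion-positive when some kept inclusion centroid lies
    within ``radius`` px of the nucleus centroid — a proximity stand-in for
    cell delineation, since no cell-body segmentation is performed.
    """
    centroids = np.asarray(list(nuclei_centroids), dtype=float)
    if centroids.size == 0:
        raise ValueError("percent positive undefined with zero nuclei")
    if not inclusions:
        return 0.0
    inc = np.asarray([m.centroid for m in inclusions], dtype=float)
    d2 = ((centroids[:, None, :] - inc[None, :, :]) ** 2).sum(axis=2)
    positive = (d2 <= radius**2).any(axis=1)
    return 100.0 * positive.sum() / centroids.shape[0]
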