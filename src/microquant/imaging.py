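"""Image-processing stages: preprocessing, droplet segmentation, nuclear
counting, and live/dead classification.

A *microtissue* here is a cell-laden collagen microsphere (~100-300 μm)
imaged as a 2D projection in multi-channel fluorescence (nuclei / marker /
live stains).  Each field of view nominally contains one droplet; the
segmentation stage nevertheless returns every connected component that
survives the area and border filters.

Conventions: pixel coordinates are 0-based ``(row, col)`` with the origin at
the top-left; areas and diameters are reported in physical units via the
image's pixel size.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_isodata, threshold_otsu
from skimage.measure import label as _label, regionprops
from skimage.morphology import disk as _disk_footprint

logger = logging.getLogger(__name__)

__all__ = [
    "MicrotissueImage",
    "DropletMask",
    "PreprocessParams",
    "SegmentationParams",
    "NucleusDetectionParams",
    "ViabilityParams",
    "ViabilityResult",
    "preprocess",
    "segment_droplets",
    "count_nuclei",
    "classify_viability",
]


@dataclass
class MicrotissueImage:
    """One multi-channel field of view plus acquisition/experiment metadata.

    Parameters
    ----------
    channels
        Mapping of stain name (e.g. ``"nuclei"``, ``"marker"``, ``"live"``)
        to a 2D pixel array.  All channels must share one shape.
    pixel_size_um
        Lateral pixel size in μm/px (> 0).
    bit_depth
        Camera bit depth, 8 or 16; pixel values must lie in
        ``[0, 2**bit_depth - 1]``.
    metadata
        Experimental annotations (condition, dose_uM, timepoint_days,
        patient_id, replicate, droplet_id, ...).
    """

    channels: dict
    pixel_size_um: float
    bit_depth: int = 16
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("MicrotissueImage requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError(f"channels must be 2D, got shape {shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        top = 2**self.bit_depth - 1
        for name, arr in self.channels.items():
            arr = np.asarray(arr)
            if arr.size and (arr.min() < 0 or arr.max() > top):
                raise ValueError(
                    f"channel {name!r} has values outside [0, {top}]"
                )

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise KeyError(
                f"channel {name!r} not present; have {sorted(self.channels)}"
            ) from None


@dataclass
class DropletMask:
    """A labeled binary region for one microtissue with shape descriptors.

    ``area_um2 = area_px * pixel_size**2`` and
    ``equiv_diameter_um = 2*sqrt(area_um2/pi)`` by construction;
    ``circularity = 4*pi*area/perimeter**2`` may exceed 1 by a small
    discretization tolerance on digitized disks.
    """

    label: int
    mask: np.ndarray
    area_px: int
    area_um2: float
    equiv_diameter_um: float
    circularity: float
    centroid: tuple
    touches_border: bool


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessParams:
    """Settings for illumination correction and contrast normalization.

    ``background_sigma`` is the Gaussian scale (px) of the large-scale
    background estimate; it should greatly exceed the droplet diameter.
    ``None`` defaults to half the larger image dimension.  After background
    subtraction (negatives clamped to zero) the image is linearly rescaled
    between the ``low_percentile`` and ``high_percentile`` robust bounds.
    """

    background_sigma: float | None = None
    low_percentile: float = 1.0
    high_percentile: float = 99.5
    rescale: bool = True


def preprocess(
    channel: np.ndarray,
    params: PreprocessParams | None = None,
    provenance: dict | None = None,
) -> np.ndarray:
    """Subtract large-scale background and stretch contrast for mask finding.

    Returns a float array; when contrast stretching succeeds the output is
    in [0, 1].  The corrected image is intended for *segmentation only* —
    intensity quantification always reads the raw channel.

    A constant input has no contrast to stretch: the (all-zero) background-
    subtracted image is returned with a warning.  The correction is exactly
    invariant to a global additive offset.
    """
    params = params or PreprocessParams()
    img = np.asarray(channel, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("preprocess expects a non-empty 2D array")
    sigma = params.background_sigma
    if sigma is None:
        sigma = max(img.shape) / 2.0
    background = ndi.gaussian_filter(img, sigma=sigma, mode="reflect")
    corrected = np.clip(img - background, 0.0, None)
    low = float(np.percentile(corrected, params.low_percentile))
    high = float(np.percentile(corrected, params.high_percentile))
    stretched = params.rescale and high - low > 1e-12
    if params.rescale and not stretched:
        warnings.warn(
            "image has no contrast after background subtraction; "
            "skipping contrast stretch",
            stacklevel=2,
        )
    if stretched:
        corrected = np.clip((corrected - low) / (high - low), 0.0, 1.0)
    if provenance is not None:
        provenance.update(
            background_sigma=float(sigma),
            stretch_low=low,
            stretch_high=high,
            stretched=bool(stretched),
        )
    return corrected


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationParams:
    """Settings for droplet mask extraction.

    Bright per-cell puncta would otherwise dominate a global threshold of
    the marker channel, so the channel is first grey-opened with a disk
    footprint of ``texture_radius`` px (larger than one punctum, much
    smaller than a droplet) — this levels the texture to the diffuse tissue
    signal while leaving the convex droplet outline untouched.  The opened
    channel is Gaussian-smoothed, thresholded (automatic bimodal isodata by
    default, fixed value optional), closed, hole-filled and labeled.  Components
    below ``min_area_px`` or touching the image border are discarded
    (border exclusion configurable: a border-clipped droplet has a censored
    projected area).
    """

    texture_radius: int = 7
    smooth_sigma: float = 2.0
    threshold: float | None = None
    closing_radius: int = 2
    min_area_px: float = 1000.0
    exclude_border: bool = True


def segment_droplets(
    image: np.ndarray,
    pixel_size_um: float,
    params: SegmentationParams | None = None,
) -> list[DropletMask]:
    """Threshold a (preprocessed) channel into per-droplet masks.

    Returns one :class:`DropletMask` per surviving connected component,
    ordered by label.  Zero surviving components yields an empty list and a
    logged warning, not an exception.
    """
    params = params or SegmentationParams()
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("segment_droplets expects a non-empty 2D array")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    smoothed = ndi.gaussian_filter(img, sigma=params.smooth_sigma)
    if params.threshold is not None:
        thr = params.threshold
    else:
        # the threshold is estimated on the grey-opened (texture-suppressed)
        # channel, where the histogram is cleanly background-vs-tissue, but
        # applied to the unopened smoothed channel so the opening's erosion
        # bite cannot pull the boundary inward
        estimator = smoothed
        if params.texture_radius > 0:
            opened = ndi.grey_opening(
                img, footprint=_disk_footprint(params.texture_radius)
            )
            estimator = ndi.gaussian_filter(opened, sigma=params.smooth_sigma)
        if np.ptp(estimator) < 1e-12:
            logger.warning("constant image: no droplets found")
            return []
        # isodata (Ridler-Calvard): threshold converges to the midpoint of
        # the two class means, which tracks the tissue edge's half-height
        # and stays stable when background dominates the histogram
        thr = threshold_isodata(estimator)
    binary = smoothed > thr
    if params.closing_radius > 0:
        # pad by edge replication so closing cannot erode at image borders
        r = params.closing_radius
        padded = np.pad(binary, r, mode="edge")
        padded = ndi.binary_closing(padded, structure=_disk_footprint(r))
        binary = padded[r:-r, r:-r]
    binary = ndi.binary_fill_holes(binary)
    labeled = _label(binary, connectivity=2)

    out: list[DropletMask] = []
    nrows, ncols = img.shape
    for prop in regionprops(labeled):
        if prop.area < params.min_area_px:
            logger.debug(
                "dropping component %d (area %d px < %g)",
                prop.label, prop.area, params.min_area_px,
            )
            continue
        minr, minc, maxr, maxc = prop.bbox
        touches = minr == 0 or minc == 0 or maxr == nrows or maxc == ncols
        if touches and params.exclude_border:
            logger.debug("excluding border-touching component %d", prop.label)
            continue
        area_um2 = prop.area * pixel_size_um**2
        perim = prop.perimeter_crofton
        circ = 4.0 * np.pi * prop.area / perim**2 if perim > 0 else 0.0
        out.append(
            DropletMask(
                label=int(prop.label),
                mask=labeled == prop.label,
                area_px=int(prop.area),
                area_um2=float(area_um2),
                equiv_diameter_um=float(2.0 * np.sqrt(area_um2 / np.pi)),
                circularity=float(circ),
                centroid=tuple(float(c) for c in prop.centroid),
                touches_border=bool(touches),
            )
        )
    if not out:
        logger.warning("no droplet passed the area/border filters")
    return out


# ---------------------------------------------------------------------------
# nuclear counting
# ---------------------------------------------------------------------------

@dataclass
class NucleusDetectionParams:
    """Blob-detection settings for nuclear counting.

    ``sigma`` is the expected nucleus blob width (px).  Peaks closer than
    ``min_separation`` (default ``2*sigma``) merge into one detection by
    definition of the separation rule.  A peak must exceed the in-mask
    background by ``rel_prominence`` of the in-mask dynamic range.
    """

    sigma: float = 2.0
    smooth_sigma: float = 1.0
    min_separation: float | None = None
    rel_prominence: float = 0.25


def count_nuclei(
    nuclei_channel: np.ndarray,
    mask: DropletMask | np.ndarray,
    params: NucleusDetectionParams | None = None,
) -> tuple[int, np.ndarray]:
    """Count nuclei inside a droplet mask via smoothed local maxima.

    Returns ``(count, centroids)`` with centroids as an ``(n, 2)`` array of
    ``(row, col)`` peak coordinates inside the mask.  An identically-zero
    channel yields zero; an empty mask is an error.
    """
    params = params or NucleusDetectionParams()
    binary = mask.mask if isinstance(mask, DropletMask) else np.asarray(mask, bool)
    if not binary.any():
        raise ValueError("cannot count nuclei in an empty mask")
    img = np.asarray(nuclei_channel, dtype=float)
    if img.shape != binary.shape:
        raise ValueError("channel and mask shapes differ")
    smoothed = ndi.gaussian_filter(img, sigma=params.smooth_sigma)
    inside = smoothed[binary]
    lo = float(np.percentile(inside, 10))
    hi = float(np.percentile(inside, 99))
    if hi - lo <= 1e-12:
        return 0, np.empty((0, 2))
    thr = lo + params.rel_prominence * (hi - lo)
    sep = params.min_separation
    if sep is None:
        sep = 2.0 * params.sigma
    peaks = peak_local_max(
        smoothed,
        min_distance=max(1, int(round(sep))),
        threshold_abs=thr,
        labels=binary.astype(np.int32),
        exclude_border=False,
    )
    return len(peaks), peaks


# ---------------------------------------------------------------------------
# viability
# ---------------------------------------------------------------------------

@dataclass
class ViabilityParams:
    """Settings for live/dead classification of detected cells.

    Each cell's mean live-stain intensity is taken over a disk of
    ``radius`` px around its centroid.  Cells are split live/dead by an
    automatic bimodal (Otsu) threshold over the per-cell means; when the
    means are not credibly bimodal — split separation below
    ``separation_factor`` times the within-class spread, or below
    ``min_contrast_fraction`` of the intensity scale — the classifier falls
    back to the fixed absolute threshold (``threshold`` if given, else
    ``fixed_fraction`` of the channel's dtype range).
    """

    radius: int = 3
    threshold: float | None = None
    fixed_fraction: float = 0.05
    separation_factor: float = 2.0
    min_contrast_fraction: float = 0.05


@dataclass
class ViabilityResult:
    live_count: int
    total_count: int
    live_fraction: float
    threshold: float
    used_fallback: bool


def _intensity_scale(channel: np.ndarray) -> float:
    if np.issubdtype(channel.dtype, np.integer):
        return float(np.iinfo(channel.dtype).max)
    top = float(channel.max()) if channel.size else 0.0
    return top if top > 0 else 1.0


def classify_viability(
    live_channel: np.ndarray,
    centroids: np.ndarray,
    params: ViabilityParams | None = None,
) -> ViabilityResult:
    """Classify each detected cell as live or dead from the live stain.

    The live fraction is ``live/total`` and always lies in [0, 1]; live plus
    dead equals the total by construction.  Zero cells is an error (there is
    nothing to classify).
    """
    params = params or ViabilityParams()
    centroids = np.asarray(centroids)
    if centroids.size == 0:
        raise ValueError("classify_viability requires at least one cell")
    img = np.asarray(live_channel)
    nrows, ncols = img.shape
    r = params.radius
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    foot = (yy**2 + xx**2) <= r**2

    means = np.empty(len(centroids))
    for i, (cy, cx) in enumerate(centroids):
        cy, cx = int(round(cy)), int(round(cx))
        y0, y1 = max(0, cy - r), min(nrows, cy + r + 1)
        x0, x1 = max(0, cx - r), min(ncols, cx + r + 1)
        sub = img[y0:y1, x0:x1]
        f = foot[y0 - (cy - r) : y1 - (cy - r), x0 - (cx - r) : x1 - (cx - r)]
        means[i] = float(sub[f].mean())

    scale = _intensity_scale(img)
    fixed = params.threshold if params.threshold is not None else params.fixed_fraction * scale

    thr, fallback = fixed, True
    if len(np.unique(means)) > 1:
        t = float(threshold_otsu(means, nbins=256))
        lo, hi = means[means <= t], means[means > t]
        if lo.size and hi.size:
            separation = hi.mean() - lo.mean()
            spread = lo.std() + hi.std()
            if (
                separation > params.separation_factor * spread
                and separation > params.min_contrast_fraction * scale
            ):
                thr, fallback = t, False
    if fallback:
        warnings.warn(
            "per-cell live intensities not bimodal; using fixed threshold "
            f"{fixed:.3g}",
            stacklevel=2,
        )
    live = int(np.sum(means > thr))
    total = len(means)
    return ViabilityResult(
        live_count=live,
        total_count=total,
        live_fraction=live / total,
        threshold=float(thr),
        used_fallback=bool(fallback),
    )
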