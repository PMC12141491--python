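"""Chloroplast shape analysis from fluorescence micrographs.

Chloroplasts are detected via their chlorophyll *a* fluorescence, segmented,
and measured for area, perimeter and circularity

    circularity = 4 * pi * Area / Perimeter**2,

which is 1 for a perfect circle and tends to 0 for elongated shapes.  Because
circularity distributions over hundreds of organelles are heavy-tailed, the
unit of analysis is the per-replicate *median* circularity, and treatment
groups are compared on those medians through the gated statistics module.

Segmentation is a classical pipeline — percentile intensity normalization,
Gaussian smoothing, Otsu (or fixed) thresholding, and watershed on the
distance transform to split touching convex blobs.  Externally produced label
masks (e.g. from a neural segmenter) can be imported and re-measured through
the same :func:`measure_objects` path.

The perimeter is the length of a sub-pixel contour — marching squares at
level 0.5 of the binary mask, regularised by a periodic smoothing spline —
rather than a pixel-edge count: pixel-edge perimeters overestimate by up to
~27 % and would cap the circularity of a true circle near 0.79 instead of 1.
The spline's permitted deviation is a fixed sub-pixel budget per contour
point, so the pixel-staircase wiggle is removed at every object scale and
the measured circularity of a rasterized circle converges to 1 as its
radius grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate
from scipy import ndimage as ndi
from skimage import feature, filters, measure, segmentation

from . import stats as _stats

__all__ = [
    "Micrograph",
    "SegmentationParams",
    "ObjectShape",
    "ReplicateShapeSummary",
    "segment_objects",
    "measure_objects",
    "circularity",
    "summarize_replicate",
    "compare_shape_groups",
]


@dataclass
class Micrograph:
    """A single-plane grayscale fluorescence image with isotropic pixel size."""

    image: np.ndarray
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 2 or self.image.size == 0:
            raise ValueError("image must be a non-empty 2-D array")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")


@dataclass
class SegmentationParams:
    """Knobs for the classical segmentation pipeline.

    ``threshold`` is "otsu" or an absolute intensity on the normalized image;
    ``min_distance_px`` is the minimum spacing between watershed seeds and
    should be of the order of the smallest expected object radius.
    """

    threshold: str | float = "otsu"
    smooth_sigma_px: float = 1.0
    min_area_px: int = 20
    split_touching: bool = True
    min_distance_px: int = 10
    percentile_norm: tuple[float, float] = (1.0, 99.9)


@dataclass
class ObjectShape:
    """Measurements of one segmented object."""

    label: int
    area_px2: float
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    circularity: float
    centroid_px: tuple[float, float]
    touches_border: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class ReplicateShapeSummary:
    """Median/IQR shape metrics of one biological replicate."""

    replicate_id: str
    n_objects: int
    median_circularity: float
    iqr_circularity: float
    median_area_um2: float
    iqr_area_um2: float
    flags: list[str] = field(default_factory=list)


def circularity(area: float, perimeter: float) -> float:
    """``4 * pi * area / perimeter**2``; 1 for a circle, -> 0 when elongated."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be positive")
    return 4.0 * np.pi * area / perimeter**2


def segment_objects(mg: Micrograph, params: SegmentationParams | None = None) -> np.ndarray:
    """Segment fluorescent objects into a label mask (background 0, labels 1..N).

    Pipeline: percentile intensity normalization -> Gaussian smoothing ->
    threshold -> optional watershed split of touching blobs (seeds are local
    maxima of a smoothed distance transform) -> small-object removal ->
    contiguous relabelling.  An image that thresholds to nothing yields a
    zero-object mask (callers may warn); it is not an error.
    """
    if params is None:
        params = SegmentationParams()
    img = mg.image.astype(float)
    lo, hi = np.percentile(img, params.percentile_norm)
    if hi > lo:
        img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    else:
        img = np.zeros_like(img)
    if params.smooth_sigma_px > 0:
        img = filters.gaussian(img, sigma=params.smooth_sigma_px)
    if params.threshold == "otsu":
        if np.ptp(img) == 0:
            return np.zeros(mg.image.shape, dtype=np.int32)
        thr = filters.threshold_otsu(img)
    else:
        thr = float(params.threshold)
    binary = img > thr
    if not binary.any():
        return np.zeros(mg.image.shape, dtype=np.int32)

    if params.split_touching:
        distance = ndi.distance_transform_edt(binary)
        # smoothing the distance map suppresses spurious ridge maxima that
        # would oversplit elongated objects
        distance_s = filters.gaussian(distance, sigma=2.0)
        coords = feature.peak_local_max(
            distance_s,
            min_distance=params.min_distance_px,
            labels=binary,
            exclude_border=False,
        )
        markers = np.zeros(binary.shape, dtype=np.int32)
        for i, (r, c) in enumerate(coords, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels = measure.label(binary)
        else:
            labels = segmentation.watershed(-distance, markers, mask=binary)
    else:
        labels = measure.label(binary)

    # drop small objects, then relabel contiguously
    counts = np.bincount(labels.ravel())
    small = np.nonzero(counts < params.min_area_px)[0]
    if len(small):
        labels[np.isin(labels, small)] = 0
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def _subpixel_perimeter(obj_mask: np.ndarray, smooth_per_point: float = 0.05) -> float:
    """Perimeter of a binary object from a spline-regularised 0.5 iso-contour.

    The mask is padded and traced with marching squares; the longest closed
    contour is fitted with a periodic cubic smoothing spline whose total
    squared-deviation budget is ``smooth_per_point`` pixels^2 per contour
    vertex, then the spline is densely resampled and its polyline length
    measured.  The fixed per-vertex budget removes the half-pixel staircase
    wiggle at every object scale while leaving genuine curvature (and all
    but the last ~2 px around sharp corners) intact.
    """
    padded = np.pad(obj_mask.astype(float), 4)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return 0.0
    c = max(contours, key=lambda cc: np.sum(np.hypot(*np.diff(cc, axis=0).T)))
    raw_len = float(np.sum(np.hypot(*np.diff(c, axis=0).T)))
    c = c[:-1]  # drop duplicated closing vertex
    if len(c) < 10:
        return raw_len  # too few vertices for a stable periodic cubic fit
    tck, _ = interpolate.splprep(
        [c[:, 0], c[:, 1]], per=1, s=smooth_per_point * len(c), quiet=2
    )
    u = np.linspace(0.0, 1.0, max(200, 4 * len(c)))
    y, x = interpolate.splev(u, tck)
    return float(np.sum(np.hypot(np.diff(y), np.diff(x))))


def measure_objects(
    mask: np.ndarray, pixel_size_um: float, contour_smooth_per_point: float = 0.05
) -> list[ObjectShape]:
    """Measure area, perimeter and circularity of every labelled object.

    Area is the pixel count times the pixel area; perimeter is the sub-pixel
    contour length.  Circularity is reported raw: values slightly above 1 can
    occur from the contour estimator (tolerance ~0.02) and are flagged rather
    than clipped.
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(mask)
    out: list[ObjectShape] = []
    for prop in measure.regionprops(mask):
        minr, minc, maxr, maxc = prop.bbox
        obj = mask[minr:maxr, minc:maxc] == prop.label
        perim_px = _subpixel_perimeter(obj, smooth_per_point=contour_smooth_per_point)
        area_px2 = float(prop.area)
        if perim_px <= 0:
            continue
        circ = circularity(area_px2, perim_px)
        touches = minr == 0 or minc == 0 or maxr == mask.shape[0] or maxc == mask.shape[1]
        flags = []
        if circ > 1.0 + 0.02:
            flags.append("circularity_above_one")
        out.append(
            ObjectShape(
                label=int(prop.label),
                area_px2=area_px2,
                area_um2=area_px2 * pixel_size_um**2,
                perimeter_px=perim_px,
                perimeter_um=perim_px * pixel_size_um,
                circularity=circ,
                centroid_px=tuple(map(float, prop.centroid)),
                touches_border=bool(touches),
                flags=flags,
            )
        )
    return out


def summarize_replicate(
    objects: list[ObjectShape],
    replicate_id: str,
    exclude_border: bool = True,
    min_n_warn: int = 50,
) -> ReplicateShapeSummary:
    """Median and IQR of circularity and area over one replicate's objects.

    Border-touching objects are excluded by default (their shape is
    truncated by the field of view).  Fewer than ``min_n_warn`` objects
    yields a low-n flag, since the replicate median is then unstable.
    """
    kept = [o for o in objects if not (exclude_border and o.touches_border)]
    if not kept:
        raise ValueError("no objects to summarize")
    circ = np.array([o.circularity for o in kept])
    area = np.array([o.area_um2 for o in kept])
    q1c, med_c, q3c = np.percentile(circ, [25, 50, 75])
    q1a, med_a, q3a = np.percentile(area, [25, 50, 75])
    flags = [] if len(kept) >= min_n_warn else ["low_object_count"]
    return ReplicateShapeSummary(
        replicate_id=replicate_id,
        n_objects=len(kept),
        median_circularity=float(med_c),
        iqr_circularity=float(q3c - q1c),
        median_area_um2=float(med_a),
        iqr_area_um2=float(q3a - q1a),
        flags=flags,
    )


def compare_shape_groups(
    groups: dict[str, list[ReplicateShapeSummary]],
    metric: str = "median_circularity",
    alpha: float = 0.05,
) -> _stats.GroupComparison:
    """Gated comparison of per-replicate shape medians between treatments.

    The replicate (not the individual organelle) is the unit of analysis:
    each datum is one replicate's median of the chosen metric.
    """
    data = {
        name: np.array([getattr(s, metric) for s in summaries])
        for name, summaries in groups.items()
    }
    return _stats.gated_compare(_stats.GroupData(data, alpha=alpha))
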