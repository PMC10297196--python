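"""ROI extraction from lesion probability maps.

A probability map assigns each pixel of a chest radiograph a lesion
probability in [0, 1] (the up-sampled class-activation output of a
detection network, or a synthetic surrogate).  Thresholding the map at a
0.2 cutoff yields candidate regions of interest (ROIs); for each ROI five
descriptors are computed: physical area, weighted opacity-area product
(WOAP, the integral of probability over the region), and the mean, median
and maximum pixel probability.  Up to three ROIs per image are retained,
largest first, matching how nodules were enumerated on the radiographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .errors import ConfigurationError, DomainError

DEFAULT_CUTOFF = 0.2
DEFAULT_POSITIVITY_THRESHOLD = 0.15
DEFAULT_MAX_ROIS = 3


@dataclass(frozen=True)
class ProbabilityMap:
    """A 2D per-pixel lesion-probability grid with physical pixel spacing.

    Parameters
    ----------
    values
        2D float array with entries in [0, 1].
    pixel_spacing_mm
        Isotropic pixel edge length in millimetres.
    image_id
        Identifier used to join with cohort tables.
    manufacturer_tag
        Optional acquisition-device label; carried through, never interpreted.
    """

    values: np.ndarray
    pixel_spacing_mm: float
    image_id: str = ""
    manufacturer_tag: Optional[str] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ConfigurationError("probability map must be a non-empty 2D grid")
        if not np.isfinite(v).all() or v.min() < 0.0 or v.max() > 1.0:
            raise ConfigurationError("probability values must lie in [0, 1]")
        if not (self.pixel_spacing_mm > 0):
            raise ConfigurationError("pixel spacing must be positive")
        object.__setattr__(self, "values", v)

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing_mm ** 2


@dataclass(frozen=True)
class RoiParams:
    """Descriptors of one thresholded region.

    ``area_mm2`` is pixel count times squared spacing; ``woap`` is the
    probability-weighted area (reduces to ``area_mm2`` when p == 1 inside
    the region).  Centroid is in (row, col) pixel coordinates, 0-based.
    """

    roi_id: int
    pixel_count: int
    area_mm2: float
    woap: float
    prob_mean: float
    prob_median: float
    prob_max: float
    centroid: tuple[float, float] = field(default=(0.0, 0.0))


def image_positive(pmap: ProbabilityMap, threshold: float = DEFAULT_POSITIVITY_THRESHOLD) -> bool:
    """Image-level nodule positivity gate.

    The detection network's image-level score is approximated by the
    maximum pixel probability; an image is positive when that score is
    greater than or equal to ``threshold`` (default 0.15).
    """
    return bool(pmap.values.max() >= threshold)


def threshold_mask(pmap: ProbabilityMap, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Binary mask of pixels strictly above ``cutoff``.

    Strict inequality: a map uniformly equal to the cutoff yields an
    empty mask.
    """
    if not (0.0 < cutoff < 1.0):
        raise ConfigurationError(f"cutoff must be in (0, 1), got {cutoff}")
    return pmap.values > cutoff


def compute_woap(probabilities: Sequence[float] | np.ndarray, pixel_spacing_mm: float) -> float:
    """Weighted opacity-area product: sum of p over ROI pixels times pixel area (mm²)."""
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise DomainError("WOAP of an empty ROI is undefined")
    return float(p.sum() * pixel_spacing_mm ** 2)


def _roi_params_from_pixels(roi_id, rows, cols, pmap):
    p = pmap.values[rows, cols]
    spacing2 = pmap.pixel_area_mm2
    return RoiParams(
        roi_id=roi_id,
        pixel_count=int(p.size),
        area_mm2=float(p.size * spacing2),
        woap=compute_woap(p, pmap.pixel_spacing_mm),
        prob_mean=float(p.mean()),
        prob_median=float(np.median(p)),
        prob_max=float(p.max()),
        centroid=(float(rows.mean()), float(cols.mean())),
    )


def extract_rois(
    pmap: ProbabilityMap,
    cutoff: float = DEFAULT_CUTOFF,
    max_rois: int = DEFAULT_MAX_ROIS,
) -> list[RoiParams]:
    """Extract up to ``max_rois`` ROIs, largest area first.

    Connected components of the strict-threshold mask use 8-connectivity
    (diagonal neighbours merge).  Ties on area break by descending
    maximum probability, then by row-major centroid order, so output is
    deterministic.  Returned ``roi_id`` is the rank (0 = largest).
    """
    mask = threshold_mask(pmap, cutoff)
    if not mask.any():
        return []
    labels = measure.label(mask, connectivity=2)
    rois = []
    for lab in range(1, labels.max() + 1):
        rows, cols = np.nonzero(labels == lab)
        rois.append(_roi_params_from_pixels(0, rows, cols, pmap))
    rois.sort(key=lambda r: (-r.area_mm2, -r.prob_max, r.centroid))
    rois = rois[: max(0, int(max_rois))]
    return [
        RoiParams(roi_id=i, **{f: getattr(r, f) for f in (
            "pixel_count", "area_mm2", "woap", "prob_mean", "prob_median",
            "prob_max", "centroid")})
        for i, r in enumerate(rois)
    ]


def match_rois_to_nodules(
    rois: Sequence[RoiParams],
    nodule_centers: Sequence[tuple[float, float]],
    nodule_ids: Sequence,
    max_distance_px: Sequence[float] | None = None,
) -> dict[int, object]:
    """Greedy nearest-centroid assignment of ROIs to ground-truth nodules.

    Pairs are taken in ascending centroid-distance order; each nodule is
    used at most once.  A pair is accepted only if its distance is within
    the nodule's gate (``max_distance_px``, default infinite).  Unmatched
    ROIs map to ``None``.
    """
    mapping: dict[int, object] = {r.roi_id: None for r in rois}
    if not rois or len(nodule_centers) == 0:
        return mapping
    gates = max_distance_px if max_distance_px is not None else [np.inf] * len(nodule_centers)
    pairs = []
    for r in rois:
        for j, (cr, cc) in enumerate(nodule_centers):
            d = float(np.hypot(r.centroid[0] - cr, r.centroid[1] - cc))
            pairs.append((d, r.roi_id, j))
    pairs.sort()
    used_rois, used_nods = set(), set()
    for d, rid, j in pairs:
        if rid in used_rois or j in used_nods or d > gates[j]:
            continue
        mapping[rid] = nodule_ids[j]
        used_rois.add(rid)
        used_nods.add(j)
    return mapping
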