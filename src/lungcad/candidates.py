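"""Phase 2 front-end: nodule-candidate detection inside the segmented lungs.

Bright inner structures (vessels, bronchi, nodules) are separated from the
parenchyma with a second Otsu threshold restricted to the lung mask.  Each
8-connected structure component that is large enough and round enough —
isoperimetric circularity 4*pi*A / P**2 at least ``circ_min`` — yields one
candidate seed at its centroid.  Seeds are grown into candidate regions by a
deterministic breadth-first region-growing rule: a neighboring pixel joins the
region when its normalized intensity differs from the running region mean by
at most ``max_distance`` (0.18 by default, on the [0, 1] intensity scale).
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

from .errors import DegenerateInputError, InputError
from .io import GrayscaleSlice
from .segmentation import LungMask, SegmentationResult, otsu_threshold

__all__ = [
    "StructureMask",
    "Candidate",
    "CandidateRegion",
    "CandidateDetector",
    "extract_inner_structures",
    "detect_round_centers",
    "grow_region",
    "detect_candidates",
]

_NEIGHBORS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class StructureMask:
    """Binary map of bright inner structures; always a subset of the lung mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass(frozen=True)
class Candidate:
    """A round-shape seed: centroid, slice, size and circularity of its component."""

    center: Tuple[float, float]  # (row, col)
    slice_index: int
    equivalent_diameter: float
    circularity: float


@dataclass
class CandidateRegion:
    """A grown candidate region: the set of pixels absorbed from one seed."""

    pixels: np.ndarray  # (k, 2) int array of (row, col)
    candidate: Candidate

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.int64).reshape(-1, 2)
        if len(self.pixels) < 1:
            raise InputError("a candidate region needs at least one pixel")

    @property
    def area(self) -> int:
        return int(len(self.pixels))

    @property
    def pixel_set(self) -> frozenset:
        return frozenset(map(tuple, self.pixels.tolist()))

    def centroid(self) -> Tuple[float, float]:
        return (float(self.pixels[:, 0].mean()), float(self.pixels[:, 1].mean()))


def _lung_mask_array(lung_mask) -> np.ndarray:
    if isinstance(lung_mask, LungMask):
        return lung_mask.mask
    return np.asarray(lung_mask).astype(bool)


def extract_inner_structures(lung_image, lung_mask) -> StructureMask:
    """Otsu-separate bright inner structures from the parenchyma.

    The threshold is computed over lung-mask pixels only; the structure mask
    is the set of lung pixels strictly above it.  An empty or constant lung
    region yields an empty mask with a warning instead of an error.
    """
    image = lung_image.pixels if isinstance(lung_image, GrayscaleSlice) else np.asarray(lung_image)
    inside = _lung_mask_array(lung_mask)
    if image.shape != inside.shape:
        raise InputError("lung image and lung mask dimensions disagree")
    empty = StructureMask(mask=np.zeros_like(inside, dtype=bool))
    if not inside.any():
        warnings.warn("empty lung mask: no inner structures", UserWarning, stacklevel=2)
        return empty
    try:
        t = otsu_threshold(image, domain_mask=inside)
    except DegenerateInputError:
        warnings.warn("constant lung region: no inner structures", UserWarning, stacklevel=2)
        return empty
    return StructureMask(mask=inside & (image > t))


def detect_round_centers(
    structures: StructureMask,
    *,
    slice_index: int = 1,
    circ_min: float = 0.6,
    min_candidate_area: int = 9,
) -> List[Candidate]:
    """Report one candidate per round/near-round structure component.

    A component qualifies when its area is at least ``min_candidate_area``
    and its isoperimetric circularity 4*pi*A / P**2 is at least ``circ_min``
    (P is the Crofton boundary-length estimate of skimage's regionprops).
    There is no upper size bound, so detection is size invariant.  Rasterized
    small discs can score slightly above 1.
    """
    labels = measure.label(structures.mask, connectivity=2)
    out: List[Candidate] = []
    for rp in measure.regionprops(labels):
        if rp.area < min_candidate_area:
            continue
        perimeter = rp.perimeter_crofton
        if perimeter <= 0:
            continue
        circ = 4.0 * math.pi * rp.area / perimeter**2
        if circ < circ_min:
            continue
        out.append(
            Candidate(
                center=(float(rp.centroid[0]), float(rp.centroid[1])),
                slice_index=slice_index,
                equivalent_diameter=float(rp.equivalent_diameter_area),
                circularity=float(circ),
            )
        )
    return out


def _seed_pixel(seed, structures: Optional[StructureMask], shape) -> Tuple[int, int]:
    """Round a (row, col) seed; snap to the nearest structure pixel if needed."""
    if isinstance(seed, Candidate):
        center = seed.center
    else:
        center = (float(seed[0]), float(seed[1]))
    r = int(round(center[0]))
    c = int(round(center[1]))
    r = min(max(r, 0), shape[0] - 1)
    c = min(max(c, 0), shape[1] - 1)
    if structures is not None and not structures.mask[r, c]:
        pts = np.argwhere(structures.mask)
        if len(pts):
            d2 = (pts[:, 0] - center[0]) ** 2 + (pts[:, 1] - center[1]) ** 2
            r, c = (int(v) for v in pts[int(np.argmin(d2))])
    return r, c


def grow_region(
    lung_image,
    lung_mask,
    seed,
    *,
    max_distance: float = 0.18,
    structures: Optional[StructureMask] = None,
) -> CandidateRegion:
    """Grow a candidate region from a seed by intensity similarity.

    Intensities are normalized to [0, 1] (value / 255).  Starting from the
    seed pixel, the frontier is processed first-in-first-out; an 8-neighbor
    joins the region when the absolute difference between its normalized
    intensity and the current region mean is at most ``max_distance``.  The
    region never leaves the lung mask.  The visit order is fixed (row-major
    neighbor order), so the result is deterministic.
    """
    if not 0.0 <= max_distance <= 1.0:
        raise InputError("max_distance must be in [0, 1]")
    image = lung_image.pixels if isinstance(lung_image, GrayscaleSlice) else np.asarray(lung_image)
    inside = _lung_mask_array(lung_mask)
    norm = image.astype(np.float64) / 255.0
    rows, cols = image.shape
    r0, c0 = _seed_pixel(seed, structures, image.shape)
    if not inside[r0, c0]:
        raise InputError(f"seed ({r0}, {c0}) lies outside the lung mask")

    in_region = np.zeros(image.shape, dtype=bool)
    in_region[r0, c0] = True
    total = norm[r0, c0]
    count = 1
    queue: deque = deque([(r0, c0)])
    eps = 1e-12
    while queue:
        r, c = queue.popleft()
        for dr, dc in _NEIGHBORS_8:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < rows and 0 <= cc < cols):
                continue
            if in_region[rr, cc] or not inside[rr, cc]:
                continue
            if abs(norm[rr, cc] - total / count) <= max_distance + eps:
                in_region[rr, cc] = True
                total += norm[rr, cc]
                count += 1
                queue.append((rr, cc))
    pixels = np.argwhere(in_region)
    cand = seed if isinstance(seed, Candidate) else Candidate(
        center=(float(r0), float(c0)), slice_index=1, equivalent_diameter=1.0, circularity=1.0
    )
    return CandidateRegion(pixels=pixels, candidate=cand)


class CandidateDetector(BaseEstimator):
    """Stateless detector turning a segmented slice into candidate regions.

    Parameters mirror the detection stage: ``circ_min`` and
    ``min_candidate_area`` gate the round-shape seeds, ``max_distance`` is the
    region-growing intensity tolerance on the [0, 1] scale.
    """

    def __init__(
        self,
        circ_min: float = 0.6,
        min_candidate_area: int = 9,
        max_distance: float = 0.18,
    ):
        self.circ_min = circ_min
        self.min_candidate_area = min_candidate_area
        self.max_distance = max_distance

    def fit(self, X=None, y=None) -> "CandidateDetector":
        """No-op: the detector learns nothing from data."""
        return self

    def transform(self, X) -> "List[CandidateRegion] | List[List[CandidateRegion]]":
        """Detect candidates on one or many :class:`SegmentationResult` objects."""
        if isinstance(X, SegmentationResult):
            return self._detect_one(X)
        return [self._detect_one(seg) for seg in X]

    def _detect_one(self, seg: SegmentationResult) -> List[CandidateRegion]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            structures = extract_inner_structures(seg.lung_image, seg.mask)
        if structures.is_empty:
            return []
        seeds = detect_round_centers(
            structures,
            slice_index=seg.slice_index,
            circ_min=self.circ_min,
            min_candidate_area=self.min_candidate_area,
        )
        regions: List[CandidateRegion] = []
        seen = set()
        for seed in seeds:
            region = grow_region(
                seg.lung_image,
                seg.mask,
                seed,
                max_distance=self.max_distance,
                structures=structures,
            )
            key = region.pixel_set
            if key in seen:
                continue
            seen.add(key)
            regions.append(region)
        return regions


def detect_candidates(slc, seg: SegmentationResult, **params) -> List[CandidateRegion]:
    """Thin wrapper over :class:`CandidateDetector` for one segmented slice."""
    del slc  # the segmentation result carries everything needed
    return CandidateDetector(**params).transform(seg)
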