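"""Phase 1: automatic lung segmentation of a chest CT slice.

The slice is assumed to show four intensity regions: a black background, a
dark-gray rim around the body, a bright chest wall, and the dark lung
parenchyma inside it.  Segmentation proceeds by

1. histogram analysis with bin step ``kappa`` — the background threshold
   ``lambda`` is the upper edge of the bin holding the *second* local minimum
   of the count sequence, i.e. the valley that closes the dark background/rim
   peaks;
2. background removal (keep intensities strictly above ``lambda``) followed by
   complementing the image, so the removed background and the dark lungs both
   turn bright;
3. Otsu thresholding of the complemented image to a binary mask;
4. refinement: delete the largest connected component (the bright frame
   enclosing the lungs), delete border-touching components and components
   below ``min_area``, fill interior holes punched by bright inner structures,
   and dilate;
5. a 3x3 median filter on the masked grayscale lungs.

Everything is deterministic and needs no user interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DegenerateInputError, EmptySegmentationWarning, InputError
from .io import GrayscaleSlice

__all__ = [
    "Histogram",
    "SegmentationThresholds",
    "LungMask",
    "SegmentationResult",
    "LungSegmenter",
    "compute_histogram",
    "estimate_background_threshold",
    "remove_background",
    "otsu_threshold",
    "make_lung_mask",
    "segment_lungs",
]


@dataclass(frozen=True)
class Histogram:
    """Intensity histogram of one slice with bin step ``kappa``.

    Bins cover [0, kappa), [kappa, 2*kappa), ...; the last bin is truncated at
    255 inclusive, so there are ceil(256 / kappa) bins and the counts conserve
    the slice's pixel count.
    """

    bin_step: int
    counts: np.ndarray
    bin_edges: np.ndarray  # lower edge intensity of each bin

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def bin_upper_edge(self, i: int) -> int:
        """Largest intensity belonging to bin ``i``."""
        return int(min((i + 1) * self.bin_step - 1, 255))


@dataclass
class SegmentationThresholds:
    """Per-slice thresholds chosen by the segmenter.

    ``lambda_bg`` separates background+rim from the rest; ``tau_lung`` is the
    Otsu threshold on the complemented image; ``lambda_source`` records
    whether the second-minimum rule or the Otsu fallback produced lambda.
    """

    lambda_bg: int
    tau_lung: Optional[int] = None
    lambda_source: str = "second_minimum"  # or "otsu_fallback"


@dataclass
class LungMask:
    """Binary lung-parenchyma map plus its connected components.

    ``components`` lists ``(label, pixel_count, bbox)`` with bbox in skimage
    order (min_row, min_col, max_row, max_col).
    """

    mask: np.ndarray
    components: List[Tuple[int, int, Tuple[int, int, int, int]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())


@dataclass
class SegmentationResult:
    """Output of one slice segmentation: mask, masked lungs, thresholds."""

    mask: LungMask
    lung_image: np.ndarray  # median-filtered grayscale lungs, 0 outside mask
    thresholds: SegmentationThresholds
    slice_index: int = 1


def _pixels_of(image) -> np.ndarray:
    if isinstance(image, GrayscaleSlice):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim != 2:
        raise InputError("expected a 2-D grayscale grid")
    return arr


def compute_histogram(slc, kappa: int = 5) -> Histogram:
    """Histogram of a slice with bin step ``kappa`` (1 <= kappa <= 128)."""
    if not 1 <= int(kappa) <= 128:
        raise InputError("kappa must be in [1, 128]")
    kappa = int(kappa)
    pixels = _pixels_of(slc)
    n_bins = -(-256 // kappa)  # ceil
    counts = np.bincount(pixels.ravel() // kappa, minlength=n_bins).astype(np.int64)
    edges = np.arange(n_bins, dtype=np.int64) * kappa
    return Histogram(bin_step=kappa, counts=counts, bin_edges=edges)


def _plateau_local_minima(counts: Sequence[float]) -> List[int]:
    """Indices of interior local minima, one per flat run.

    An interior bin ``i`` is a minimum iff counts[i-1] > counts[i] < counts[i+1];
    a flat run of equal counts bounded on both sides by strictly larger values
    counts as a single minimum located at its center bin.
    """
    counts = np.asarray(counts, dtype=float)
    n = len(counts)
    minima: List[int] = []
    s = 0
    while s < n:
        e = s
        while e + 1 < n and counts[e + 1] == counts[s]:
            e += 1
        if s > 0 and e < n - 1 and counts[s - 1] > counts[s] and counts[e + 1] > counts[s]:
            minima.append((s + e) // 2)
        s = e + 1
    return minima


def _smooth(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average of odd width; edge bins copied unchanged."""
    if window <= 1:
        return np.asarray(counts, dtype=float)
    if window % 2 == 0:
        raise InputError("smooth window must be odd")
    half = window // 2
    out = np.asarray(counts, dtype=float).copy()
    kernel = np.ones(window) / window
    inner = np.convolve(counts, kernel, mode="valid")
    out[half : len(counts) - half] = inner
    return out


def estimate_background_threshold(
    hist: Histogram, *, smooth_window: int = 1, image=None
) -> SegmentationThresholds:
    """Background threshold lambda from the 2nd local minimum of the histogram.

    Scans bins from 0 upward for interior local minima (plateau rule: a flat
    run bounded by larger neighbors is one minimum at its center).  lambda is
    the upper-edge intensity of the bin holding the second minimum, so that
    thresholding with strict ``> lambda`` drops that bin and everything below.

    If fewer than two minima exist (degenerate histograms), the Otsu threshold
    of the raw slice is used instead — pass the slice via ``image``; without it
    the fallback raises :class:`InputError`.
    """
    if hist.n_bins < 3:
        raise InputError("need at least 3 histogram bins")
    smoothed = _smooth(hist.counts, smooth_window)
    minima = _plateau_local_minima(smoothed)
    if len(minima) >= 2:
        lam = hist.bin_upper_edge(minima[1])
        return SegmentationThresholds(lambda_bg=lam, lambda_source="second_minimum")
    if image is None:
        raise InputError(
            "histogram has fewer than two local minima and no image was "
            "supplied for the Otsu fallback"
        )
    lam = otsu_threshold(image)
    return SegmentationThresholds(lambda_bg=int(lam), lambda_source="otsu_fallback")


def remove_background(slc, lambda_bg: int) -> np.ndarray:
    """Drop background (intensity <= lambda) and complement the result.

    Pixels strictly above ``lambda_bg`` keep their value, the rest become 0;
    the image is then complemented (255 - value), so removed background turns
    white and the bright chest wall turns black.
    """
    if not 0 <= lambda_bg <= 255:
        raise InputError("lambda must be in [0, 255]")
    pixels = _pixels_of(slc)
    kept = np.where(pixels > lambda_bg, pixels, 0)
    return (255 - kept).astype(np.uint8)


def otsu_threshold(image, domain_mask: Optional[np.ndarray] = None) -> int:
    """Otsu threshold over the pixels inside ``domain_mask`` (whole image if None).

    Returns the integer t maximizing the between-class variance of the split
    {<= t} vs {> t}; exact ties are broken toward the smallest t.  A constant
    domain raises :class:`DegenerateInputError`.
    """
    pixels = _pixels_of(image)
    if domain_mask is not None:
        vals = pixels[np.asarray(domain_mask).astype(bool)]
    else:
        vals = pixels.ravel()
    if vals.size == 0:
        raise DegenerateInputError("empty domain for Otsu thresholding")
    if vals.min() == vals.max():
        raise DegenerateInputError("constant image in Otsu domain")
    hist = np.bincount(vals, minlength=256).astype(np.float64)
    p = hist / hist.sum()
    omega = np.cumsum(p)          # weight of class {<= t}
    mu = np.cumsum(p * np.arange(256))
    mu_t = mu[-1]
    valid = (omega > 0) & (omega < 1)
    sigma_b = np.zeros(256)
    sigma_b[valid] = (mu_t * omega[valid] - mu[valid]) ** 2 / (
        omega[valid] * (1.0 - omega[valid])
    )
    return int(np.argmax(sigma_b))  # first occurrence = smallest threshold


def make_lung_mask(
    complemented: np.ndarray,
    tau_lung: int,
    *,
    connectivity: int = 2,
    min_area: int = 50,
    dilation_radius: int = 2,
    fill_holes: bool = True,
) -> LungMask:
    """Binary lung mask from the complemented image and Otsu threshold tau.

    B(x, y) = 1 iff complemented(x, y) > tau.  Refinement then deletes the
    largest component (the bright frame enclosing the lungs; exact ties are
    all deleted), every component touching the image border, and components
    smaller than ``min_area``; fills interior holes (bright vessels/nodules
    punch holes in the parenchyma mask); and dilates with a disk of
    ``dilation_radius``.  An empty result is returned with an
    :class:`EmptySegmentationWarning`, not an error.
    """
    comp_img = _pixels_of(complemented)
    binary = comp_img > int(tau_lung)

    def _empty() -> LungMask:
        warnings.warn(
            "segmentation produced an empty lung mask", EmptySegmentationWarning, stacklevel=3
        )
        return LungMask(mask=np.zeros_like(binary, dtype=bool), components=[])

    labels = measure.label(binary, connectivity=connectivity)
    if labels.max() == 0:
        return _empty()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.ones(len(sizes), dtype=bool)
    keep[0] = False
    keep[sizes == sizes.max()] = False  # largest component(s): the enclosing frame
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    keep[border_labels] = False
    keep[sizes < int(min_area)] = False
    mask = keep[labels]
    if not mask.any():
        return _empty()
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if dilation_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(int(dilation_radius)))
    relabeled = measure.label(mask, connectivity=connectivity)
    components = [
        (int(rp.label), int(rp.area), tuple(int(v) for v in rp.bbox))
        for rp in measure.regionprops(relabeled)
    ]
    return LungMask(mask=mask, components=components)


class LungSegmenter(TransformerMixin, BaseEstimator):
    """Stateless transformer running the full per-slice lung segmentation.

    Parameters
    ----------
    kappa : int, default 5
        Histogram bin step used for the background-threshold estimate.
    smooth_window : int, default 1
        Odd width of an optional moving-average smoothing of the histogram
        counts before the minima scan (1 = no smoothing).
    min_area : int, default 50
        Components smaller than this survive neither refinement.
    dilation_radius : int, default 2
        Radius of the disk structuring element of the final dilation.
    connectivity : int, default 2
        skimage connectivity for component labeling (2 = 8-connectivity).
    fill_holes : bool, default True
        Fill interior holes left by bright inner structures.
    median_size : int, default 3
        Side of the square median filter applied to the masked lungs.
    allow_fallback : bool, default True
        Permit the Otsu fallback when the histogram lacks a second minimum.
    """

    def __init__(
        self,
        kappa: int = 5,
        smooth_window: int = 1,
        min_area: int = 50,
        dilation_radius: int = 2,
        connectivity: int = 2,
        fill_holes: bool = True,
        median_size: int = 3,
        allow_fallback: bool = True,
    ):
        self.kappa = kappa
        self.smooth_window = smooth_window
        self.min_area = min_area
        self.dilation_radius = dilation_radius
        self.connectivity = connectivity
        self.fill_holes = fill_holes
        self.median_size = median_size
        self.allow_fallback = allow_fallback

    def fit(self, X=None, y=None) -> "LungSegmenter":
        """No-op: the segmenter learns nothing from data."""
        return self

    def transform(self, X) -> "SegmentationResult | List[SegmentationResult]":
        """Segment one slice or a sequence/stack of slices."""
        if isinstance(X, GrayscaleSlice) or (isinstance(X, np.ndarray) and X.ndim == 2):
            return self._segment_one(X)
        return [self._segment_one(s) for s in X]

    def _segment_one(self, slc) -> SegmentationResult:
        pixels = _pixels_of(slc)
        slice_index = slc.slice_index if isinstance(slc, GrayscaleSlice) else 1

        def _empty(thresholds: SegmentationThresholds) -> SegmentationResult:
            warnings.warn(
                "segmentation produced an empty lung mask",
                EmptySegmentationWarning,
                stacklevel=3,
            )
            empty = LungMask(mask=np.zeros_like(pixels, dtype=bool), components=[])
            return SegmentationResult(
                mask=empty,
                lung_image=np.zeros_like(pixels),
                thresholds=thresholds,
                slice_index=slice_index,
            )

        hist = compute_histogram(pixels, self.kappa)
        try:
            thresholds = estimate_background_threshold(
                hist,
                smooth_window=self.smooth_window,
                image=pixels if self.allow_fallback else None,
            )
        except DegenerateInputError:
            # constant slice: nothing to segment
            return _empty(SegmentationThresholds(lambda_bg=0, lambda_source="otsu_fallback"))
        complemented = remove_background(pixels, thresholds.lambda_bg)
        try:
            tau = otsu_threshold(complemented)
        except DegenerateInputError:
            return _empty(thresholds)
        thresholds.tau_lung = int(tau)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EmptySegmentationWarning)
            mask = make_lung_mask(
                complemented,
                tau,
                connectivity=self.connectivity,
                min_area=self.min_area,
                dilation_radius=self.dilation_radius,
                fill_holes=self.fill_holes,
            )
        if mask.is_empty:
            return _empty(thresholds)
        lung = np.where(mask.mask, pixels, 0).astype(np.uint8)
        if self.median_size > 1:
            lung = ndimage.median_filter(lung, size=int(self.median_size))
            lung = np.where(mask.mask, lung, 0).astype(np.uint8)
        return SegmentationResult(
            mask=mask, lung_image=lung, thresholds=thresholds, slice_index=slice_index
        )


def segment_lungs(slc, **params) -> Tuple[LungMask, np.ndarray]:
    """Segment one slice; thin wrapper over :class:`LungSegmenter`.

    Returns ``(mask, lung_image)`` where ``lung_image`` is the median-filtered
    masked grayscale slice (0 outside the mask).
    """
    result = LungSegmenter(**params).transform(slc)
    return result.mask, result.lung_image
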