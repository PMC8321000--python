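# Methods

This note records the model behind `lungcad`, the choices made where the
design was genuinely open, and what the synthetic phantom does and does not
demonstrate.

## Image model and segmentation

A PNG-exported axial chest CT slice is modeled as four intensity regions:
black background (≈0), a dark-gray rim around the body (≈60), a bright
chest wall (≈255, with darker patches ≈210), and dark lung parenchyma.
The histogram therefore carries four peaks, and the valley that closes the
two dark peaks separates "background + rim" from "wall + lungs-context".

**Second-minimum rule.**  The histogram (bin step κ = 5 intensity units) is
scanned from bin 0 for interior local minima; a flat run of equal counts
bounded on both sides by strictly larger values counts as one minimum at
its center bin.  λ is the upper-edge intensity of the bin holding the
second minimum, so thresholding with strict `> λ` drops that bin and
everything below.  The scan runs on the **raw** counts by default; an
optional centered moving average (`smooth_window`, odd, edge bins copied)
is available but off, because smoothing merges the narrow first valley of
clean histograms and changes which minimum is "second".  When fewer than
two minima exist (degenerate slices), λ falls back to the Otsu threshold of
the raw slice and the choice is recorded in the per-slice threshold log.

**Otsu.**  Implemented as a vectorized exhaustive argmax of the
between-class variance over all 256 split points, with exact ties broken
toward the smallest threshold, and with an optional domain mask so the same
routine serves both the complemented-image split and the inner-structure
split restricted to lung pixels.  This keeps the tie-break and domain
semantics explicit; a library Otsu is used only as an independent
cross-check in the tests.

**Mask refinement.**  After `B = Ī > τ`: 8-connected labeling; the largest
component is deleted (it is the complemented background/rim frame that
encloses the lungs; exact ties are all deleted); border-touching components
and components below `min_area = 50 px` are deleted; interior holes are
filled; survivors are dilated with a disk of radius 2.  Hole filling is an
explicit step here: bright nodules and vessels survive the λ threshold and
therefore punch holes in the parenchyma mask, and a radius-2 dilation alone
cannot re-include a structure wider than 2 px — yet the whole point of the
mask is to keep those structures inside the search region.  Filling
implements that intent deterministically; it is configurable
(`fill_holes`).  The 3×3 median filter is applied to the masked grayscale
lungs (not to the binary mask), and masked-out pixels are forced back to 0
afterwards.

## Candidate detection

Inner structures are the lung pixels strictly above the lung-restricted
Otsu threshold.  Each 8-connected component with area ≥ 9 px is scored by
isoperimetric circularity `4πA/P²` with `P` the Crofton perimeter estimate
of `skimage.measure.regionprops`.  The Crofton estimator was chosen because
the naive count of boundary edge steps biases `P` upward by ≈ 4/π for
smooth shapes (a rasterized disc would score ≈ 0.62 and discs and bars
would become inseparable); with Crofton, rasterized discs of radius 5–50
score 0.88–1.0 (small discs can slightly exceed 1) and 5:1 bars score near
the analytic `5π/36 ≈ 0.44`.  The gate is `circ ≥ 0.6`.  Nodules fused with
a vessel form one component and are scored as one shape; no splitting is
attempted.

**Region growing.**  Seeds are component centroids (snapped to the nearest
component pixel if the centroid falls outside).  Intensities are normalized
to [0, 1]; the frontier is a FIFO queue with a fixed row-major neighbor
order, and a pixel joins when `|I(p) − mean(region)| ≤ 0.18` against the
*running* region mean.  The result is deterministic; growth confined to the
lung mask.  With a running mean, monotonicity in the distance parameter is
not guaranteed in general, so it is checked empirically on fixtures, not
asserted universally.

## Features and classification

Per region: mean, median (midpoint of the two central values for even
counts), mode (most frequent 8-bit value, smallest on ties), population
variance (divide by region size) and its square root, plus the consistency
bit.  The consistency search window of size 2k+1 (k = 1) covers the 2k
neighboring slices — the candidate's own slice is excluded — and a match is
a neighbor-slice candidate center within `max(3 px, equivalent_diameter/2)`
(inclusive), with missing slices at stack boundaries simply absent.

The classifier is a linear SVM (`LinearSVC`, C = 1.0, fixed seed) on
features standardized with the training set's mean and standard deviation
(zero-variance features get scale 1; standardization matters because raw
features span [0, 255] against a {0, 1} bit).  Consistency handling is
configurable: `feature` (default — t is just the sixth feature), `filter`
(t = 0 candidates are dropped without scoring), or `both`.  The default
follows the formal feature-vector definition; the filter mode reproduces
the narrative in which inconsistent candidates are discarded outright.
Models persist to JSON with exact float round-trip.

## Evaluation conventions

Greedy nearest-first one-to-one matching of detection centers to
ground-truth centers on the same slice (radius 5 px by default); unmatched
detections are FP, unmatched truths FN.  True negatives are counted over
classified candidates — a candidate labeled non-nodule with no truth center
nearby — because image-level TN is ill-defined for a detection task.  Any
metric with a zero denominator reports 0 and is listed in the report's
`degenerate` field; MCC additionally returns 0 when any marginal sum is 0.
Fβ uses β = 0.5; FPI = FP / images, FPE = FP / exams, both exact ratios.

## The phantom: what it emulates and what it does not

Each slice is the four-region layout above: body rim and parenchyma share
the same dark gray (60) — which is what produces the canonical four-peak
histogram — wall at 255 with patches at 210, additive Gaussian noise
(σ = 5) clipped to [0, 255].  Lungs are two mirrored ellipses (semi-axes
0.215·M and 0.125·N) with a sinusoidal boundary perturbation.  Planted
structures:

* **Nodules** (level 210): spheres of radius 4–7 px spanning 5 slices with
  a fixed in-plane center; ground truth records the slices where the
  cross-section radius is ≥ 2 px (below that, a cross-section is smaller
  than the 9 px candidate gate and not a meaningful target).
* **Vessels** (level 190): oblique cylinders of radius 2.5–4.5 px whose
  cross-section centers drift 8 px per slice — beyond the maximal default
  consistency radius, so vessels fail the across-slice test by
  construction.  Vessels are placed before nodules because their 64 px
  drifting paths are the most constrained geometry; all structures keep a
  minimum mutual per-slice separation of 22 px so consistency matches are
  never accidental.

Placement is rejection sampling against the lung's Euclidean distance
transform; infeasible configurations raise a config error rather than
degrade silently.  Generation is bit-deterministic given the seed.

Passing on the phantom shows the pipeline's logic is correct end to end —
thresholds land between the designed modes, refinement isolates the lung
fields (mean Jaccard ≈ 0.91, the loss dominated by the prescribed radius-2
dilation overshoot), candidates are found, and the consistency bit plus
intensity statistics separate the two structure classes.  It does **not**
demonstrate clinical performance: real CT has HU calibration and windowing
variation, juxta-pleural and juxta-vascular nodules, textured parenchyma,
partial-volume effects and scanner noise that the phantom deliberately
omits.  Results on the phantom are an upper bound of method behavior under
its own assumptions, not a claim about patient data.

## Problem sizes and numerical conventions

The standard experiment (tests and `scripts/acceptance.py`) uses 256×256
slices, 9 slices per exam, 2 nodules + 3 vessels per exam, 10 training and
20 held-out test exams, 20 phantoms for segmentation recovery, 100 random
images for the Otsu oracle and 1000 random histograms for the
second-minimum oracle — sizes chosen to exercise every code path with
comfortably repeatable statistics.  All randomness flows through
`numpy.random.default_rng` seeds; pipeline outputs are byte-identical
across repeated runs.  DICOM inputs are reduced to 8 bits by per-slice
min–max scaling (a constant slice maps to all zeros) or an explicit
(center, width) window; no HU calibration is attempted.  Series order is
DICOM InstanceNumber when every file carries one, else lexicographic
filename.

## Known limitations

Strictly 2-D per-slice segmentation (no lobe separation, trachea removal or
3-D labeling); no FROC analysis or confidence intervals; no splitting of
juxta-vascular candidates; the consistency feature assumes roughly
contiguous slice sampling (large slice gaps would break the co-location
assumption); the linear SVM is intentionally minimal — no kernels, no
probability calibration.
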