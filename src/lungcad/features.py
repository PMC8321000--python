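"""Candidate features and SVM classification.

Each candidate region is summarized by a six-element feature vector

    F = (mean, median, mode, variance, std, consistency)

computed over the region's 8-bit intensities.  Variance is the population
variance (divide by the region size), the mode breaks ties toward the
smallest value, and the consistency bit records whether the candidate's
center re-occurs in any of the 2k neighboring slices of a window of size
2k + 1 (k = 1 by default): nodules are spherical, so their cross-sections
stay put across adjacent slices, while vessel cross-sections drift.

Classification is a linear SVM (LIBLINEAR family) on the standardized
feature vectors; the fitted model can be saved to and loaded from a JSON
file with an exact round trip.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import LinearSVC

from .candidates import Candidate, CandidateRegion
from .errors import InputError
from .io import GrayscaleSlice

__all__ = [
    "FeatureVector",
    "LabeledExample",
    "NoduleClassifier",
    "stat_features",
    "consistency_feature",
    "assign_consistency",
    "build_feature_vector",
    "train_classifier",
    "classify_candidates",
    "save_classifier",
    "load_classifier",
    "examples_to_frame",
    "frame_to_examples",
]

FEATURE_NAMES = ("mean", "median", "mode", "variance", "std", "consistency")

NODULE = "nodule"
NON_NODULE = "non_nodule"


@dataclass(frozen=True)
class FeatureVector:
    """The six-element candidate descriptor, in fixed order."""

    mean: float
    median: float
    mode: float
    variance: float
    std: float
    consistency: int

    def __post_init__(self) -> None:
        if self.consistency not in (0, 1):
            raise InputError("consistency bit must be 0 or 1")
        if self.variance < 0:
            raise InputError("variance must be non-negative")
        if not math.isclose(self.std, math.sqrt(self.variance), rel_tol=1e-9, abs_tol=1e-9):
            raise InputError("std must equal sqrt(variance)")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.median, self.mode, self.variance, self.std, self.consistency],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class LabeledExample:
    """One training/testing row: features, binary label, provenance."""

    features: FeatureVector
    label: str
    provenance: Tuple[str, int, Tuple[float, float]] = ("", 0, (0.0, 0.0))

    def __post_init__(self) -> None:
        if self.label not in (NODULE, NON_NODULE):
            raise InputError(f"label must be {NODULE!r} or {NON_NODULE!r}")


def _region_values(region: CandidateRegion, image) -> np.ndarray:
    pixels = image.pixels if isinstance(image, GrayscaleSlice) else np.asarray(image)
    vals = pixels[region.pixels[:, 0], region.pixels[:, 1]]
    if vals.size == 0:
        raise InputError("empty candidate region")
    return vals.astype(np.int64)


def stat_features(region: CandidateRegion, image) -> Tuple[float, float, float, float, float]:
    """(mean, median, mode, variance, std) of the region's intensities.

    Median of an even count is the midpoint of the two central values; the
    mode is the most frequent 8-bit value with ties broken toward the
    smallest; the variance is the population variance.
    """
    vals = _region_values(region, image)
    mean = float(vals.mean())
    median = float(np.median(vals))
    mode = float(np.bincount(vals, minlength=256).argmax())
    variance = float(vals.var())  # ddof=0: divide by region size
    return mean, median, mode, variance, math.sqrt(variance)


def _match_radius_for(candidate: Candidate, match_radius: Optional[float]) -> float:
    if match_radius is not None:
        return float(match_radius)
    return max(3.0, candidate.equivalent_diameter / 2.0)


def consistency_feature(
    candidate: Candidate,
    neighbor_centers: Mapping[int, Sequence[Candidate]],
    k: int = 1,
    match_radius: Optional[float] = None,
) -> int:
    """1 iff the candidate's center re-occurs in a neighboring slice.

    Searches the 2k slices j-k..j+k excluding j itself (slices missing at the
    stack boundary are simply absent from ``neighbor_centers``).  A neighbor
    matches when its center lies within Euclidean distance ``match_radius``
    of this candidate's center, boundary inclusive.  The default radius is
    max(3 px, half the candidate's equivalent diameter).
    """
    if k < 1:
        raise InputError("half-window k must be >= 1")
    radius = _match_radius_for(candidate, match_radius)
    j = candidate.slice_index
    r0, c0 = candidate.center
    for jj in range(j - k, j + k + 1):
        if jj == j:
            continue
        for other in neighbor_centers.get(jj, ()):
            dr = other.center[0] - r0
            dc = other.center[1] - c0
            if math.hypot(dr, dc) <= radius:
                return 1
    return 0


def assign_consistency(
    candidates_by_slice: Mapping[int, Sequence[Candidate]],
    k: int = 1,
    match_radius: Optional[float] = None,
) -> Dict[int, List[int]]:
    """Consistency bit for every candidate of every slice of one exam."""
    return {
        j: [
            consistency_feature(cand, candidates_by_slice, k=k, match_radius=match_radius)
            for cand in cands
        ]
        for j, cands in candidates_by_slice.items()
    }


def build_feature_vector(region: CandidateRegion, t: int, image) -> FeatureVector:
    """Assemble the six features in the fixed order (mean, median, mode, var, std, t)."""
    mean, median, mode, variance, std = stat_features(region, image)
    return FeatureVector(
        mean=mean, median=median, mode=mode, variance=variance, std=std, consistency=int(t)
    )


class NoduleClassifier(ClassifierMixin, BaseEstimator):
    """Linear SVM separating nodules from vessels/bronchi.

    Features are standardized with center/scale learned on the training data
    (a zero-variance feature gets scale 1), then a linear-kernel SVM
    (LIBLINEAR family, regularization ``C``) is fit.  The decision function
    and predictions are deterministic given the features.

    Fitted attributes: ``classes_``, ``coef_``, ``intercept_`` (in
    standardized feature space), ``center_``, ``scale_``, ``n_features_in_``.
    """

    def __init__(self, C: float = 1.0, class_weight=None, random_state: int = 0):
        self.C = C
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y) -> "NoduleClassifier":
        X = self._as_matrix(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise InputError("X and y length mismatch")
        classes = np.unique(y)
        if len(classes) < 2:
            raise InputError("training data must contain both classes")
        center = X.mean(axis=0)
        scale = X.std(axis=0)
        scale = np.where(scale == 0.0, 1.0, scale)
        svc = LinearSVC(
            C=self.C,
            class_weight=self.class_weight,
            random_state=self.random_state,
            dual="auto",
        )
        svc.fit((X - center) / scale, y)
        self.center_ = center
        self.scale_ = scale
        self.coef_ = svc.coef_.copy()
        self.intercept_ = svc.intercept_.copy()
        self.classes_ = svc.classes_.copy()
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        self._check_fitted()
        X = self._as_matrix(X)
        return ((X - self.center_) / self.scale_) @ self.coef_.ravel() + float(
            self.intercept_[0]
        )

    def predict(self, X) -> np.ndarray:
        d = self.decision_function(X)
        return self.classes_[(d > 0).astype(int)]

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise InputError("classifier is not fitted")

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if len(X) and isinstance(X[0], FeatureVector):
            X = np.vstack([fv.as_array() for fv in X])
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != len(FEATURE_NAMES):
            raise InputError(f"expected an (n, {len(FEATURE_NAMES)}) feature matrix")
        return X


def train_classifier(
    examples: Sequence[LabeledExample],
    *,
    C: float = 1.0,
    class_weight=None,
    random_state: int = 0,
) -> NoduleClassifier:
    """Fit a :class:`NoduleClassifier` on labeled feature vectors."""
    if not examples:
        raise InputError("no training examples")
    X = np.vstack([ex.features.as_array() for ex in examples])
    y = np.array([ex.label for ex in examples])
    return NoduleClassifier(C=C, class_weight=class_weight, random_state=random_state).fit(X, y)


def classify_candidates(
    model: NoduleClassifier,
    vectors: Sequence[FeatureVector],
    mode: str = "feature",
) -> List[str]:
    """Label candidates as nodule / non-nodule.

    mode="feature" (default): every candidate is scored by the SVM on the full
    six-element vector.  mode="filter": candidates whose consistency bit is 0
    are dropped (labeled non-nodule) without scoring, the rest are nodules.
    mode="both": drop inconsistent candidates, then score the survivors.
    """
    if mode not in ("feature", "filter", "both"):
        raise InputError(f"unknown consistency mode {mode!r}")
    if not vectors:
        return []
    labels = [NON_NODULE] * len(vectors)
    if mode == "filter":
        for i, fv in enumerate(vectors):
            labels[i] = NODULE if fv.consistency == 1 else NON_NODULE
        return labels
    if mode == "feature":
        survivors = list(range(len(vectors)))
    else:  # both
        survivors = [i for i, fv in enumerate(vectors) if fv.consistency == 1]
    if survivors:
        pred = model.predict([vectors[i] for i in survivors])
        for i, p in zip(survivors, pred):
            labels[i] = str(p)
    return labels


_MODEL_FORMAT_VERSION = 1


def save_classifier(model: NoduleClassifier, path) -> None:
    """Persist a fitted classifier as JSON (exact float round trip)."""
    model._check_fitted()
    payload = {
        "format_version": _MODEL_FORMAT_VERSION,
        "params": {
            "C": model.C,
            "class_weight": model.class_weight,
            "random_state": model.random_state,
        },
        "classes": [str(c) for c in model.classes_],
        "center": model.center_.tolist(),
        "scale": model.scale_.tolist(),
        "coef": model.coef_.ravel().tolist(),
        "intercept": float(model.intercept_[0]),
        "feature_names": list(FEATURE_NAMES),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_classifier(path) -> NoduleClassifier:
    """Load a classifier saved by :func:`save_classifier`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _MODEL_FORMAT_VERSION:
        raise InputError("unrecognized model file version")
    model = NoduleClassifier(**payload["params"])
    model.center_ = np.asarray(payload["center"], dtype=np.float64)
    model.scale_ = np.asarray(payload["scale"], dtype=np.float64)
    model.coef_ = np.asarray(payload["coef"], dtype=np.float64).reshape(1, -1)
    model.intercept_ = np.asarray([payload["intercept"]], dtype=np.float64)
    model.classes_ = np.asarray(payload["classes"])
    model.n_features_in_ = model.coef_.shape[1]
    return model


def examples_to_frame(examples: Sequence[LabeledExample]) -> pd.DataFrame:
    """Labeled examples as a flat table (feature columns + label + provenance)."""
    rows = []
    for ex in examples:
        row = dict(zip(FEATURE_NAMES, ex.features.as_array()))
        row["label"] = ex.label
        row["exam_id"], row["slice_index"], (row["row"], row["col"]) = ex.provenance
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_examples(frame: pd.DataFrame) -> List[LabeledExample]:
    """Inverse of :func:`examples_to_frame`."""
    out = []
    for _, row in frame.iterrows():
        fv = FeatureVector(
            mean=float(row["mean"]),
            median=float(row["median"]),
            mode=float(row["mode"]),
            variance=float(row["variance"]),
            std=float(row["std"]),
            consistency=int(row["consistency"]),
        )
        prov = (
            str(row.get("exam_id", "")),
            int(row.get("slice_index", 0)),
            (float(row.get("row", 0.0)), float(row.get("col", 0.0))),
        )
        out.append(LabeledExample(features=fv, label=str(row["label"]), provenance=prov))
    return out
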