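"""Detection evaluation: matching and the metric battery.

Detections are matched to ground-truth nodules per slice by a greedy
nearest-first one-to-one rule, then the usual confusion-matrix metrics are
computed: sensitivity (recall), specificity, precision, accuracy, the Fbeta
score (beta = 0.5 by default), the Matthews correlation coefficient, and the
CAD burden metrics FPI (false positives per image) and FPE (false positives
per exam).

True negatives for a detection task are counted over classified candidates:
a candidate region classified non-nodule with no ground-truth nodule nearby
is a TN.  Any metric whose denominator is zero is reported as 0 and the
metric's name is recorded in the report's ``degenerate`` list.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from .errors import InputError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "TruthEntry",
    "match_detections",
    "compute_metrics",
    "read_truth",
    "write_truth",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Non-negative TP / TN / FP / FN counts."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            tn=self.tn + other.tn,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class TruthEntry:
    """One ground-truth nodule cross-section on one slice."""

    exam_id: str
    slice_index: int
    center: Tuple[float, float]
    radius_px: float
    kind: str = "nodule"


@dataclass
class MetricReport:
    """The full metric battery for one evaluation run."""

    counts: ConfusionCounts
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f_beta: float
    beta: float
    mcc: float
    fpi: float
    fpe: float
    n_images: int
    n_exams: int
    degenerate: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "f_beta": self.f_beta,
            "beta": self.beta,
            "mcc": self.mcc,
            "fpi": self.fpi,
            "fpe": self.fpe,
            "n_images": self.n_images,
            "n_exams": self.n_exams,
            "degenerate": list(self.degenerate),
        }


def _as_points(items: Iterable) -> List[Tuple[int, float, float]]:
    """Normalize detections/truths to (slice_index, row, col) triples."""
    out = []
    for it in items:
        if hasattr(it, "slice_index") and hasattr(it, "center"):
            out.append((int(it.slice_index), float(it.center[0]), float(it.center[1])))
        else:
            j, r, c = it
            out.append((int(j), float(r), float(c)))
    return out


def match_detections(
    detections: Iterable,
    truth: Iterable,
    *,
    negatives: Iterable = (),
    match_radius: float = 5.0,
) -> ConfusionCounts:
    """Greedy nearest-first one-to-one matching of detections to truths.

    A detection is a TP when its center lies within ``match_radius`` of a
    still-unmatched truth center on the same slice; pairs are taken in order
    of increasing distance, so each truth absorbs at most one detection.
    Unmatched detections are FP, unmatched truths are FN.  ``negatives`` are
    candidate centers classified non-nodule; each with no truth center within
    the radius counts one TN.

    Items may be (slice_index, row, col) triples or any object exposing
    ``slice_index`` and ``center``.
    """
    dets = _as_points(detections)
    trus = _as_points(truth)
    negs = _as_points(negatives)

    pairs = []
    for i, (jd, rd, cd) in enumerate(dets):
        for t, (jt, rt, ct) in enumerate(trus):
            if jd != jt:
                continue
            d = math.hypot(rd - rt, cd - ct)
            if d <= match_radius:
                pairs.append((d, i, t))
    pairs.sort()
    det_matched = [False] * len(dets)
    tru_matched = [False] * len(trus)
    tp = 0
    for _, i, t in pairs:
        if det_matched[i] or tru_matched[t]:
            continue
        det_matched[i] = True
        tru_matched[t] = True
        tp += 1
    fp = det_matched.count(False)
    fn = tru_matched.count(False)
    tn = 0
    for jn, rn, cn in negs:
        near = any(
            jn == jt and math.hypot(rn - rt, cn - ct) <= match_radius for jt, rt, ct in trus
        )
        if not near:
            tn += 1
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_div(num: float, den: float, name: str, degenerate: List[str]) -> float:
    if den == 0:
        degenerate.append(name)
        return 0.0
    return num / den


def compute_metrics(
    counts: ConfusionCounts,
    *,
    beta: float = 0.5,
    n_images: int = 1,
    n_exams: int = 1,
) -> MetricReport:
    """All metrics of the battery from one set of confusion counts.

    Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); precision =
    TP/(TP+FP); accuracy = (TP+TN)/total; Fbeta = (1+beta^2)PR /
    (beta^2 P + R); MCC = (TP*TN - FP*FN) / sqrt of the four marginal
    products (0 when any marginal is 0); FPI = FP/n_images; FPE = FP/n_exams.
    """
    if counts.total < 1:
        raise InputError("confusion counts are all zero")
    if n_images < 1 or n_exams < 1:
        raise InputError("n_images and n_exams must be >= 1")
    if beta <= 0:
        raise InputError("beta must be positive")
    degenerate: List[str] = []
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = _safe_div(tp, tp + fn, "sensitivity", degenerate)
    spec = _safe_div(tn, tn + fp, "specificity", degenerate)
    prec = _safe_div(tp, tp + fp, "precision", degenerate)
    acc = (tp + tn) / counts.total
    fb = _safe_div(
        (1.0 + beta**2) * prec * sens, beta**2 * prec + sens, "f_beta", degenerate
    )
    marginals = [tp + fp, tp + fn, tn + fp, tn + fn]
    if any(m == 0 for m in marginals):
        degenerate.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(float(m) for m in marginals))
    return MetricReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        accuracy=acc,
        f_beta=fb,
        beta=beta,
        mcc=mcc,
        fpi=fp / n_images,
        fpe=fp / n_exams,
        n_images=n_images,
        n_exams=n_exams,
        degenerate=degenerate,
    )


def write_truth(entries: Sequence[TruthEntry], path) -> None:
    """Write ground truth as JSON lines {exam_id, slice_index, center, radius_px, kind}."""
    with Path(path).open("w") as fh:
        for e in entries:
            fh.write(
                json.dumps(
                    {
                        "exam_id": e.exam_id,
                        "slice_index": e.slice_index,
                        "center": [e.center[0], e.center[1]],
                        "radius_px": e.radius_px,
                        "kind": e.kind,
                    }
                )
                + "\n"
            )


def read_truth(path, kinds: Optional[Sequence[str]] = ("nodule",)) -> List[TruthEntry]:
    """Read JSON-lines ground truth; by default only nodule entries."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        obj = json.loads(line)
        kind = obj.get("kind", "nodule")
        if kinds is not None and kind not in kinds:
            continue
        out.append(
            TruthEntry(
                exam_id=str(obj.get("exam_id", "")),
                slice_index=int(obj["slice_index"]),
                center=(float(obj["center"][0]), float(obj["center"][1])),
                radius_px=float(obj.get("radius_px", 0.0)),
                kind=kind,
            )
        )
    return out
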