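"""End-to-end orchestration of the detection pipeline.

Per slice: lung segmentation, then candidate detection; per exam: the
across-slice consistency bits, the six-element feature vectors, and the SVM
classification.  Everything is deterministic given the inputs and the
configuration, and every per-slice threshold choice (lambda, tau, source) is
recorded so a run can be audited.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .candidates import CandidateDetector, CandidateRegion
from .errors import ConfigError, InputError
from .features import (
    NODULE,
    NON_NODULE,
    FeatureVector,
    LabeledExample,
    NoduleClassifier,
    assign_consistency,
    build_feature_vector,
    classify_candidates,
    train_classifier,
)
from .io import SliceStack, load_series
from .metrics import (
    ConfusionCounts,
    MetricReport,
    TruthEntry,
    compute_metrics,
    match_detections,
    read_truth,
)
from .segmentation import LungSegmenter, SegmentationResult

__all__ = [
    "RunConfig",
    "Detection",
    "ExamResult",
    "process_stack",
    "run_stack",
    "run_exam",
    "build_training_examples",
    "evaluate_results",
]


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their default values.

    Defaults follow the method's stated settings where one exists: histogram
    step kappa = 5, region-growing intensity distance 0.18, consistency
    half-window k = 1 (window of size 3), 3x3 median filter, F-score
    beta = 0.5.
    """

    kappa: int = 5
    smooth_window: int = 1
    min_area: int = 50
    dilation_radius: int = 2
    connectivity: int = 2
    fill_holes: bool = True
    median_size: int = 3
    circ_min: float = 0.6
    min_candidate_area: int = 9
    max_intensity_distance: float = 0.18
    k: int = 1
    match_radius: Optional[float] = None  # None = max(3, eq. diameter / 2)
    consistency_mode: str = "feature"  # feature | filter | both
    svm_c: float = 1.0
    svm_class_weight: Optional[str] = None
    random_state: int = 0
    beta: float = 0.5
    eval_match_radius: float = 5.0

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a config from a flat YAML/JSON mapping; unknown keys are errors."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def updated(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def segmenter(self) -> LungSegmenter:
        return LungSegmenter(
            kappa=self.kappa,
            smooth_window=self.smooth_window,
            min_area=self.min_area,
            dilation_radius=self.dilation_radius,
            connectivity=self.connectivity,
            fill_holes=self.fill_holes,
            median_size=self.median_size,
        )

    def detector(self) -> CandidateDetector:
        return CandidateDetector(
            circ_min=self.circ_min,
            min_candidate_area=self.min_candidate_area,
            max_distance=self.max_intensity_distance,
        )


@dataclass
class Detection:
    """One classified candidate."""

    slice_index: int
    center: Tuple[float, float]
    area: int
    circularity: float
    equivalent_diameter: float
    features: FeatureVector
    label: str

    def to_json_obj(self) -> dict:
        return {
            "slice_index": self.slice_index,
            "center": [self.center[0], self.center[1]],
            "area": self.area,
            "circularity": self.circularity,
            "equivalent_diameter": self.equivalent_diameter,
            "features": list(self.features.as_array()),
            "label": self.label,
        }


@dataclass
class ExamResult:
    """All per-exam outputs: classified candidates and threshold provenance."""

    exam_id: str
    n_slices: int
    detections: List[Detection]
    thresholds: List[dict]  # per slice: slice_index, lambda, tau, lambda_source

    def positives(self) -> List[Detection]:
        return [d for d in self.detections if d.label == NODULE]

    def negatives(self) -> List[Detection]:
        return [d for d in self.detections if d.label == NON_NODULE]

    def detections_jsonl(self) -> str:
        return "".join(
            json.dumps(d.to_json_obj(), sort_keys=True) + "\n" for d in self.detections
        )

    def thresholds_jsonl(self) -> str:
        return "".join(json.dumps(t, sort_keys=True) + "\n" for t in self.thresholds)


def process_stack(
    stack: SliceStack, config: RunConfig
) -> Tuple[List[SegmentationResult], Dict[int, List[CandidateRegion]], Dict[int, List[FeatureVector]]]:
    """Segment + detect + featurize one stack (no classification yet).

    Returns the per-slice segmentation results, the candidate regions keyed by
    slice index, and the parallel feature vectors (consistency bits included).
    """
    segmenter = config.segmenter()
    detector = config.detector()
    seg_results: List[SegmentationResult] = []
    regions_by_slice: Dict[int, List[CandidateRegion]] = {}
    images_by_slice: Dict[int, np.ndarray] = {}
    for slc in stack:
        seg = segmenter.transform(slc)
        seg_results.append(seg)
        regions_by_slice[slc.slice_index] = detector.transform(seg)
        images_by_slice[slc.slice_index] = seg.lung_image
    candidates_by_slice = {
        j: [r.candidate for r in regions] for j, regions in regions_by_slice.items()
    }
    t_by_slice = assign_consistency(
        candidates_by_slice, k=config.k, match_radius=config.match_radius
    )
    vectors_by_slice: Dict[int, List[FeatureVector]] = {}
    for j, regions in regions_by_slice.items():
        vectors_by_slice[j] = [
            build_feature_vector(region, t, images_by_slice[j])
            for region, t in zip(regions, t_by_slice[j])
        ]
    return seg_results, regions_by_slice, vectors_by_slice


def run_stack(
    stack: SliceStack, model: NoduleClassifier, config: Optional[RunConfig] = None
) -> ExamResult:
    """Run the full pipeline on an in-memory stack with a trained model."""
    config = config or RunConfig()
    seg_results, regions_by_slice, vectors_by_slice = process_stack(stack, config)
    detections: List[Detection] = []
    for j in sorted(regions_by_slice):
        regions = regions_by_slice[j]
        vectors = vectors_by_slice[j]
        labels = classify_candidates(model, vectors, mode=config.consistency_mode)
        for region, fv, label in zip(regions, vectors, labels):
            detections.append(
                Detection(
                    slice_index=j,
                    center=region.centroid(),
                    area=region.area,
                    circularity=region.candidate.circularity,
                    equivalent_diameter=region.candidate.equivalent_diameter,
                    features=fv,
                    label=label,
                )
            )
    thresholds = [
        {
            "slice_index": seg.slice_index,
            "lambda": seg.thresholds.lambda_bg,
            "tau": seg.thresholds.tau_lung,
            "lambda_source": seg.thresholds.lambda_source,
        }
        for seg in seg_results
    ]
    return ExamResult(
        exam_id=stack.exam_id,
        n_slices=len(stack),
        detections=detections,
        thresholds=thresholds,
    )


def build_training_examples(
    stack: SliceStack,
    truth_entries: Sequence[TruthEntry],
    config: Optional[RunConfig] = None,
) -> List[LabeledExample]:
    """Run segmentation + detection and label candidates against ground truth.

    A candidate is labeled ``nodule`` when its centroid lies within the
    evaluation match radius of a ground-truth nodule center on its slice,
    ``non_nodule`` otherwise.
    """
    config = config or RunConfig()
    _, regions_by_slice, vectors_by_slice = process_stack(stack, config)
    nodule_truth = [e for e in truth_entries if e.kind == "nodule"]
    examples: List[LabeledExample] = []
    for j in sorted(regions_by_slice):
        for region, fv in zip(regions_by_slice[j], vectors_by_slice[j]):
            r0, c0 = region.centroid()
            near = any(
                e.slice_index == j
                and (e.center[0] - r0) ** 2 + (e.center[1] - c0) ** 2
                <= config.eval_match_radius**2
                for e in nodule_truth
            )
            examples.append(
                LabeledExample(
                    features=fv,
                    label=NODULE if near else NON_NODULE,
                    provenance=(stack.exam_id, j, (r0, c0)),
                )
            )
    return examples


def evaluate_results(
    results: Sequence[ExamResult],
    truth_entries: Sequence[TruthEntry],
    config: Optional[RunConfig] = None,
) -> MetricReport:
    """Match predicted nodules of one or more exams to ground truth and score."""
    config = config or RunConfig()
    truth_by_exam: Dict[str, List[TruthEntry]] = {}
    for e in truth_entries:
        if e.kind == "nodule":
            truth_by_exam.setdefault(e.exam_id, []).append(e)
    counts = ConfusionCounts()
    n_images = 0
    for res in results:
        truth = truth_by_exam.get(res.exam_id, [])
        counts = counts + match_detections(
            res.positives(),
            truth,
            negatives=res.negatives(),
            match_radius=config.eval_match_radius,
        )
        n_images += res.n_slices
    return compute_metrics(
        counts,
        beta=config.beta,
        n_images=max(n_images, 1),
        n_exams=max(len(results), 1),
    )


def run_exam(
    exam_dir,
    config: Optional[RunConfig] = None,
    *,
    model: Optional[NoduleClassifier] = None,
    train_on_the_fly: bool = False,
    truth_path=None,
    out_dir=None,
) -> Tuple[ExamResult, Optional[MetricReport]]:
    """Load an exam directory, run the pipeline, optionally evaluate and write.

    A trained model is required unless ``train_on_the_fly`` is set (which
    needs ground truth and fits the SVM on this exam's own candidates — a
    smoke-test mode, not a validation protocol).  When ``out_dir`` is given,
    ``detections.jsonl``, ``thresholds.jsonl`` and (if truth was supplied)
    ``report.json`` are written there.
    """
    config = config or RunConfig()
    stack = load_series(exam_dir)
    truth = None
    if truth_path:
        # the truth file describes this exam: rebind its entries to the
        # opaque exam id the loader assigned
        truth = [replace(e, exam_id=stack.exam_id) for e in read_truth(truth_path)]
    if model is None:
        if not train_on_the_fly:
            raise ConfigError("no trained model supplied (and train_on_the_fly is off)")
        if truth is None:
            raise ConfigError("train_on_the_fly needs ground truth")
        examples = build_training_examples(stack, truth, config)
        model = train_classifier(
            examples,
            C=config.svm_c,
            class_weight=config.svm_class_weight,
            random_state=config.random_state,
        )
    result = run_stack(stack, model, config)
    report = evaluate_results([result], truth, config) if truth is not None else None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "detections.jsonl").write_text(result.detections_jsonl())
        (out_dir / "thresholds.jsonl").write_text(result.thresholds_jsonl())
        if report is not None:
            (out_dir / "report.json").write_text(
                json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
            )
    return result, report
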