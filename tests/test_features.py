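"""Statistical features, consistency bit, and SVM training/classification."""

import math

import numpy as np
import pytest

from lungcad import (
    Candidate,
    CandidateRegion,
    FeatureVector,
    InputError,
    LabeledExample,
    build_feature_vector,
    classify_candidates,
    consistency_feature,
    load_classifier,
    save_classifier,
    stat_features,
    train_classifier,
)


def region_from_values(values):
    """A 1-row region whose pixel intensities are exactly ``values``."""
    values = list(values)
    image = np.array([values], dtype=np.uint8)
    pixels = [(0, c) for c in range(len(values))]
    cand = Candidate(center=(0.0, 0.0), slice_index=1, equivalent_diameter=2.0, circularity=1.0)
    return CandidateRegion(pixels=np.array(pixels), candidate=cand), image


def make_candidate(center, slice_index, diameter=6.0):
    return Candidate(
        center=center, slice_index=slice_index, equivalent_diameter=diameter, circularity=0.9
    )


# ------------------------------------------------------------- statistics


def test_stat_features_simple_triplet():
    region, image = region_from_values([1, 2, 3])
    mean, median, mode, var, std = stat_features(region, image)
    assert mean == 2 and median == 2
    assert var == pytest.approx(2 / 3)
    assert std == pytest.approx(math.sqrt(2 / 3))
    assert mode == 1  # three-way tie broken toward the smallest value


def test_stat_features_constant_region():
    region, image = region_from_values([7] * 5)
    assert stat_features(region, image) == (7.0, 7.0, 7.0, 0.0, 0.0)


def test_stat_features_even_count_median_and_mode():
    region, image = region_from_values([2, 2, 3, 9])
    mean, median, mode, var, std = stat_features(region, image)
    assert mean == 4.0
    assert median == 2.5  # midpoint of the two central values
    assert mode == 2.0


def test_stat_features_empty_region_rejected():
    with pytest.raises(InputError):
        CandidateRegion(
            pixels=np.empty((0, 2)),
            candidate=make_candidate((0.0, 0.0), 1),
        )


# ---------------------------------------------------------- feature vector


def test_build_feature_vector_order_and_length():
    region, image = region_from_values([7] * 4)
    fv = build_feature_vector(region, 1, image)
    np.testing.assert_allclose(fv.as_array(), [7, 7, 7, 0, 0, 1])
    assert len(fv.as_array()) == 6


def test_feature_vector_coherence_enforced():
    with pytest.raises(InputError):
        FeatureVector(mean=1, median=1, mode=1, variance=4.0, std=1.0, consistency=0)
    with pytest.raises(InputError):
        FeatureVector(mean=1, median=1, mode=1, variance=0.0, std=0.0, consistency=2)


# ------------------------------------------------------------- consistency


def test_consistency_matches_adjacent_slices_scenario():
    # four candidates on slice 2; only one re-occurs in slices 1 and 3
    consistent = make_candidate((50.0, 50.0), 2)
    others = [
        make_candidate((80.0, 20.0), 2),
        make_candidate((20.0, 80.0), 2),
        make_candidate((70.0, 70.0), 2),
    ]
    by_slice = {
        1: [make_candidate((50.0, 51.0), 1)],
        2: [consistent, *others],
        3: [make_candidate((49.0, 50.0), 3)],
    }
    assert consistency_feature(consistent, by_slice, k=1) == 1
    for cand in others:
        assert consistency_feature(cand, by_slice, k=1) == 0


def test_consistency_single_slice_stack_is_zero():
    cand = make_candidate((10.0, 10.0), 1)
    assert consistency_feature(cand, {1: [cand]}, k=1) == 0


def test_consistency_inclusive_boundary():
    cand = make_candidate((10.0, 10.0), 2, diameter=6.0)  # radius = max(3, 3) = 3
    neighbor = make_candidate((10.0, 13.0), 3)  # distance exactly 3
    assert consistency_feature(cand, {3: [neighbor]}, k=1) == 1
    far = make_candidate((10.0, 13.001), 3)
    assert consistency_feature(cand, {3: [far]}, k=1) == 0


def test_consistency_window_excludes_distant_slices():
    cand = make_candidate((10.0, 10.0), 5)
    neighbor = make_candidate((10.0, 10.0), 8)  # outside j +/- 1
    assert consistency_feature(cand, {8: [neighbor]}, k=1) == 0
    assert consistency_feature(cand, {8: [neighbor]}, k=3) == 1


# ------------------------------------------------------------------- SVM


def toy_examples(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_per_class):
        # nodules: bright, tight, consistent
        v = float(rng.uniform(0, 4))
        out.append(
            LabeledExample(
                features=FeatureVector(
                    mean=float(rng.uniform(200, 215)),
                    median=float(rng.uniform(200, 215)),
                    mode=float(rng.uniform(200, 215)),
                    variance=v,
                    std=math.sqrt(v),
                    consistency=1,
                ),
                label="nodule",
            )
        )
        # vessels: dimmer, wider spread, inconsistent
        v = float(rng.uniform(200, 500))
        out.append(
            LabeledExample(
                features=FeatureVector(
                    mean=float(rng.uniform(120, 160)),
                    median=float(rng.uniform(120, 160)),
                    mode=float(rng.uniform(120, 160)),
                    variance=v,
                    std=math.sqrt(v),
                    consistency=0,
                ),
                label="non_nodule",
            )
        )
    return out


def test_training_separable_set_perfectly():
    examples = toy_examples()
    model = train_classifier(examples)
    X = [ex.features for ex in examples]
    pred = model.predict(X)
    assert (pred == np.array([ex.label for ex in examples])).all()


def test_prediction_deterministic():
    examples = toy_examples()
    model = train_classifier(examples)
    X = [ex.features for ex in examples]
    np.testing.assert_array_equal(model.predict(X), model.predict(X))


def test_single_class_training_rejected():
    examples = [ex for ex in toy_examples() if ex.label == "nodule"]
    with pytest.raises(InputError):
        train_classifier(examples)


def test_classification_order_invariant():
    examples = toy_examples()
    model = train_classifier(examples)
    vectors = [ex.features for ex in examples]
    labels = classify_candidates(model, vectors)
    rng = np.random.default_rng(3)
    perm = rng.permutation(len(vectors))
    shuffled = classify_candidates(model, [vectors[i] for i in perm])
    assert [labels[i] for i in perm] == shuffled


def test_filter_mode_drops_inconsistent():
    examples = toy_examples()
    model = train_classifier(examples)
    inconsistent_bright = FeatureVector(
        mean=210, median=210, mode=210, variance=1.0, std=1.0, consistency=0
    )
    assert classify_candidates(model, [inconsistent_bright], mode="filter") == ["non_nodule"]
    assert classify_candidates(model, [inconsistent_bright], mode="both") == ["non_nodule"]


def test_both_mode_composes_filter_and_feature():
    examples = toy_examples()
    model = train_classifier(examples)
    rng = np.random.default_rng(11)
    vectors = []
    for _ in range(30):
        v = float(rng.uniform(0, 400))
        vectors.append(
            FeatureVector(
                mean=float(rng.uniform(100, 220)),
                median=float(rng.uniform(100, 220)),
                mode=float(rng.uniform(100, 220)),
                variance=v,
                std=math.sqrt(v),
                consistency=int(rng.integers(0, 2)),
            )
        )
    both = classify_candidates(model, vectors, mode="both")
    feature = classify_candidates(model, vectors, mode="feature")
    for fv, b, f in zip(vectors, both, feature):
        assert b == ("non_nodule" if fv.consistency == 0 else f)


def test_unknown_mode_rejected():
    model = train_classifier(toy_examples())
    with pytest.raises(InputError):
        classify_candidates(model, [], mode="bogus")


def test_model_persistence_roundtrip(tmp_path):
    examples = toy_examples()
    model = train_classifier(examples)
    path = tmp_path / "model.json"
    save_classifier(model, path)
    loaded = load_classifier(path)
    X = [ex.features for ex in examples]
    np.testing.assert_array_equal(model.predict(X), loaded.predict(X))
    np.testing.assert_array_equal(model.decision_function(X), loaded.decision_function(X))
    np.testing.assert_array_equal(model.coef_, loaded.coef_)
    np.testing.assert_array_equal(model.center_, loaded.center_)


def test_sklearn_get_set_params():
    from lungcad import NoduleClassifier

    model = NoduleClassifier(C=2.0)
    assert model.get_params()["C"] == 2.0
    model.set_params(C=0.5)
    assert model.C == 0.5
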