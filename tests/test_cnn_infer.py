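"""Differentiability-test machinery: datasets, splits, augmentation,
training contract, aggregation and the decision rule."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from neuroseason import cnn_infer
from neuroseason.cnn_infer import (
    AugmentationPolicy,
    CNNClassifier,
    DifferentiabilityTest,
    ModelConfig,
    PairedDataset,
    augment,
    build_control_dataset,
    build_model,
    build_pairwise_dataset,
    decide,
    make_splits,
    summarize,
    train_and_validate,
)
from neuroseason.synthgen import NeuropilImage


def _const_image(value, animal_id, shape=(40, 40), kind="lamina", side=1):
    return NeuropilImage(
        pixels=np.full(shape, float(value), dtype=np.float32),
        mask=np.ones(shape, dtype=bool),
        animal_id=animal_id, cohort="A", kind=kind, side_index=side,
    )


def _cohort(value, n, prefix, **kw):
    return [_const_image(value, f"{prefix}{i:02d}", **kw) for i in range(n)]


@pytest.fixture(scope="module")
def separable_dataset():
    """Two classes of constant images (means 60 vs 200): a threshold on the
    image mean classifies them perfectly, so a trained CNN must too."""
    return build_pairwise_dataset(_cohort(60, 20, "a"), _cohort(200, 20, "b"), "AB")


# ---------------------------------------------------------------------------
# dataset construction


def test_pairwise_counts_and_labels():
    ds = build_pairwise_dataset(_cohort(10, 30, "a"), _cohort(20, 34, "b"), "AH")
    assert len(ds) == 64
    assert (ds.labels == 0).sum() == 30
    assert (ds.labels == 1).sum() == 34
    assert ds.dataset_tag == "AH" and not ds.is_control


def test_pairwise_rejects_mixed_kinds():
    lam = _cohort(10, 4, "a", shape=(20, 20), kind="lamina")
    lob = _cohort(10, 4, "b", shape=(20, 20), kind="lobula")
    with pytest.raises(ValueError, match="kind"):
        build_pairwise_dataset(lam, lob, "XY")


def test_pairwise_rejects_empty_cohort():
    with pytest.raises(ValueError, match="non-empty"):
        build_pairwise_dataset([], _cohort(10, 4, "b"), "XY")


def test_control_balanced_halves():
    ds = build_control_dataset(_cohort(5, 30, "a"), "AA", seed=0)
    assert ds.is_control
    assert (ds.labels == 0).sum() == 15 and (ds.labels == 1).sum() == 15


def test_control_odd_n_larger_half_label_zero():
    ds = build_control_dataset(_cohort(5, 31, "a"), "AA", seed=0)
    assert (ds.labels == 0).sum() == 16
    assert (ds.labels == 1).sum() == 15


def test_control_seed_determinism():
    imgs = _cohort(5, 20, "a")
    l1 = build_control_dataset(imgs, "AA", seed=7).labels
    l2 = build_control_dataset(imgs, "AA", seed=7).labels
    l3 = build_control_dataset(imgs, "AA", seed=8).labels
    assert np.array_equal(l1, l2)
    assert not np.array_equal(l1, l3)


def test_control_too_small_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        build_control_dataset(_cohort(5, 3, "a"), "AA", seed=0)


# ---------------------------------------------------------------------------
# splits


def test_split_sizes_and_disjointness():
    ds = build_pairwise_dataset(_cohort(1, 30, "a"), _cohort(2, 30, "b"), "AB")
    plan = make_splits(ds, n_splits=10, validation_fraction=0.2, seed=0)
    for train, val in plan.splits:
        assert len(val) == 12
        assert not set(train) & set(val)
        assert sorted(np.r_[train, val].tolist()) == list(range(60))


def test_split_stratification_exhaustive_n20():
    ds = build_pairwise_dataset(_cohort(1, 12, "a"), _cohort(2, 8, "b"), "AB")
    plan = make_splits(ds, n_splits=25, validation_fraction=0.25, seed=1)
    for _, val in plan.splits:
        n1 = ds.labels[val].sum()
        # overall class-1 share is 0.4 -> 2 of 5 validation images, within 1
        assert abs(n1 - 0.4 * len(val)) <= 1
        assert 0 < n1 < len(val)


def test_grouped_split_keeps_animals_together():
    imgs = []
    for i in range(10):
        for side in (1, 2):
            imgs.append(_const_image(1, f"a{i:02d}", side=side))
    ds = build_control_dataset(imgs, "AA", seed=0)
    plan = make_splits(ds, n_splits=5, validation_fraction=0.3, seed=2,
                       group_by_animal=True)
    groups = ds.groups()
    for train, val in plan.splits:
        assert not set(groups[train]) & set(groups[val])


def test_split_invalid_fraction():
    ds = build_pairwise_dataset(_cohort(1, 5, "a"), _cohort(2, 5, "b"), "AB")
    with pytest.raises(ValueError):
        make_splits(ds, n_splits=2, validation_fraction=1.2, seed=0)


# ---------------------------------------------------------------------------
# augmentation


class _StubRng:
    """Deterministic stand-in recording the uniform bounds requested."""

    def __init__(self, uniform_value=0.0, random_value=0.0):
        self.uniform_calls = []
        self._u, self._r = uniform_value, random_value

    def uniform(self, lo, hi):
        self.uniform_calls.append((lo, hi))
        return self._u

    def random(self):
        return self._r


def test_augment_identity_policy(toy_image):
    policy = AugmentationPolicy(rotation_range_deg=0.0, horizontal_flip=False)
    out = augment(toy_image.pixels, policy, np.random.default_rng(0))
    assert np.array_equal(out, toy_image.pixels)


def test_augment_flip_is_involution(toy_image):
    policy = AugmentationPolicy(rotation_range_deg=0.0, horizontal_flip=True)
    rng = _StubRng(random_value=0.0)  # < 0.5 -> always flip
    once = augment(toy_image.pixels, policy, rng)
    twice = augment(once, policy, rng)
    assert not np.array_equal(once, toy_image.pixels)
    assert np.array_equal(twice, toy_image.pixels)


def test_augment_rotation_bounds_and_shape(toy_image):
    policy = AugmentationPolicy(rotation_range_deg=5.0, horizontal_flip=False)
    stub = _StubRng(uniform_value=3.0)
    out = augment(toy_image.pixels, policy, stub)
    assert out.shape == toy_image.pixels.shape
    assert stub.uniform_calls == [(-5.0, 5.0)]
    # the sampled angle stays inside the band for any number of draws
    rng = np.random.default_rng(0)
    angles = [rng.uniform(-policy.rotation_range_deg, policy.rotation_range_deg)
              for _ in range(10_000)]
    assert max(np.abs(angles)) <= 5.0


def test_augmentation_policy_validation():
    with pytest.raises(ValueError):
        AugmentationPolicy(rotation_range_deg=-1.0)
    with pytest.raises(ValueError):
        AugmentationPolicy(expansion=0)


# ---------------------------------------------------------------------------
# model + training


def test_model_outputs_are_probabilities():
    model = build_model(ModelConfig(conv_blocks=((4, 3), (8, 3))), (30, 30), seed=0)
    x = np.random.default_rng(1).random((3, 30, 30, 1)).astype(np.float32)
    p = model.predict_proba(x)
    assert p.shape == (3, 2)
    assert np.allclose(p.sum(axis=1), 1.0)


def test_model_rejects_vanishing_input():
    with pytest.raises(ValueError, match="too small"):
        build_model(ModelConfig(), (10, 6), seed=0)  # 3 blocks exhaust 6 cols


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_outputs=3)
    with pytest.raises(ValueError):
        ModelConfig(epochs=0)


def test_trace_length_equals_epochs(separable_dataset):
    plan = make_splits(separable_dataset, n_splits=1, seed=0)
    cfg = ModelConfig(conv_blocks=((4, 3),), dense_units=8, epochs=7)
    acc, trace = train_and_validate(separable_dataset, plan.splits[0], None,
                                    cfg, seed=0)
    assert len(trace) == 7
    assert acc == trace[-1]


def test_separable_classes_reach_perfect_validation(separable_dataset):
    """A mean threshold separates the classes, so the CNN must reach 1.0."""
    plan = make_splits(separable_dataset, n_splits=1, seed=3)
    acc, _ = train_and_validate(separable_dataset, plan.splits[0], None,
                                ModelConfig(epochs=15), seed=1)
    assert acc == 1.0


def test_validation_images_never_enter_training(separable_dataset, monkeypatch):
    plan = make_splits(separable_dataset, n_splits=1, seed=0)
    train_idx, val_idx = plan.splits[0]
    X = separable_dataset.pixel_stack()
    seen = {}
    orig_fit = CNNClassifier.fit

    def spy(self, Xf, yf, validation_data=None):
        seen["train"] = np.asarray(Xf)
        seen["val"] = np.asarray(validation_data[0])
        return orig_fit(self, Xf, yf, validation_data=validation_data)

    monkeypatch.setattr(CNNClassifier, "fit", spy)
    train_and_validate(separable_dataset, plan.splits[0], None,
                       ModelConfig(conv_blocks=((4, 3),), dense_units=4,
                                   epochs=1), seed=0)
    assert np.array_equal(seen["train"], X[train_idx])
    assert np.array_equal(seen["val"], X[val_idx])
    train_means = {round(float(im.mean()), 6) for im in seen["train"]}
    for v in seen["val"]:
        # constant images: membership checkable through the pixel values
        assert np.array_equal(v, X[val_idx][np.abs(X[val_idx] - v).sum((1, 2)).argmin()])
    assert len(seen["train"]) == len(train_idx)


def test_training_divergence_reported():
    """A non-finite loss (here induced by a NaN pixel) is raised explicitly
    rather than silently propagated into the accuracy aggregate."""
    X = np.random.default_rng(0).random((8, 12, 12)).astype(np.float32)
    X[0, 0, 0] = np.nan
    y = np.r_[np.zeros(4, int), np.ones(4, int)]
    cfg = ModelConfig(conv_blocks=((4, 3),), dense_units=4, epochs=2)
    with pytest.raises(cnn_infer.TrainingDivergedError):
        CNNClassifier(config=cfg, random_state=0).fit(X, y)


def test_classifier_sklearn_interface(separable_dataset):
    from sklearn.base import clone

    clf = CNNClassifier(config=ModelConfig(conv_blocks=((4, 3),),
                                           dense_units=4, epochs=2),
                        random_state=5)
    params = clf.get_params()
    assert params["random_state"] == 5
    clone(clf)  # must be cloneable for model selection
    X = separable_dataset.pixel_stack()[:8]
    y = separable_dataset.labels[:8].copy()
    y[4:] = 1
    clf.fit(X, y)
    assert set(clf.predict(X)) <= {0, 1}
    assert clf.predict_proba(X).shape == (8, 2)


# ---------------------------------------------------------------------------
# aggregation + decision


def test_summarize_zero_variance():
    s = summarize(np.full((10, 10), 0.5), dataset_tag="AA")
    assert s.grand_mean == 0.5
    assert s.ci_low == s.ci_high == 0.5
    assert len(s.per_split_mean) == 10


def test_summarize_matches_closed_form_t_interval():
    """Two split means (0.8, 0.9): mean 0.85 and half-width
    t_{0.975,1} * sd / sqrt(2) computed by hand."""
    s = summarize(np.array([[0.8], [0.9]]))
    sd = np.std([0.8, 0.9], ddof=1)
    half = stats.t.ppf(0.975, df=1) * sd / np.sqrt(2)
    assert s.grand_mean == pytest.approx(0.85)
    assert s.ci_low == pytest.approx(0.85 - half)
    assert s.ci_high == pytest.approx(0.85 + half)
    assert half == pytest.approx(12.7062047364 * 0.0707106781 / 1.41421356, rel=1e-6)


def test_summarize_normal_method_and_errors():
    acc = np.array([[0.6, 0.7], [0.8, 0.9], [0.5, 0.6]])
    t_ci = summarize(acc)
    n_ci = summarize(acc, method="normal")
    assert n_ci.ci_low > t_ci.ci_low  # normal interval is narrower
    with pytest.raises(ValueError):
        summarize(np.array([[0.5, 0.6]]))  # single split


def test_decision_rule_strict_boundary():
    s = summarize(np.full((3, 2), 0.7), dataset_tag="XY")
    s_sig = dataclasses.replace(s, ci_low=0.51)
    s_not = dataclasses.replace(s, ci_low=0.50)
    assert decide(s_sig).significant
    assert not decide(s_not).significant


def test_differentiability_test_reproducible(separable_dataset):
    kw = dict(
        n_splits=2, runs_per_split=1,
        config=ModelConfig(conv_blocks=((4, 3),), dense_units=4, epochs=2),
        augmentation=AugmentationPolicy(expansion=2),
        random_state=11,
    )
    t1 = DifferentiabilityTest(**kw).fit(separable_dataset)
    t2 = DifferentiabilityTest(**kw).fit(separable_dataset)
    assert np.array_equal(t1.accuracies_, t2.accuracies_)
    assert np.array_equal(t1.traces_, t2.traces_)
    assert t1.summary_.grand_mean == t2.summary_.grand_mean
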