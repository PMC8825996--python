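"""Classifier-based differentiability testing of two image cohorts.

The inference logic: if a convolutional network can classify held-out images
from two cohorts better than chance, the cohorts' image distributions differ.
The protocol mirrors common practice for very small image datasets —

* pairwise datasets (cohort X vs cohort Y) and matched *control* datasets
  (one cohort arbitrarily halved and relabelled, carrying no signal),
* repeated stratified random train/validation splits (default 10),
* per-epoch augmentation of the training images only (rotation within ±5°,
  horizontal flips),
* a small conv/pool/dropout/dense/softmax network trained with Adam on
  cross-entropy for a fixed number of epochs (default 50), re-initialized
  for each of several runs per split (default 10),
* a 95% t-interval over the split-mean validation accuracies, and the
  decision rule "differentiable" iff the interval's lower bound strictly
  exceeds 50%.

`CNNClassifier` and `DifferentiabilityTest` are scikit-learn style
estimators; the module-level functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from . import nn
from .synthgen import NeuropilImage, NeuropilKind

__all__ = [
    "PairedDataset",
    "SplitPlan",
    "AugmentationPolicy",
    "ModelConfig",
    "AccuracySummary",
    "DecisionOutcome",
    "TrainingDivergedError",
    "CNNClassifier",
    "DifferentiabilityTest",
    "build_pairwise_dataset",
    "build_control_dataset",
    "make_splits",
    "augment",
    "build_model",
    "train_and_validate",
    "summarize",
    "decide",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class PairedDataset:
    """A labelled two-class image collection of one neuropil kind."""

    images: list[NeuropilImage]
    labels: np.ndarray
    kind: NeuropilKind
    dataset_tag: str
    is_control: bool = False

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be 0/1")
        if (self.labels == 0).sum() == 0 or (self.labels == 1).sum() == 0:
            raise ValueError("both classes must be non-empty")
        self.kind = NeuropilKind(self.kind)
        shapes = {im.pixels.shape for im in self.images}
        if len(shapes) != 1:
            raise ValueError(f"images have mixed shapes: {shapes}")
        kinds = {im.kind for im in self.images}
        if kinds != {self.kind}:
            raise ValueError(f"images have mixed kinds: {kinds}")

    def __len__(self) -> int:
        return len(self.images)

    def pixel_stack(self) -> np.ndarray:
        """(N, H, W) float32 stack scaled to [0, 1]."""
        return np.stack([im.pixels for im in self.images]).astype(np.float32) / 255.0

    def groups(self) -> np.ndarray:
        return np.asarray([im.animal_id for im in self.images])


@dataclass
class SplitPlan:
    """Randomized train/validation partitions of one dataset."""

    n_splits: int
    splits: list[tuple[np.ndarray, np.ndarray]]
    validation_fraction: float
    seed: int

    def __post_init__(self):
        if len(self.splits) != self.n_splits:
            raise ValueError("n_splits does not match the split list")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Label-preserving training-set transforms: bounded rotation and
    horizontal flips, imitating slight deviations during imaging.

    ``expansion`` is how many independently deformed copies of each training
    image the network sees per epoch — augmentation enlarges the training
    set rather than merely perturbing it, which matters for convergence
    when the raw training set yields only a handful of optimizer updates
    per epoch.  Validation images are never augmented.
    """

    rotation_range_deg: float = 5.0
    horizontal_flip: bool = True
    expansion: int = 4

    def __post_init__(self):
        if self.rotation_range_deg < 0:
            raise ValueError("rotation_range_deg must be >= 0")
        if self.expansion < 1:
            raise ValueError("expansion must be >= 1")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters of the small CNN.

    Defaults: three conv blocks (32/64/128 filters, 3x3 kernels, each
    followed by ReLU and 2x2 max-pool), dropout 0.25 after the last block,
    a 128-unit dense layer with ReLU, dropout 0.5, and a 2-way softmax
    output; 50 epochs of Adam (lr 1e-3) on cross-entropy, batch size 16.
    """

    conv_blocks: tuple[tuple[int, int], ...] = ((32, 3), (64, 3), (128, 3))
    pool_size: int = 2
    dropout_rates: tuple[float, float] = (0.25, 0.5)
    dense_units: int = 128
    n_outputs: int = 2
    epochs: int = 50
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    batch_size: int = 16
    learning_rate: float = 1e-3

    def __post_init__(self):
        if self.n_outputs != 2:
            raise ValueError("the differentiability test is two-class only")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam" or self.loss != "cross_entropy":
            raise ValueError("only adam + cross_entropy are supported")


@dataclass
class AccuracySummary:
    """Per-split mean validation accuracies and their 95% CI."""

    dataset_tag: str
    per_split_mean: np.ndarray
    grand_mean: float
    ci_low: float
    ci_high: float
    runs_per_split: int
    confidence: float = 0.95

    def to_dict(self) -> dict:
        return {
            "dataset_tag": self.dataset_tag,
            "per_split_mean": [float(v) for v in self.per_split_mean],
            "grand_mean": self.grand_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "runs_per_split": self.runs_per_split,
            "confidence": self.confidence,
        }


@dataclass
class DecisionOutcome:
    """Above-chance verdict: significant iff ci_low strictly exceeds 0.5."""

    dataset_tag: str
    significant: bool
    threshold: float = 0.5

    def to_dict(self) -> dict:
        return {
            "dataset_tag": self.dataset_tag,
            "significant": bool(self.significant),
            "threshold": self.threshold,
        }


# ---------------------------------------------------------------------------
# Dataset construction


def build_pairwise_dataset(
    cohort_x: Sequence[NeuropilImage],
    cohort_y: Sequence[NeuropilImage],
    tag: str,
) -> PairedDataset:
    """Two-cohort dataset: label 0 for cohort_x, 1 for cohort_y."""
    if not cohort_x or not cohort_y:
        raise ValueError("both cohorts must be non-empty")
    images = list(cohort_x) + list(cohort_y)
    labels = np.r_[np.zeros(len(cohort_x), int), np.ones(len(cohort_y), int)]
    kind = images[0].kind
    return PairedDataset(images, labels, kind, tag, is_control=False)


def build_control_dataset(
    cohort: Sequence[NeuropilImage], tag: str, seed: int
) -> PairedDataset:
    """Null-control dataset: one cohort randomly halved and relabelled.

    Labels carry no information, so validation accuracy has chance level as
    its expected value.  For odd n the larger half receives label 0.
    """
    n = len(cohort)
    if n < 4:
        raise ValueError("control dataset needs at least 4 images")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = np.ones(n, dtype=int)
    labels[order[: (n + 1) // 2]] = 0
    return PairedDataset(list(cohort), labels, cohort[0].kind, tag, is_control=True)


def make_splits(
    dataset: PairedDataset,
    n_splits: int = 10,
    validation_fraction: float = 0.2,
    seed: int = 0,
    group_by_animal: bool = False,
) -> SplitPlan:
    """Repeated stratified random train/validation partitions.

    With ``group_by_animal`` the two neuropils of one animal always land on
    the same side of the split (guards against identity leakage when an
    animal contributes multiple images).
    """
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    y = dataset.labels
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    if group_by_animal:
        rng = np.random.default_rng(seed)
        groups = dataset.groups()
        unique_groups = np.unique(groups)
        n_val_groups = max(1, int(round(validation_fraction * len(unique_groups))))
        for _ in range(n_splits):
            # whole animals move to validation together; redraw until both
            # classes appear on both sides (an animal's images may carry
            # different labels in control datasets)
            for _attempt in range(200):
                chosen = rng.choice(unique_groups, size=n_val_groups,
                                    replace=False)
                val_mask = np.isin(groups, chosen)
                train = np.flatnonzero(~val_mask)
                val = np.flatnonzero(val_mask)
                if (len(np.unique(y[train])) == 2
                        and len(np.unique(y[val])) == 2):
                    break
            else:
                raise ValueError(
                    "could not build a grouped split with both classes on "
                    "both sides; adjust validation_fraction"
                )
            _check_split(y, train, val)
            splits.append((train, val))
    else:
        sss = StratifiedShuffleSplit(
            n_splits=n_splits, test_size=validation_fraction, random_state=seed
        )
        for train, val in sss.split(np.zeros(len(y)), y):
            _check_split(y, train, val)
            splits.append((np.sort(train), np.sort(val)))
    return SplitPlan(n_splits, splits, validation_fraction, seed)


def _check_split(y, train, val):
    if set(train) & set(val):
        raise ValueError("train and validation overlap")
    for part, name in ((train, "train"), (val, "validation")):
        if len(np.unique(y[part])) < 2:
            raise ValueError(f"{name} set lost a class; adjust validation_fraction")


# ---------------------------------------------------------------------------
# Augmentation


def augment(
    image: np.ndarray,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
) -> np.ndarray:
    """One augmented copy: rotation uniform in ±rotation_range_deg (bilinear,
    nearest-border fill), then a horizontal flip with probability 1/2."""
    out = image
    if policy.rotation_range_deg > 0:
        angle = rng.uniform(-policy.rotation_range_deg, policy.rotation_range_deg)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="nearest")
    if policy.horizontal_flip and rng.random() < 0.5:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


# ---------------------------------------------------------------------------
# Model


def build_model(
    config: ModelConfig,
    input_shape: tuple[int, int],
    seed: int | np.random.SeedSequence = 0,
) -> nn.Sequential:
    """Assemble the conv/pool/dropout/dense/softmax stack for a given
    single-channel input shape; raises if pooling exhausts the spatial size."""
    rng = np.random.default_rng(seed)
    h, w = input_shape
    layers: list[nn.Layer] = []
    channels = 1
    for filters, ksize in config.conv_blocks:
        h, w = h - ksize + 1, w - ksize + 1
        if h < 1 or w < 1:
            raise ValueError(
                f"input too small: spatial size vanished before the "
                f"{filters}-filter block"
            )
        layers += [nn.Conv2D(channels, filters, ksize, rng), nn.ReLU()]
        channels = filters
        h, w = h // config.pool_size, w // config.pool_size
        if h < 1 or w < 1:
            raise ValueError("input too small for the configured pooling")
        layers.append(nn.MaxPool2D(config.pool_size))
    layers.append(nn.Dropout(config.dropout_rates[0], rng))
    layers.append(nn.Flatten())
    layers.append(nn.Dense(h * w * channels, config.dense_units, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Dropout(config.dropout_rates[1], rng))
    layers.append(nn.Dense(config.dense_units, config.n_outputs, rng))
    return nn.Sequential(layers)


class CNNClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style wrapper around the small CNN.

    Parameters
    ----------
    config : ModelConfig or None
        Architecture/training hyperparameters (None = defaults).
    augmentation : AugmentationPolicy or None
        Applied on the fly to each training batch, never to validation data.
    random_state : int
        Seeds weight init, dropout, shuffling and augmentation.

    Attributes
    ----------
    model_ : nn.Sequential
        The trained network.
    classes_ : ndarray
        Sorted class labels.
    history_ : dict
        Per-epoch "loss" and (if validation data was supplied)
        "val_accuracy" — the 50-point trace of the full protocol.
    """

    def __init__(self, config: ModelConfig | None = None,
                 augmentation: AugmentationPolicy | None = None,
                 random_state: int = 0):
        self.config = config
        self.augmentation = augmentation
        self.random_state = random_state

    def fit(self, X, y, validation_data=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, rows, cols)")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("exactly two classes required")
        cfg = self.config or ModelConfig()
        ss = np.random.SeedSequence(self.random_state)
        init_ss, aug_ss, shuf_ss = ss.spawn(3)
        self.model_ = build_model(cfg, X.shape[1:], init_ss)
        opt = nn.Adam(self.model_.layers, learning_rate=cfg.learning_rate)
        aug_rng = np.random.default_rng(aug_ss)
        shuf_rng = np.random.default_rng(shuf_ss)

        val = None
        if validation_data is not None:
            Xv = np.asarray(validation_data[0], dtype=np.float32)
            yv = np.searchsorted(self.classes_, np.asarray(validation_data[1]))
            val = (Xv, yv)

        n = len(X)
        expansion = 1 if self.augmentation is None else self.augmentation.expansion
        pool = np.repeat(np.arange(n), expansion)
        history: dict[str, list[float]] = {"loss": []}
        if val is not None:
            history["val_accuracy"] = []
        for _ in range(cfg.epochs):
            order = shuf_rng.permutation(pool)
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb = X[idx]
                if self.augmentation is not None:
                    xb = np.stack(
                        [augment(im, self.augmentation, aug_rng) for im in xb]
                    )
                loss = self.model_.loss_and_grad(xb[..., None], y_idx[idx])
                if not np.isfinite(loss):
                    raise TrainingDivergedError(
                        f"non-finite training loss ({loss}) at step {opt.t}"
                    )
                opt.step()
                epoch_loss += loss * len(idx)
            history["loss"].append(epoch_loss / len(order))
            if val is not None:
                acc = float(np.mean(self._predict_idx(val[0]) == val[1]))
                history["val_accuracy"].append(acc)
        self.history_ = history
        return self

    def _predict_idx(self, X):
        proba = self.model_.predict_proba(
            np.asarray(X, dtype=np.float32)[..., None]
        )
        return proba.argmax(axis=1)

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(np.asarray(X, dtype=np.float32)[..., None])

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.classes_[self._predict_idx(X)]


def train_and_validate(
    dataset: PairedDataset,
    split: tuple[np.ndarray, np.ndarray],
    policy: AugmentationPolicy | None,
    config: ModelConfig | None,
    seed: int,
) -> tuple[float, list[float]]:
    """One run: train a fresh model on the augmented training part, evaluate
    the unaugmented validation part each epoch.  Returns the final-epoch
    validation accuracy and the full per-epoch accuracy trace."""
    train_idx, val_idx = split
    X = dataset.pixel_stack()
    y = dataset.labels
    clf = CNNClassifier(config=config, augmentation=policy, random_state=seed)
    clf.fit(X[train_idx], y[train_idx], validation_data=(X[val_idx], y[val_idx]))
    trace = clf.history_["val_accuracy"]
    return trace[-1], trace


# ---------------------------------------------------------------------------
# Aggregation and decision


def summarize(
    accuracies: np.ndarray,
    confidence: float = 0.95,
    dataset_tag: str = "",
    method: str = "t",
) -> AccuracySummary:
    """Aggregate an (n_splits, runs_per_split) accuracy matrix.

    The CI is computed over the n_splits split means: a t-interval with
    n_splits - 1 degrees of freedom by default, or a normal approximation
    with ``method="normal"``.
    """
    acc = np.atleast_2d(np.asarray(accuracies, dtype=float))
    n_splits, runs = acc.shape
    if n_splits < 2:
        raise ValueError("at least 2 splits are required for a CI")
    split_means = acc.mean(axis=1)
    grand = float(split_means.mean())
    se = float(split_means.std(ddof=1) / np.sqrt(n_splits))
    if method == "t":
        crit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n_splits - 1))
    elif method == "normal":
        crit = float(stats.norm.ppf(0.5 + confidence / 2.0))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    half = crit * se
    return AccuracySummary(
        dataset_tag=dataset_tag,
        per_split_mean=split_means,
        grand_mean=grand,
        ci_low=grand - half,
        ci_high=grand + half,
        runs_per_split=runs,
        confidence=confidence,
    )


def decide(summary: AccuracySummary, threshold: float = 0.5) -> DecisionOutcome:
    """Differentiability verdict: the CI lower bound must strictly exceed
    chance level."""
    return DecisionOutcome(
        dataset_tag=summary.dataset_tag,
        significant=bool(summary.ci_low > threshold),
        threshold=threshold,
    )


class DifferentiabilityTest(BaseEstimator):
    """Classifier two-sample test for a labelled image dataset.

    fit() runs the full protocol — n_splits stratified random splits,
    runs_per_split independently re-initialized trainings per split —
    and stores the accuracy matrix, its summary and the verdict.

    Attributes
    ----------
    accuracies_ : ndarray, (n_splits, runs_per_split)
        Final-epoch validation accuracy of every run.
    traces_ : ndarray, (n_splits, runs_per_split, epochs)
        Per-epoch validation accuracy traces.
    summary_ : AccuracySummary
    decision_ : DecisionOutcome
    split_plan_ : SplitPlan
    """

    def __init__(self, n_splits: int = 10, runs_per_split: int = 10,
                 validation_fraction: float = 0.2,
                 augmentation: AugmentationPolicy | None = AugmentationPolicy(),
                 config: ModelConfig | None = None,
                 group_by_animal: bool = False,
                 confidence: float = 0.95,
                 random_state: int = 0):
        self.n_splits = n_splits
        self.runs_per_split = runs_per_split
        self.validation_fraction = validation_fraction
        self.augmentation = augmentation
        self.config = config
        self.group_by_animal = group_by_animal
        self.confidence = confidence
        self.random_state = random_state

    def fit(self, dataset: PairedDataset, y=None):
        ss = np.random.SeedSequence(self.random_state)
        split_ss, *run_ss = ss.spawn(1 + self.n_splits * self.runs_per_split)
        plan = make_splits(
            dataset,
            n_splits=self.n_splits,
            validation_fraction=self.validation_fraction,
            seed=int(split_ss.generate_state(1)[0] % (2**31 - 1)),
            group_by_animal=self.group_by_animal,
        )
        cfg = self.config or ModelConfig()
        acc = np.empty((self.n_splits, self.runs_per_split))
        traces = np.empty((self.n_splits, self.runs_per_split, cfg.epochs))
        k = 0
        for s, split in enumerate(plan.splits):
            for r in range(self.runs_per_split):
                seed = int(run_ss[k].generate_state(1)[0] % (2**31 - 1))
                a, trace = train_and_validate(
                    dataset, split, self.augmentation, cfg, seed
                )
                acc[s, r] = a
                traces[s, r] = trace
                k += 1
        self.split_plan_ = plan
        self.accuracies_ = acc
        self.traces_ = traces
        self.summary_ = summarize(
            acc, confidence=self.confidence, dataset_tag=dataset.dataset_tag
        )
        self.decision_ = decide(self.summary_)
        return self
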