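"""End-to-end experiment driver: generate → quantify → infer (→ Grad-CAM).

One master seed deterministically derives every stage seed through
``numpy.random.SeedSequence`` spawning, in a fixed documented order:

    SeedSequence(master_seed).spawn(2) -> (generation, inference)
    generation.spawn(n_cohorts)        -> one per cohort (sorted labels)
    inference.spawn(n_datasets)        -> one per dataset tag, in config order

so any sub-stage can be re-run in isolation.  Completed datasets are
checkpointed as JSON in the output directory and skipped on re-run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .cnn_infer import (
    AccuracySummary,
    AugmentationPolicy,
    DecisionOutcome,
    DifferentiabilityTest,
    ModelConfig,
    PairedDataset,
    build_control_dataset,
    build_pairwise_dataset,
    decide,
    summarize,
)
from .quantify import compare_cohorts, correlate_size, quantify_images
from .synthgen import (
    CohortSpec,
    NeuropilImage,
    NeuropilKind,
    cohort_presets,
    generate_cohort,
    plant_effect,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "power_sweep",
    "downscale_images",
    "control_calibration",
    "planted_effect_decision",
    "plot_report",
]

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Configuration of one full differentiability experiment.

    ``scaled_down=True`` swaps in the reduced protocol used for routine
    checks (3 splits × 2 runs, 15 epochs, images downscaled 4×); the full
    protocol is 10 splits × 10 runs × 50 epochs at native resolution.
    """

    kind: str = "lamina"
    cohorts: dict[str, CohortSpec] | None = None
    n_animals: int = 15
    neuropils_per_animal: int = 2
    pairs: tuple[str, ...] = ("AH", "HO", "AO")
    controls: tuple[str, ...] = ("AA", "HH", "OO")
    n_splits: int = 10
    runs_per_split: int = 10
    epochs: int = 50
    validation_fraction: float = 0.2
    downscale: int = 1
    model: ModelConfig | None = None
    augmentation: AugmentationPolicy | None = field(default_factory=AugmentationPolicy)
    group_by_animal: bool = False
    master_seed: int = 0
    out_dir: str | None = None
    scaled_down: bool = False

    SCALED_DOWN = {"n_splits": 3, "runs_per_split": 2, "epochs": 15, "downscale": 4}

    def resolved(self) -> "ExperimentConfig":
        """Config with presets and the scaled-down overrides applied."""
        cfg = self
        if cfg.scaled_down:
            cfg = replace(cfg, scaled_down=False, **self.SCALED_DOWN)
        if cfg.cohorts is None:
            cfg = replace(cfg, cohorts=cohort_presets(cfg.kind))
        needed = {c for tag in cfg.pairs + cfg.controls for c in tag}
        missing = needed - set(cfg.cohorts)
        if missing:
            raise ValueError(f"datasets reference undefined cohorts: {sorted(missing)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohorts" in raw and raw["cohorts"] is not None:
            raw["cohorts"] = {
                label: CohortSpec(label=label, **params)
                for label, params in raw["cohorts"].items()
            }
        if "model" in raw and raw["model"] is not None:
            m = dict(raw["model"])
            if "conv_blocks" in m:
                m["conv_blocks"] = tuple(tuple(b) for b in m["conv_blocks"])
            if "dropout_rates" in m:
                m["dropout_rates"] = tuple(m["dropout_rates"])
            raw["model"] = ModelConfig(**m)
        if "augmentation" in raw and raw["augmentation"] is not None:
            raw["augmentation"] = AugmentationPolicy(**raw["augmentation"])
        for key in ("pairs", "controls"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class ExperimentReport:
    """All artefacts of one experiment, JSON/CSV serializable."""

    config_used: ExperimentConfig
    records: pd.DataFrame
    covariates: pd.DataFrame
    anova: object
    correlation: tuple[float, float]
    summaries: dict[str, AccuracySummary]
    decisions: dict[str, DecisionOutcome]
    traces: dict[str, np.ndarray]
    accuracies: dict[str, np.ndarray]

    def decision_dict(self) -> dict:
        return {
            tag: {
                "grand_mean": self.summaries[tag].grand_mean,
                "ci_low": self.summaries[tag].ci_low,
                "ci_high": self.summaries[tag].ci_high,
                "significant": self.decisions[tag].significant,
            }
            for tag in self.summaries
        }

    def accuracy_table(self) -> pd.DataFrame:
        rows = []
        for tag, acc in self.accuracies.items():
            for s in range(acc.shape[0]):
                for r in range(acc.shape[1]):
                    rows.append(
                        {"dataset_tag": tag, "split": s + 1, "run": r + 1,
                         "accuracy": acc[s, r]}
                    )
        return pd.DataFrame(rows)


def _model_with_epochs(cfg: ExperimentConfig) -> ModelConfig:
    """Model config with the experiment-level epoch count applied."""
    base = cfg.model or ModelConfig()
    return ModelConfig(**{**dataclasses.asdict(base), "epochs": cfg.epochs})


def downscale_images(images: list[NeuropilImage], factor: int) -> list[NeuropilImage]:
    """Bilinear downscale by an integer factor (1 = no-op)."""
    if factor == 1:
        return list(images)
    out = []
    for img in images:
        h, w = img.pixels.shape
        target = (max(1, h // factor), max(1, w // factor))
        pixels = _sk_resize(
            img.pixels.astype(np.float64), target, order=1, mode="edge",
            anti_aliasing=True, preserve_range=True,
        )
        mask = _sk_resize(
            img.mask.astype(np.float64), target, order=0, mode="edge",
            preserve_range=True,
        ) > 0.5
        out.append(replace(img, pixels=np.clip(pixels, 0, 255).astype(np.float32),
                           mask=mask))
    return out


def _dataset_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _build_dataset(tag: str, images_by_cohort: dict[str, list[NeuropilImage]],
                   seed: int) -> PairedDataset:
    a, b = tag[0], tag[1]
    if a == b:
        return build_control_dataset(images_by_cohort[a], tag, seed)
    return build_pairwise_dataset(images_by_cohort[a], images_by_cohort[b], tag)


def run_experiment(config: ExperimentConfig, resume: bool = True) -> ExperimentReport:
    """Run the full generate → quantify → infer pipeline.

    With ``out_dir`` set, per-dataset results are checkpointed as JSON and
    reloaded on re-run (``resume=True``), so a partially failed experiment
    continues where it stopped.  Rerunning a finished experiment with the
    same master seed reproduces the report bit-for-bit.
    """
    cfg = config.resolved()
    gen_ss, infer_ss = np.random.SeedSequence(cfg.master_seed).spawn(2)
    needed = sorted({c for tag in cfg.pairs + cfg.controls for c in tag})
    cohort_ss = dict(zip(needed, gen_ss.spawn(len(needed))))

    images_by_cohort: dict[str, list[NeuropilImage]] = {}
    covariates = []
    for label in needed:
        imgs, cov = generate_cohort(
            cfg.n_animals, cfg.kind, cfg.cohorts[label],
            neuropils_per_animal=cfg.neuropils_per_animal, seed=cohort_ss[label],
        )
        images_by_cohort[label] = imgs
        covariates.append(cov)
    covariates = pd.concat(covariates, ignore_index=True)

    records = quantify_images([im for imgs in images_by_cohort.values() for im in imgs])
    anova = compare_cohorts(records)
    correlation = correlate_size(covariates)

    out_dir = Path(cfg.out_dir) if cfg.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    tags = tuple(cfg.pairs) + tuple(cfg.controls)
    tag_ss = dict(zip(tags, infer_ss.spawn(len(tags))))
    net_images = {
        label: downscale_images(imgs, cfg.downscale)
        for label, imgs in images_by_cohort.items()
    }

    summaries, decisions, traces, accuracies = {}, {}, {}, {}
    for tag in tags:
        ckpt = out_dir / f"dataset_{tag}.json" if out_dir else None
        if ckpt and resume and ckpt.exists():
            logger.info("resuming dataset %s from checkpoint", tag)
            payload = json.loads(ckpt.read_text())
            acc = np.asarray(payload["accuracies"])
            traces[tag] = np.asarray(payload["traces"])
        else:
            seed = _dataset_seed(tag_ss[tag])
            dataset = _build_dataset(tag, net_images, seed)
            test = DifferentiabilityTest(
                n_splits=cfg.n_splits,
                runs_per_split=cfg.runs_per_split,
                validation_fraction=cfg.validation_fraction,
                augmentation=cfg.augmentation,
                config=_model_with_epochs(cfg),
                group_by_animal=cfg.group_by_animal,
                random_state=seed,
            ).fit(dataset)
            acc = test.accuracies_
            traces[tag] = test.traces_
            if ckpt:
                ckpt.write_text(
                    json.dumps(
                        {"accuracies": acc.tolist(),
                         "traces": traces[tag].tolist()}
                    )
                )
        summaries[tag] = summarize(acc, dataset_tag=tag)
        decisions[tag] = decide(summaries[tag])
        accuracies[tag] = acc

    report = ExperimentReport(
        config_used=cfg,
        records=records,
        covariates=covariates,
        anova=anova,
        correlation=correlation,
        summaries=summaries,
        decisions=decisions,
        traces=traces,
        accuracies=accuracies,
    )
    if out_dir:
        _write_report(report, out_dir)
    return report


def _write_report(report: ExperimentReport, out_dir: Path) -> None:
    report.records.to_csv(out_dir / "fluorescence_records.csv", index=False)
    report.covariates.to_csv(out_dir / "covariates.csv", index=False)
    report.accuracy_table().to_csv(out_dir / "run_accuracies.csv", index=False)
    anova = report.anova
    anova_payload = {
        "f_stat": anova.f_stat,
        "p_value": anova.p_value,
        "comparisons": [c.__dict__ for c in anova.comparisons],
    }
    summary_payload = {
        "anova": anova_payload,
        "size_width_correlation": {"r": report.correlation[0],
                                   "p": report.correlation[1]},
        "datasets": {
            tag: {**report.summaries[tag].to_dict(),
                  **report.decisions[tag].to_dict()}
            for tag in report.summaries
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary_payload, indent=2))
    for tag, tr in report.traces.items():
        n_s, n_r, n_e = tr.shape
        frame = pd.DataFrame(
            tr.reshape(n_s * n_r, n_e),
            index=pd.MultiIndex.from_product(
                [range(1, n_s + 1), range(1, n_r + 1)], names=["split", "run"]
            ),
        )
        frame.columns = [f"epoch_{e + 1}" for e in range(n_e)]
        frame.to_csv(out_dir / f"traces_{tag}.csv")


def plot_report(report: ExperimentReport, out_dir: str | Path) -> list[Path]:
    """Render the standard report figures as PNG files.

    Produces a per-cohort strip plot of mean fluorescence, a per-split
    accuracy chart with 95% CI whiskers per dataset, and per-epoch
    validation-accuracy traces.  Returns the written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    rng = np.random.default_rng(0)  # jitter only, cosmetic
    fig, ax = plt.subplots(figsize=(4, 3))
    cohorts = sorted(report.records["cohort"].unique())
    for i, cohort in enumerate(cohorts):
        vals = report.records.loc[report.records["cohort"] == cohort, "mean_rfu"]
        x = i + rng.uniform(-0.12, 0.12, len(vals))
        ax.plot(x, vals, "o", ms=4, alpha=0.7)
        ax.hlines(vals.mean(), i - 0.25, i + 0.25, color="k")
    ax.set_xticks(range(len(cohorts)), cohorts)
    ax.set_ylabel("mean fluorescence (RFU)")
    ax.set_xlabel("cohort")
    fig.tight_layout()
    path = out_dir / "fluorescence_by_cohort.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 3))
    for i, (tag, summ) in enumerate(report.summaries.items()):
        x = i + rng.uniform(-0.12, 0.12, len(summ.per_split_mean))
        ax.plot(x, summ.per_split_mean, "o", ms=4, alpha=0.7)
        ax.hlines(summ.grand_mean, i - 0.25, i + 0.25, color="k")
        ax.vlines(i + 0.3, summ.ci_low, summ.ci_high, color="k", lw=1)
    ax.axhline(0.5, ls=":", color="gray")
    ax.set_xticks(range(len(report.summaries)), list(report.summaries))
    ax.set_ylabel("validation accuracy per split")
    ax.set_xlabel("dataset")
    fig.tight_layout()
    path = out_dir / "accuracy_by_dataset.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5, 3))
    for tag, tr in report.traces.items():
        mean_trace = tr.mean(axis=(0, 1))
        ax.plot(np.arange(1, len(mean_trace) + 1), mean_trace, label=tag)
    ax.axhline(0.5, ls=":", color="gray")
    ax.set_xlabel("epoch")
    ax.set_ylabel("mean validation accuracy")
    ax.legend(fontsize=7)
    fig.tight_layout()
    path = out_dir / "epoch_traces.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    written.append(path)
    return written


def control_calibration(
    replicates: int = 3,
    kind: str | NeuropilKind = "lamina",
    spec: CohortSpec | None = None,
    config: ExperimentConfig | None = None,
    master_seed: int = 0,
) -> list[float]:
    """Null calibration: grand-mean validation accuracy on control datasets.

    Each replicate generates one fresh cohort from a single spec, halves it
    arbitrarily into a control dataset, and runs the split/train/evaluate
    protocol.  Because the labels carry no information, the grand means
    should scatter around 0.5.  Returns one grand mean per replicate.
    """
    cfg = (config or ExperimentConfig(scaled_down=True)).resolved()
    spec = spec or cohort_presets(kind)["A"]
    kind = NeuropilKind(kind)
    means = []
    for ss in np.random.SeedSequence(master_seed).spawn(replicates):
        gen_ss, ctrl_ss, infer_ss = ss.spawn(3)
        imgs, _ = generate_cohort(
            cfg.n_animals, kind, spec,
            neuropils_per_animal=cfg.neuropils_per_animal, seed=gen_ss,
        )
        dataset = build_control_dataset(
            downscale_images(imgs, cfg.downscale),
            tag=f"{spec.label}{spec.label}",
            seed=_dataset_seed(ctrl_ss),
        )
        test = DifferentiabilityTest(
            n_splits=cfg.n_splits,
            runs_per_split=cfg.runs_per_split,
            validation_fraction=cfg.validation_fraction,
            augmentation=cfg.augmentation,
            config=_model_with_epochs(cfg),
            random_state=_dataset_seed(infer_ss),
        ).fit(dataset)
        means.append(test.summary_.grand_mean)
    return means


def planted_effect_decision(
    delta: float = 0.25,
    kind: str | NeuropilKind = "lamina",
    base: CohortSpec | None = None,
    config: ExperimentConfig | None = None,
    master_seed: int = 0,
) -> tuple[AccuracySummary, DecisionOutcome]:
    """Decision rule on a planted mean-intensity effect.

    Generates two cohorts identical except for mean intensity scaled by
    (1 + delta) in the second, builds the pairwise dataset, runs the
    protocol and returns the accuracy summary and the CI-above-chance
    verdict.
    """
    cfg = (config or ExperimentConfig(scaled_down=True)).resolved()
    base = base or cohort_presets(kind)["A"]
    kind = NeuropilKind(kind)
    gen_a, gen_b, infer_ss = np.random.SeedSequence(master_seed).spawn(3)
    imgs_a, _ = generate_cohort(
        cfg.n_animals, kind, replace(base, label="X"),
        neuropils_per_animal=cfg.neuropils_per_animal, seed=gen_a,
    )
    imgs_b, _ = generate_cohort(
        cfg.n_animals, kind, plant_effect(base, delta_intensity=delta, label="Y"),
        neuropils_per_animal=cfg.neuropils_per_animal, seed=gen_b,
    )
    dataset = build_pairwise_dataset(
        downscale_images(imgs_a, cfg.downscale),
        downscale_images(imgs_b, cfg.downscale),
        tag="XY",
    )
    test = DifferentiabilityTest(
        n_splits=cfg.n_splits,
        runs_per_split=cfg.runs_per_split,
        validation_fraction=cfg.validation_fraction,
        augmentation=cfg.augmentation,
        config=_model_with_epochs(cfg),
        random_state=_dataset_seed(infer_ss),
    ).fit(dataset)
    return test.summary_, test.decision_


def power_sweep(
    base_spec: CohortSpec,
    deltas: tuple[float, ...] = (0.0, 0.1, 0.25, 0.5),
    replicates: int = 3,
    kind: str | NeuropilKind = "lamina",
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Detection power of the decision rule across planted intensity effects.

    For each delta and replicate, two cohorts are freshly generated — the
    base spec and the base spec with mean intensity scaled by (1 + delta) —
    and the full decision procedure runs on their pairwise dataset.  Seeds
    are paired: replicate r reuses the same generation and inference seeds
    across all deltas, so power comparisons between deltas are low-variance.
    Returns one row per (delta, replicate) plus detection rates via groupby.
    """
    if 0.0 not in deltas:
        raise ValueError("delta grid must include 0 (the null point)")
    cfg = (config or ExperimentConfig(scaled_down=True)).resolved()
    kind = NeuropilKind(kind)
    rows = []
    rep_ss = np.random.SeedSequence(cfg.master_seed).spawn(replicates)
    for r, ss in enumerate(rep_ss):
        gen_a, gen_b, infer_seed = (_dataset_seed(s) for s in ss.spawn(3))
        for delta in deltas:
            # paired seeds: the same generation/inference seeds are reused
            # across the whole delta grid within a replicate
            eff = plant_effect(base_spec, delta_intensity=delta, label="Y")
            imgs_a, _ = generate_cohort(
                cfg.n_animals, kind, replace(base_spec, label="X"),
                neuropils_per_animal=cfg.neuropils_per_animal, seed=gen_a,
            )
            imgs_b, _ = generate_cohort(
                cfg.n_animals, kind, eff,
                neuropils_per_animal=cfg.neuropils_per_animal, seed=gen_b,
            )
            dataset = build_pairwise_dataset(
                downscale_images(imgs_a, cfg.downscale),
                downscale_images(imgs_b, cfg.downscale),
                tag=f"d{delta:g}",
            )
            test = DifferentiabilityTest(
                n_splits=cfg.n_splits,
                runs_per_split=cfg.runs_per_split,
                validation_fraction=cfg.validation_fraction,
                augmentation=cfg.augmentation,
                config=_model_with_epochs(cfg),
                random_state=infer_seed,
            ).fit(dataset)
            rows.append(
                {
                    "delta": delta,
                    "replicate": r,
                    "grand_mean": test.summary_.grand_mean,
                    "ci_low": test.summary_.ci_low,
                    "significant": test.decision_.significant,
                }
            )
    return pd.DataFrame(rows)
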