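"""End-to-end study orchestration and accuracy-vs-parameter analysis.

`run_study` reproduces the whole experimental design on the synthetic
library: generate class templates, render replicate spectra, augment to the
training corpus, train the Bayesian network, score a broadened-resolution
(low-res instrument) test set, analyse accuracy as a function of each
augmentation parameter, and screen a mixed known/OOD discrimination set with
the IPR rule.  Optionally the tree-ensemble baselines are trained on the
identical vectors for comparison.  Everything is deterministic given the
seeds in `StudyConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, Corpus, apply, build_corpus, sample_params
from .baselines import BaselineConfig, baseline_discriminate, train_baseline
from .bnn import ArchitectureConfig, BayesianSpectrumClassifier, TrainConfig, VariationalFitResults
from .spectra import Spectrum
from .synth import ClassTemplate, LibrarySpec, make_library, render
from .uncertainty import discriminate, discrimination_metrics, predict_distribution

__all__ = [
    "ParameterSweepReport",
    "StudyConfig",
    "StudyResults",
    "accuracy_by_parameter",
    "run_study",
    "run_pipeline",
]

CONTINUOUS_PARAMS = ("noise_frac", "amp_slope", "shift")


@dataclasses.dataclass
class ParameterSweepReport:
    """Mean accuracy binned by each augmentation parameter.

    ``bins[param]`` is a DataFrame with columns (lo, hi, accuracy, count);
    for the integer downsampling factor each integer is its own bin.
    """

    bins: dict[str, pd.DataFrame]
    n_evaluated: int

    def max_variation(self, params: Sequence[str] | None = None) -> float:
        """Max minus min per-bin accuracy over the given parameters (all by default)."""
        params = list(self.bins) if params is None else list(params)
        accs = np.concatenate([
            self.bins[p]["accuracy"].to_numpy()[self.bins[p]["count"].to_numpy() > 0]
            for p in params
        ])
        return float(accs.max() - accs.min())


def accuracy_by_parameter(
    predictions: pd.DataFrame,
    ledger: pd.DataFrame,
    n_bins: int = 10,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> ParameterSweepReport:
    """Bin per-sample correctness by each augmentation parameter.

    ``predictions`` needs columns (id, correct); every id must appear in the
    ledger.  Continuous parameters are cut into ``n_bins`` equal-width bins
    over their sampled range (defaults from `AugmentationConfig`); the
    downsampling factor gets one bin per integer value.
    """
    missing = set(predictions["id"]) - set(ledger["id"])
    if missing:
        raise KeyError(f"ledger missing entries for ids: {sorted(missing)[:5]}...")
    merged = predictions.merge(ledger, on="id", how="left", validate="one_to_one")
    default = AugmentationConfig()
    if ranges is None:
        ranges = {
            "noise_frac": default.noise_range,
            "amp_slope": default.amp_slope_range,
            "shift": default.shift_range,
        }
    bins: dict[str, pd.DataFrame] = {}
    for param in CONTINUOUS_PARAMS:
        lo, hi = ranges[param]
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.digitize(merged[param], edges) - 1, 0, n_bins - 1)
        rows = []
        for b in range(n_bins):
            sel = merged.loc[idx == b, "correct"]
            rows.append({
                "lo": edges[b], "hi": edges[b + 1],
                "accuracy": float(sel.mean()) if len(sel) else np.nan,
                "count": int(len(sel)),
            })
        bins[param] = pd.DataFrame(rows)
    rows = []
    for value in sorted(merged["downsample"].unique()):
        sel = merged.loc[merged["downsample"] == value, "correct"]
        rows.append({
            "lo": float(value), "hi": float(value),
            "accuracy": float(sel.mean()), "count": int(len(sel)),
        })
    bins["downsample"] = pd.DataFrame(rows)
    report = ParameterSweepReport(bins, n_evaluated=len(merged))
    counts = sum(int(frame["count"].sum()) for frame in bins.values())
    assert counts == len(merged) * len(bins)
    return report


@dataclasses.dataclass
class StudyConfig:
    """All knobs of the end-to-end study, mirroring the experimental design.

    Defaults: 4 known classes rendered 8 times each (standing in for the 33
    labelled laboratory spectra), 2000 augmentations per class (8000-vector
    corpus, 70/30 split); an 8000-vector low-resolution test set rendered at
    3x band broadening from one known class; and a 1300-vector discrimination
    set augmented from 12 original spectra (5 renders over 3 known classes +
    7 OOD molecules), screened at IPR < 0.35 over 200 inferences.
    """

    library: LibrarySpec = dataclasses.field(default_factory=LibrarySpec)
    augmentation: AugmentationConfig = dataclasses.field(default_factory=AugmentationConfig)
    train: TrainConfig = dataclasses.field(default_factory=TrainConfig)
    arch: ArchitectureConfig | None = None
    replicates_per_class: int = 8
    test_class_index: int = 0
    test_broadening: float = 3.0
    test_replicates: int = 4
    test_total: int = 8000
    disc_total: int = 1300
    disc_known_renders: tuple[int, ...] = (2, 2, 1)  # per known class, 3 classes seen
    n_inferences: int = 200
    threshold: float = 0.35
    include_baselines: bool = False
    baseline_rf: BaselineConfig = dataclasses.field(
        default_factory=lambda: BaselineConfig(method="random_forest"))
    baseline_gbt: BaselineConfig = dataclasses.field(
        default_factory=lambda: BaselineConfig(method="gradient_boosted_trees", max_depth=6))


@dataclasses.dataclass
class StudyResults:
    config: StudyConfig
    classes: list[str]
    corpus: Corpus
    fit: VariationalFitResults
    val_accuracy: float
    test_accuracy: float
    test_predictions: pd.DataFrame
    test_ledger: pd.DataFrame
    sweep: ParameterSweepReport
    disc_metrics: object
    disc_table: pd.DataFrame
    disc_vectors: np.ndarray
    disc_labels: list[str]
    baseline_report: pd.DataFrame | None

    def summary_dict(self) -> dict:
        """The machine-readable study summary (headline numbers)."""
        return {
            "val_acc": self.val_accuracy,
            "test_acc": self.test_accuracy,
            "precision@0.35": self.disc_metrics.precision,
            "tpr": self.disc_metrics.tpr,
            "fpr": self.disc_metrics.fpr,
            "sweep_max_variation": self.sweep.max_variation(["amp_slope", "downsample"]),
            "corpus_size": len(self.corpus),
        }


def _render_replicates(
    templates: list[ClassTemplate], n_replicates: int, rng: np.random.Generator,
    broadening: float = 1.0,
) -> dict[str, list[Spectrum]]:
    out: dict[str, list[Spectrum]] = {}
    for t in templates:
        out[t.name] = [render(t, broadening=broadening, rng=rng) for _ in range(n_replicates)]
    return out


def _augment_set(
    sources: list[Spectrum], total: int, aug: AugmentationConfig, rng: np.random.Generator,
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Augment a fixed pool of source spectra to ``total`` vectors + ledger."""
    base, extra = divmod(total, len(sources))
    X, labels, rows = [], [], []
    i = 0
    for j, src in enumerate(sources):
        for _ in range(base + (1 if j < extra else 0)):
            params = sample_params(aug, rng)
            vec = apply(src, params, rng)
            sid = f"s{i:05d}"
            X.append(vec.values)
            labels.append(src.label)
            rows.append({"id": sid, "class": src.label, **dataclasses.asdict(params)})
            i += 1
    return np.stack(X), labels, pd.DataFrame(rows)


def mean_probability_accuracy(
    fit: VariationalFitResults, X: np.ndarray, y: np.ndarray,
    T: int, rng: np.random.Generator,
) -> tuple[float, np.ndarray]:
    """Accuracy of argmax of the T-inference mean probability."""
    dists = predict_distribution(fit.model, X, T=T, rng=rng)
    pred = np.array([d.predicted for d in dists])
    return float(np.mean(pred == y)), pred


def run_study(config: StudyConfig | None = None, seed: int | None = None) -> StudyResults:
    """Execute the full pipeline and collect every headline quantity.

    If ``seed`` is given it re-seeds the library, augmentation and training
    configs (offset so the stages use independent streams).
    """
    config = config or StudyConfig()
    if seed is not None:
        config = dataclasses.replace(
            config,
            library=dataclasses.replace(config.library, seed=seed),
            augmentation=dataclasses.replace(config.augmentation, seed=seed + 1),
            train=dataclasses.replace(config.train, seed=seed + 2),
        )
    master = np.random.default_rng(config.library.seed + 10_000)

    templates = make_library(config.library)
    known = [t for t in templates if not t.name.startswith("OOD:")]
    ood = [t for t in templates if t.name.startswith("OOD:")]
    classes = [t.name for t in known]

    # dataset 1 analogue: standard-resolution replicates -> augmented corpus
    by_class = _render_replicates(known, config.replicates_per_class, master)
    corpus = build_corpus(by_class, config.augmentation)
    model = BayesianSpectrumClassifier.from_corpus(corpus, arch=config.arch)
    fit = model.fit(config.train)

    xt, yt, xv, yv, _ = corpus.arrays(classes)
    rng_eval = np.random.default_rng(config.augmentation.seed + 20_000)
    val_accuracy, _ = mean_probability_accuracy(fit, xv, yv, config.n_inferences, rng_eval)

    # dataset 2 analogue: one known class on the low-resolution instrument
    test_t = known[config.test_class_index]
    test_sources = [
        render(test_t, broadening=config.test_broadening, rng=master)
        for _ in range(config.test_replicates)
    ]
    X_test, test_labels, test_ledger = _augment_set(
        test_sources, config.test_total, config.augmentation, master
    )
    y_test = np.array([classes.index(lbl) for lbl in test_labels])
    test_accuracy, test_pred = mean_probability_accuracy(
        fit, X_test, y_test, config.n_inferences, rng_eval
    )
    test_predictions = pd.DataFrame({
        "id": test_ledger["id"],
        "true": test_labels,
        "predicted": [classes[p] for p in test_pred],
        "correct": test_pred == y_test,
    })
    sweep = accuracy_by_parameter(test_predictions[["id", "correct"]], test_ledger)

    # dataset 3 analogue: endogenous mixture of known + OOD originals
    disc_sources: list[Spectrum] = []
    for cls_idx, n_renders in enumerate(config.disc_known_renders):
        for _ in range(n_renders):
            disc_sources.append(render(known[cls_idx], rng=master))
    for t in ood:
        disc_sources.append(render(t, rng=master))
    X_disc, disc_labels, disc_ledger = _augment_set(
        disc_sources, config.disc_total, config.augmentation, master
    )
    dists = predict_distribution(
        fit.model, X_disc, T=config.n_inferences, rng=rng_eval
    )
    results = [discriminate(d, config.threshold) for d in dists]
    disc_metrics = discrimination_metrics(results, disc_labels, classes)
    disc_table = pd.DataFrame({
        "id": disc_ledger["id"],
        "true": disc_labels,
        "predicted": [classes[r.predicted] for r in results],
        "accepted": [r.accepted for r in results],
        "predicted_ipr": [r.predicted_ipr for r in results],
        "mean_prob": [float(d.mean[d.predicted]) for d in dists],
    })

    baseline_report = None
    if config.include_baselines:
        baseline_report = _benchmark_baselines(
            config, classes, xt, yt, xv, yv, X_test, y_test, X_disc, disc_labels
        )

    return StudyResults(
        config=config, classes=classes, corpus=corpus, fit=fit,
        val_accuracy=val_accuracy, test_accuracy=test_accuracy,
        test_predictions=test_predictions, test_ledger=test_ledger, sweep=sweep,
        disc_metrics=disc_metrics, disc_table=disc_table,
        disc_vectors=X_disc, disc_labels=disc_labels,
        baseline_report=baseline_report,
    )


def _benchmark_baselines(config, classes, xt, yt, xv, yv, X_test, y_test, X_disc, disc_labels):
    rows = []
    for bconf in (config.baseline_rf, config.baseline_gbt):
        fitted = train_baseline(xt, yt, bconf)
        val_acc = float(np.mean(fitted.estimator.predict(xv) == yv))
        test_acc = float(np.mean(fitted.estimator.predict(X_test) == y_test))
        res = baseline_discriminate(fitted, X_disc, config.threshold)
        metrics = discrimination_metrics(res, disc_labels, classes)
        rows.append({
            "method": bconf.method, "val_acc": val_acc, "test_acc": test_acc,
            "precision": metrics.precision, "tpr": metrics.tpr, "fpr": metrics.fpr,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: StudyConfig, outdir: str | Path) -> dict:
    """Run the study and write all artifacts + a summary JSON to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        results = run_study(config)
    except Exception as exc:  # pragma: no cover - stage labelling only
        raise RuntimeError(f"pipeline failed: {exc}") from exc
    results.fit.save(outdir / "checkpoint")
    results.corpus.ledger.to_csv(outdir / "corpus_ledger.csv", index=False)
    results.test_ledger.to_csv(outdir / "test_ledger.csv", index=False)
    results.test_predictions.to_csv(outdir / "test_predictions.csv", index=False)
    results.disc_table.to_csv(outdir / "discrimination.csv", index=False)
    for param, frame in results.sweep.bins.items():
        frame.to_csv(outdir / f"sweep_{param}.csv", index=False)
    if results.baseline_report is not None:
        results.baseline_report.to_csv(outdir / "baselines.csv", index=False)
    summary = results.summary_dict()
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    seeds = {
        "library": results.config.library.seed,
        "augmentation": results.config.augmentation.seed,
        "train": results.config.train.seed,
        "baseline_rf": results.config.baseline_rf.seed,
        "baseline_gbt": results.config.baseline_gbt.seed,
    }
    (outdir / "seeds.json").write_text(json.dumps(seeds, indent=2))
    return summary


def plot_parameter_sweep(report: ParameterSweepReport, path: str | Path | None = None):
    """Accuracy-vs-augmentation-parameter panels (one per perturbation)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 6), constrained_layout=True)
    for ax, (param, frame) in zip(axes.ravel(), report.bins.items()):
        centers = (frame["lo"] + frame["hi"]) / 2.0
        ax.plot(centers, frame["accuracy"], "o-")
        ax.set_xlabel(param)
        ax.set_ylabel("accuracy")
        ax.set_ylim(0.9, 1.005)
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_prediction_maps(disc_table: pd.DataFrame, dists, classes, path=None):
    """Mean-probability and IPR heat maps over the discrimination samples."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mean = np.stack([d.mean for d in dists])
    ipr = np.stack([d.ipr for d in dists])
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 6), constrained_layout=True)
    for ax, mat, title in ((ax1, mean, "mean probability"), (ax2, ipr, "5-95 IPR")):
        im = ax.imshow(mat, aspect="auto", vmin=0, vmax=1, cmap="viridis")
        ax.set_xticks(range(len(classes)), classes, rotation=45)
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
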