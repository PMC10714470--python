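"""Epistemic-uncertainty quantification and out-of-distribution screening.

The trained variational network is run T times (default 200) on each
spectrum, resampling the weights on every pass.  The spread of the resulting
class probabilities measures the model's epistemic uncertainty: for each
class we keep the mean probability and the 5-95 interpercentile range (IPR,
linear-interpolation percentiles).  A prediction is *accepted* only when the
IPR of the winning class is strictly below a threshold (default 0.35) —
spectra from molecules outside the training categories produce broad
probability distributions and are rejected for manual review instead of
being mislabelled.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .bnn import VariationalModel, forward_sample

__all__ = [
    "PredictionDistribution",
    "DiscriminationResult",
    "DiscriminationMetrics",
    "predict_distribution",
    "discriminate",
    "discrimination_metrics",
]

OOD_PREFIX = "OOD:"


@dataclasses.dataclass
class PredictionDistribution:
    """Per-class summary of T repeated inferences on one spectrum."""

    mean: np.ndarray  # mean probability per class; sums to 1
    p5: np.ndarray  # 5th percentile per class
    p95: np.ndarray  # 95th percentile per class
    T: int

    def __post_init__(self) -> None:
        for arr in (self.mean, self.p5, self.p95):
            if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-12):
                raise ValueError("probabilities outside [0, 1]")
        if np.any(self.p5 > self.p95 + 1e-12):
            raise ValueError("p5 > p95")
        if abs(self.mean.sum() - 1.0) > 1e-9:
            raise ValueError("class means must sum to 1")

    @property
    def ipr(self) -> np.ndarray:
        """5-95 interpercentile range per class."""
        return self.p95 - self.p5

    @property
    def predicted(self) -> int:
        return int(np.argmax(self.mean))


@dataclasses.dataclass
class DiscriminationResult:
    """Argmax prediction plus the IPR acceptance decision."""

    predicted: int
    accepted: bool
    threshold: float
    predicted_ipr: float

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold <= 1.0):
            raise ValueError("threshold must be in (0, 1]")


def percentile_summary(probs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean and linear-interpolation 5/95 percentiles across inference passes.

    ``probs`` has shape (T, ...); statistics are taken over the first axis.
    """
    mean = probs.mean(axis=0)
    p5, p95 = np.percentile(probs, [5.0, 95.0], axis=0, method="linear")
    return mean, p5, p95


def predict_distribution(
    model: VariationalModel,
    X: np.ndarray,
    T: int = 200,
    rng: np.random.Generator | int | None = None,
) -> list[PredictionDistribution]:
    """Summarise T weight-resampled inferences for each input row.

    Each of the T passes draws one fresh set of weights (dropout off) and
    evaluates the whole batch; per-class means and linear-interpolation 5/95
    percentiles are taken across passes.  Deterministic given the rng state.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    probs = np.empty((T, n, model.arch.n_classes))
    for t in range(T):
        probs[t] = forward_sample(model, X, rng, training=False)
    mean, p5, p95 = percentile_summary(probs)
    return [PredictionDistribution(mean[i], p5[i], p95[i], T) for i in range(n)]


def discriminate(dist: PredictionDistribution, threshold: float = 0.35) -> DiscriminationResult:
    """Accept the argmax prediction iff its IPR is strictly below ``threshold``."""
    k = dist.predicted
    ipr = float(dist.ipr[k])
    return DiscriminationResult(
        predicted=k, accepted=bool(ipr < threshold), threshold=threshold, predicted_ipr=ipr
    )


@dataclasses.dataclass
class DiscriminationMetrics:
    precision: float  # accepted & in-distribution & correct / accepted
    tpr: float  # in-distribution accepted & correct / in-distribution
    fpr: float  # OOD accepted / OOD
    confusion: pd.DataFrame  # true label x (predicted class, acceptance)
    n_accepted: int
    n_in_distribution: int
    n_ood: int


def _is_ood(label: str, class_names: list[str]) -> bool:
    return label.startswith(OOD_PREFIX) or label not in class_names


def discrimination_metrics(
    results: list[DiscriminationResult],
    truths: list[str],
    class_names: list[str],
) -> DiscriminationMetrics:
    """Precision / TPR / FPR of the acceptance rule against annotated truths.

    A truth label matching a known class name is in-distribution; anything
    else (conventionally prefixed ``"OOD:"``) is out-of-distribution.  A true
    positive requires acceptance *and* correct classification.  Ratios with a
    zero denominator are reported as NaN with a warning, never silently 0.
    """
    if len(results) != len(truths):
        raise ValueError(f"{len(results)} results vs {len(truths)} truths")
    rows = []
    for res, truth in zip(results, truths):
        ood = _is_ood(truth, class_names)
        correct = (not ood) and (class_names[res.predicted] == truth)
        rows.append({
            "truth": truth,
            "predicted": class_names[res.predicted],
            "ood": ood,
            "accepted": res.accepted,
            "correct": correct,
        })
    frame = pd.DataFrame(rows)
    n_acc = int(frame["accepted"].sum())
    n_id = int((~frame["ood"]).sum())
    n_ood = int(frame["ood"].sum())

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=2)
            return float("nan")
        return num / den

    precision = _ratio(
        int((frame["accepted"] & ~frame["ood"] & frame["correct"]).sum()), n_acc, "precision"
    )
    tpr = _ratio(int((~frame["ood"] & frame["accepted"] & frame["correct"]).sum()), n_id, "TPR")
    fpr = _ratio(int((frame["ood"] & frame["accepted"]).sum()), n_ood, "FPR")
    confusion = pd.crosstab(frame["truth"], [frame["predicted"], frame["accepted"]])
    return DiscriminationMetrics(precision, tpr, fpr, confusion, n_acc, n_id, n_ood)
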