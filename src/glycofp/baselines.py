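"""Decision-tree-ensemble comparators: random forest and gradient boosting.

Both consume exactly the same z-scored 1200-bin vectors and train/validation
split as the Bayesian network.  Each is given a discrimination analogue of
the IPR acceptance rule so the three methods can be benchmarked on the same
footing:

* random forest — the across-tree vote distribution plays the role of the
  repeated-inference ensemble: per-tree class votes give a mean vote fraction
  and a 5-95 interpercentile range, thresholded like the Bayesian IPR;
* gradient-boosted trees expose no ensemble of comparable members, so the
  analogue accepts iff the maximum class probability exceeds 1 - threshold
  (equivalently, pseudo-IPR = 1 - max probability is below the threshold).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .uncertainty import DiscriminationResult, PredictionDistribution

__all__ = ["BaselineConfig", "FittedBaseline", "train_baseline", "baseline_discriminate"]

METHODS = ("random_forest", "gradient_boosted_trees")


@dataclasses.dataclass
class BaselineConfig:
    """Hyper-parameters of one tree-ensemble comparator."""

    method: str = "random_forest"
    n_estimators: int = 300
    max_depth: int | None = None  # None = unlimited (RF); 6 used for GBT
    learning_rate: float = 0.1  # GBT only
    seed: int = 0
    threshold: float = 0.35

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")


@dataclasses.dataclass
class FittedBaseline:
    config: BaselineConfig
    estimator: object
    n_classes: int


def train_baseline(X: np.ndarray, y: np.ndarray, config: BaselineConfig) -> FittedBaseline:
    """Fit the configured ensemble; deterministic given ``config.seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_classes = len(np.unique(y))
    if n_classes < 2:
        raise ValueError("training set contains a single class")
    if config.method == "random_forest":
        est = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth,
            random_state=config.seed,
            n_jobs=1,
        )
    else:
        est = XGBClassifier(
            n_estimators=config.n_estimators,
            max_depth=config.max_depth if config.max_depth is not None else 6,
            learning_rate=config.learning_rate,
            random_state=config.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )
    est.fit(X, y)
    return FittedBaseline(config, est, n_classes)


def baseline_predict(fitted: FittedBaseline, X: np.ndarray) -> np.ndarray:
    return np.asarray(fitted.estimator.predict(np.atleast_2d(X)))


def baseline_discriminate(
    fitted: FittedBaseline, X: np.ndarray, threshold: float | None = None
) -> list[DiscriminationResult]:
    """Acceptance decisions with the method-appropriate IPR analogue."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    thr = fitted.config.threshold if threshold is None else threshold
    results = []
    if fitted.config.method == "random_forest":
        est: RandomForestClassifier = fitted.estimator
        n_classes = len(est.classes_)
        # one-hot class vote per tree, shape (n_trees, n, n_classes);
        # individual trees emit encoded class indices 0..K-1
        votes = np.stack([
            np.eye(n_classes)[tree.predict(X).astype(int)] for tree in est.estimators_
        ])
        mean = votes.mean(axis=0)
        p5, p95 = np.percentile(votes, [5.0, 95.0], axis=0)
        for i in range(X.shape[0]):
            dist = PredictionDistribution(mean[i], p5[i], p95[i], T=len(est.estimators_))
            k = dist.predicted
            ipr = float(dist.ipr[k])
            results.append(DiscriminationResult(k, bool(ipr < thr), thr, ipr))
    else:
        probs = fitted.estimator.predict_proba(X)
        for i in range(X.shape[0]):
            k = int(np.argmax(probs[i]))
            pseudo_ipr = float(1.0 - probs[i, k])
            results.append(DiscriminationResult(k, bool(pseudo_ipr < thr), thr, pseudo_ipr))
    return results
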