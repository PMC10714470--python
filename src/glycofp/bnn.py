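"""Bayesian multilayer perceptron trained by Bayes-by-Backprop.

Every weight and bias of a fully connected ReLU network (default
1200 -> 300 -> 225 -> 100 -> n_classes, dropout 25% after the first two hidden
layers) is replaced by an independent Gaussian posterior N(mu, sigma^2) with
sigma = softplus(rho), against a standard-normal prior.  Training minimises
the negative ELBO: Monte-Carlo cross-entropy under reparameterized weight
samples (w = mu + sigma * eps) plus a weighted closed-form KL(q || N(0, 1)).
Gradients are computed analytically (reverse-mode, by hand) and optimised
with Adam.

The module exposes both the functional surface (`init_model`,
`forward_sample`, `kl_divergence`, `loss`, `train`) and a model/results pair
(`BayesianSpectrumClassifier` / `VariationalFitResults`) for fitting from
data and carrying the posterior, training history and prediction utilities.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "ArchitectureConfig",
    "TrainConfig",
    "VariationalModel",
    "init_model",
    "forward_sample",
    "forward_mean",
    "kl_divergence",
    "loss",
    "loss_and_grads",
    "train",
    "BayesianSpectrumClassifier",
    "VariationalFitResults",
]

_CHECKPOINT_VERSION = 1


@dataclasses.dataclass
class ArchitectureConfig:
    """Network shape: sizes, dropout and (implicitly) ReLU activations.

    Dropout is applied after hidden layers 1 and 2 only, and only during
    training; inference stochasticity comes solely from weight sampling.
    """

    input_dim: int = 1200
    hidden: tuple[int, ...] = (300, 225, 100)
    n_classes: int = 4
    dropout_rate: float = 0.25

    def __post_init__(self) -> None:
        sizes = (self.input_dim, *self.hidden, self.n_classes)
        if any(s < 1 for s in sizes):
            raise ValueError("all layer sizes must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def sizes(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden, self.n_classes)


@dataclasses.dataclass
class TrainConfig:
    """Optimisation settings for Bayes-by-Backprop (Adam).

    ``kl_weight=None`` resolves to 1/n_train: with a batch-*mean* likelihood
    term this charges exactly one full KL per epoch (batch objective times
    batch size equals sum-cross-entropy + KL/num_batches, the standard
    minibatched ELBO).  ``mc_samples`` is the number of weight samples per
    gradient step.
    """

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    mc_samples: int = 1
    kl_weight: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size, self.mc_samples) < 1:
            raise ValueError("epochs, batch_size and mc_samples must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.kl_weight is not None and self.kl_weight <= 0:
            raise ValueError("kl_weight must be > 0")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


@dataclasses.dataclass
class VariationalModel:
    """Per-parameter Gaussian posteriors (mu, rho) for each layer.

    ``sigma = softplus(rho)`` is strictly positive by construction.  Lists are
    indexed by layer; weight matrices have shape (fan_in, fan_out).
    """

    arch: ArchitectureConfig
    mu_W: list[np.ndarray]
    rho_W: list[np.ndarray]
    mu_b: list[np.ndarray]
    rho_b: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.mu_W)

    def n_parameters(self) -> int:
        """Weights + biases (each carries a (mu, rho) pair on top)."""
        return int(
            sum(w.size for w in self.mu_W) + sum(b.size for b in self.mu_b)
        )

    def sigma_W(self) -> list[np.ndarray]:
        return [_softplus(r) for r in self.rho_W]

    def sigma_b(self) -> list[np.ndarray]:
        return [_softplus(r) for r in self.rho_b]

    def copy(self) -> "VariationalModel":
        return VariationalModel(
            self.arch,
            [w.copy() for w in self.mu_W],
            [r.copy() for r in self.rho_W],
            [b.copy() for b in self.mu_b],
            [r.copy() for r in self.rho_b],
        )


def init_model(arch: ArchitectureConfig, seed: int = 0) -> VariationalModel:
    """Initialise posteriors: mu ~ N(0, 0.1^2)/sqrt(fan_in), rho = -3.

    rho = -3 gives sigma = softplus(-3) ~ 0.0486, a near-deterministic start.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = arch.sizes
    mu_W, rho_W, mu_b, rho_b = [], [], [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        mu_W.append(rng.normal(0.0, 0.1, size=(n_in, n_out)) / np.sqrt(n_in))
        mu_b.append(rng.normal(0.0, 0.1, size=n_out) / np.sqrt(n_in))
        rho_W.append(np.full((n_in, n_out), -3.0))
        rho_b.append(np.full(n_out, -3.0))
    return VariationalModel(arch, mu_W, rho_W, mu_b, rho_b)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sample_weights(model: VariationalModel, rng: np.random.Generator | None):
    Ws, bs, eps_W, eps_b = [], [], [], []
    for muW, rhoW, mub, rhob in zip(model.mu_W, model.rho_W, model.mu_b, model.rho_b):
        if rng is None:
            eW = np.zeros_like(muW)
            eb = np.zeros_like(mub)
        else:
            eW = rng.standard_normal(muW.shape)
            eb = rng.standard_normal(mub.shape)
        Ws.append(muW + _softplus(rhoW) * eW)
        bs.append(mub + _softplus(rhob) * eb)
        eps_W.append(eW)
        eps_b.append(eb)
    return Ws, bs, eps_W, eps_b


def _forward(Ws, bs, X, dropout_rate, training, rng):
    """Forward pass; returns probabilities and the caches needed for backprop."""
    n_layers = len(Ws)
    a = X
    acts = [X]
    relu_masks = []
    drop_masks = []
    for layer in range(n_layers):
        z = a @ Ws[layer] + bs[layer]
        if layer < n_layers - 1:
            mask = z > 0
            a = z * mask
            relu_masks.append(mask)
            if training and dropout_rate > 0 and layer < 2:
                keep = 1.0 - dropout_rate
                dmask = (rng.uniform(size=a.shape) < keep) / keep
                a = a * dmask
                drop_masks.append(dmask)
            else:
                drop_masks.append(None)
            acts.append(a)
        else:
            probs = _softmax(z)
    return probs, acts, relu_masks, drop_masks


def forward_sample(
    model: VariationalModel,
    X: np.ndarray,
    rng: np.random.Generator | None,
    training: bool = False,
) -> np.ndarray:
    """One stochastic forward pass with reparameterized weight samples.

    Weights are drawn once (w = mu + sigma * eps, shared across the batch, as
    one repeated inference of the whole batch); dropout is applied only when
    ``training`` is true.  ``rng=None`` uses the posterior means (eps = 0).
    Returns class probabilities, one row per input, each summing to 1.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.arch.input_dim:
        raise ValueError(f"expected input dim {model.arch.input_dim}, got {X.shape[1]}")
    Ws, bs, _, _ = _sample_weights(model, rng)
    probs, *_ = _forward(Ws, bs, X, model.arch.dropout_rate, training, rng)
    return probs


def forward_mean(model: VariationalModel, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass using the posterior means (no dropout)."""
    return forward_sample(model, X, rng=None, training=False)


def kl_divergence(model: VariationalModel) -> float:
    """KL(q || prior) in nats, summed over all weights and biases.

    Closed form per parameter against the N(0, 1) prior:
    ln(1/sigma) + (sigma^2 + mu^2)/2 - 1/2.
    """
    total = 0.0
    for mu, rho in zip(model.mu_W + model.mu_b, model.rho_W + model.rho_b):
        sigma = _softplus(rho)
        total += float(np.sum(-np.log(sigma) + (sigma**2 + mu**2) / 2.0 - 0.5))
    return total


def loss_and_grads(
    model: VariationalModel,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    mc_samples: int = 1,
    kl_weight: float = 1.0,
    training: bool = True,
):
    """Negative-ELBO estimate and its exact gradients w.r.t. every (mu, rho).

    Data term: mean over ``mc_samples`` weight draws of the batch-mean
    cross-entropy; plus ``kl_weight * KL``.  Reparameterization gives
    d/d mu = dL/dw and d/d rho = dL/dw * eps * sigmoid(rho).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    if y.min() < 0 or y.max() >= model.arch.n_classes:
        raise ValueError("label outside 0..n_classes-1")
    n, L = X.shape[0], model.n_layers
    g_mu_W = [np.zeros_like(w) for w in model.mu_W]
    g_rho_W = [np.zeros_like(w) for w in model.rho_W]
    g_mu_b = [np.zeros_like(b) for b in model.mu_b]
    g_rho_b = [np.zeros_like(b) for b in model.rho_b]
    sig_rho_W = [expit(r) for r in model.rho_W]
    sig_rho_b = [expit(r) for r in model.rho_b]

    ce_total = 0.0
    for _ in range(mc_samples):
        Ws, bs, eps_W, eps_b = _sample_weights(model, rng)
        probs, acts, relu_masks, drop_masks = _forward(
            Ws, bs, X, model.arch.dropout_rate, training, rng
        )
        p_true = np.clip(probs[np.arange(n), y], 1e-300, None)
        ce_total += -float(np.mean(np.log(p_true)))

        delta = probs.copy()
        delta[np.arange(n), y] -= 1.0
        delta /= n * mc_samples
        for layer in reversed(range(L)):
            a_prev = acts[layer]
            dW = a_prev.T @ delta
            db = delta.sum(axis=0)
            g_mu_W[layer] += dW
            g_rho_W[layer] += dW * eps_W[layer] * sig_rho_W[layer]
            g_mu_b[layer] += db
            g_rho_b[layer] += db * eps_b[layer] * sig_rho_b[layer]
            if layer > 0:
                delta = delta @ Ws[layer].T
                if drop_masks[layer - 1] is not None:
                    delta = delta * drop_masks[layer - 1]
                delta = delta * relu_masks[layer - 1]

    ce = ce_total / mc_samples
    kl = kl_divergence(model)
    for layer in range(L):
        sigW = _softplus(model.rho_W[layer])
        sigb = _softplus(model.rho_b[layer])
        g_mu_W[layer] += kl_weight * model.mu_W[layer]
        g_rho_W[layer] += kl_weight * (sigW - 1.0 / sigW) * sig_rho_W[layer]
        g_mu_b[layer] += kl_weight * model.mu_b[layer]
        g_rho_b[layer] += kl_weight * (sigb - 1.0 / sigb) * sig_rho_b[layer]
    total = ce + kl_weight * kl
    grads = {"mu_W": g_mu_W, "rho_W": g_rho_W, "mu_b": g_mu_b, "rho_b": g_rho_b}
    return total, ce, kl, grads


def loss(
    model: VariationalModel,
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    mc_samples: int = 1,
    kl_weight: float = 1.0,
    training: bool = True,
) -> float:
    """Scalar training objective (see `loss_and_grads`)."""
    total, _, _, _ = loss_and_grads(model, X, y, rng, mc_samples, kl_weight, training)
    return total


class _Adam:
    def __init__(self, shapes_like: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {k: [np.zeros_like(a) for a in v] for k, v in shapes_like.items()}
        self.v = {k: [np.zeros_like(a) for a in v] for k, v in shapes_like.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for key in params:
            for i, (p, g) in enumerate(zip(params[key], grads[key])):
                m = self.m[key][i]
                v = self.v[key][i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


def train(
    model: VariationalModel,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
) -> tuple[VariationalModel, pd.DataFrame]:
    """Minibatch Adam on the negative ELBO; returns (model, history).

    ``kl_weight`` defaults to 1/n_train (one full KL per epoch against the
    summed likelihood; see `TrainConfig`).  The per-epoch history records
    the epoch-mean loss, its cross-entropy and KL components, and validation
    accuracy from deterministic mean-weight (mu) forward passes.  Deterministic
    given ``config.seed``.  Aborts with a diagnostic on non-finite loss.
    """
    X, y = train_set
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0 or (val_set is not None and len(val_set[0]) == 0):
        raise ValueError("empty training or validation set")
    rng = np.random.default_rng(config.seed)
    n = len(X)
    num_batches = int(np.ceil(n / config.batch_size))
    kl_weight = config.kl_weight if config.kl_weight is not None else 1.0 / n
    params = {"mu_W": model.mu_W, "rho_W": model.rho_W,
              "mu_b": model.mu_b, "rho_b": model.rho_b}
    opt = _Adam(params, config.learning_rate)
    history = []
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        ep_loss = ep_ce = ep_kl = 0.0
        for b in range(num_batches):
            idx = perm[b * config.batch_size : (b + 1) * config.batch_size]
            total, ce, kl, grads = loss_and_grads(
                model, X[idx], y[idx], rng,
                mc_samples=config.mc_samples, kl_weight=kl_weight, training=True,
            )
            if not np.isfinite(total):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, batch {b}"
                )
            opt.step(params, grads)
            ep_loss += total
            ep_ce += ce
            ep_kl += kl
        row = {
            "epoch": epoch,
            "loss": ep_loss / num_batches,
            "cross_entropy": ep_ce / num_batches,
            "kl": ep_kl / num_batches,
        }
        if val_set is not None:
            probs = forward_mean(model, val_set[0])
            row["val_accuracy"] = float(np.mean(probs.argmax(axis=1) == val_set[1]))
        history.append(row)
    return model, pd.DataFrame(history)


class BayesianSpectrumClassifier:
    """Bayesian MLP classifier of preprocessed IR fingerprint vectors.

    Built from training (and optionally validation) data; ``fit`` runs
    Bayes-by-Backprop and returns a `VariationalFitResults`.

    Parameters
    ----------
    X, y : training inputs (n, input_dim) and integer labels
    X_val, y_val : optional held-out split used for the per-epoch accuracy
    classes : class names in label-index order
    arch : network architecture; inferred dims by default
    """

    def __init__(self, X, y, X_val=None, y_val=None,
                 classes: Sequence[str] | None = None,
                 arch: ArchitectureConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y)
        self.X_val = None if X_val is None else np.asarray(X_val, dtype=float)
        self.y_val = None if y_val is None else np.asarray(y_val)
        n_classes = int(self.y.max()) + 1 if classes is None else len(classes)
        self.classes = (
            list(classes) if classes is not None else [str(i) for i in range(n_classes)]
        )
        if arch is None:
            arch = ArchitectureConfig(input_dim=self.X.shape[1], n_classes=n_classes)
        self.arch = arch

    @classmethod
    def from_corpus(cls, corpus, arch: ArchitectureConfig | None = None
                    ) -> "BayesianSpectrumClassifier":
        """Build from an augmented `Corpus` (see `glycofp.augment`)."""
        xt, yt, xv, yv, classes = corpus.arrays()
        if arch is None:
            arch = ArchitectureConfig(input_dim=xt.shape[1], n_classes=len(classes))
        return cls(xt, yt, xv, yv, classes=classes, arch=arch)

    def fit(self, config: TrainConfig | None = None) -> "VariationalFitResults":
        config = config or TrainConfig()
        model = init_model(self.arch, seed=config.seed)
        val = None if self.X_val is None else (self.X_val, self.y_val)
        model, history = train(model, (self.X, self.y), val, config)
        return VariationalFitResults(self, model, history, config)


class VariationalFitResults:
    """Posterior, training history and prediction utilities of a fitted model."""

    def __init__(self, parent: BayesianSpectrumClassifier, model: VariationalModel,
                 history: pd.DataFrame, config: TrainConfig):
        self.model_spec = parent
        self.model = model
        self.history = history
        self.config = config
        self.classes = parent.classes

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Deterministic class probabilities from the posterior means."""
        return forward_mean(self.model, X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def predict_distribution(self, X, T: int = 200, rng=None):
        """Repeated-inference predictive distributions (see `glycofp.uncertainty`)."""
        from .uncertainty import predict_distribution

        return predict_distribution(self.model, X, T=T, rng=rng)

    @property
    def val_accuracy(self) -> float | None:
        if "val_accuracy" not in self.history:
            return None
        return float(self.history["val_accuracy"].iloc[-1])

    def summary(self) -> str:
        """Plain-text fit summary: architecture, posterior scales, history tail."""
        m = self.model
        lines = [
            "Bayesian spectrum classifier (Bayes-by-Backprop)",
            "=" * 52,
            f"layers:           {' -> '.join(map(str, m.arch.sizes))}",
            f"parameters:       {m.n_parameters()} (mu, rho pairs: {2 * m.n_parameters()})",
            f"classes:          {', '.join(self.classes)}",
            f"epochs trained:   {len(self.history)}",
            f"final loss:       {self.history['loss'].iloc[-1]:.4f}",
            f"final KL (nats):  {self.history['kl'].iloc[-1]:.1f}",
        ]
        if self.val_accuracy is not None:
            lines.append(f"val accuracy:     {self.val_accuracy:.4f} (mean-weight passes)")
        lines.append("posterior scale per layer (mean sigma):")
        for i, (sw, sb) in enumerate(zip(m.sigma_W(), m.sigma_b())):
            lines.append(f"  layer {i}: weights {sw.mean():.4f}  biases {sb.mean():.4f}")
        return "\n".join(lines)

    def save(self, directory: str | Path) -> None:
        """Checkpoint: JSON metadata + one .npz of named (mu, rho) arrays."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": _CHECKPOINT_VERSION,
            "arch": dataclasses.asdict(self.model.arch),
            "train_config": dataclasses.asdict(self.config),
            "classes": self.classes,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        arrays = {}
        for i in range(self.model.n_layers):
            arrays[f"mu_W{i}"] = self.model.mu_W[i]
            arrays[f"rho_W{i}"] = self.model.rho_W[i]
            arrays[f"mu_b{i}"] = self.model.mu_b[i]
            arrays[f"rho_b{i}"] = self.model.rho_b[i]
        np.savez(directory / "parameters.npz", **arrays)
        self.history.to_csv(directory / "history.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "VariationalFitResults":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        if meta.get("format_version") != _CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        arch_d = meta["arch"]
        arch_d["hidden"] = tuple(arch_d["hidden"])
        arch = ArchitectureConfig(**arch_d)
        config = TrainConfig(**meta["train_config"])
        with np.load(directory / "parameters.npz") as data:
            n_layers = len(arch.sizes) - 1
            mu_W = [data[f"mu_W{i}"] for i in range(n_layers)]
            rho_W = [data[f"rho_W{i}"] for i in range(n_layers)]
            mu_b = [data[f"mu_b{i}"] for i in range(n_layers)]
            rho_b = [data[f"rho_b{i}"] for i in range(n_layers)]
        sizes = arch.sizes
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            if mu_W[i].shape != (n_in, n_out) or mu_b[i].shape != (n_out,):
                raise ValueError(f"checkpoint layer {i} shape mismatch with metadata")
        model = VariationalModel(arch, mu_W, rho_W, mu_b, rho_b)
        history = pd.read_csv(directory / "history.csv")
        parent = BayesianSpectrumClassifier(
            np.zeros((1, arch.input_dim)), np.zeros(1, dtype=int),
            classes=meta["classes"], arch=arch,
        )
        return cls(parent, model, history, config)
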