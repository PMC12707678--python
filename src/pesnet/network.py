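"""Feed-forward network and the constraint-aware training loop.

The network is a compact fully connected multilayer perceptron written
directly on numpy, with analytic backpropagation.  Writing the backward
pass by hand is what lets the composite objective differentiate through
*several* forward passes per batch: the base batch plus one single-column
perturbed copy per effect-size constraint.

Tasks map to output transforms of the raw network score ``z``:

* ``regression``            -> identity (pairs with SRC constraints, MSE)
* ``binary_classification`` -> sigmoid  (pairs with OR constraints, BCE)
* ``rate_regression``       -> exp      (pairs with RR constraints, MSE on the rate)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .priors import (
    ConstraintWeights,
    PerturbedBatch,
    PriorEffect,
    composite_loss,
    constraint_loss_grads,
)

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "FitResult",
    "MLP",
    "build_network",
    "make_perturbed_inputs",
    "fit",
    "predict",
]

TASKS = ("regression", "binary_classification", "rate_regression")


@dataclass(frozen=True)
class NetworkSpec:
    n_inputs: int
    hidden_sizes: tuple[int, ...] = (32,)
    activation: str = "relu"
    task: str = "regression"

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be positive")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden layer widths must be positive")
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    max_epochs: int = 1000
    patience: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    monitor: str = "composite"  # or "prediction_only"

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch_size must be at least 2")
        if self.patience < 1:
            raise ValueError("patience must be at least 1")
        if self.monitor not in ("composite", "prediction_only"):
            raise ValueError("monitor must be 'composite' or 'prediction_only'")


@dataclass
class FitResult:
    model: "MLP"
    history: pd.DataFrame
    best_epoch: int
    stopped_epoch: int


class MLP:
    """Fully connected network with linear output score.

    Weights are He/Xavier-initialized from a seeded generator, so identical
    seeds yield identical parameters.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        rng = np.random.default_rng(seed)
        sizes = (spec.n_inputs, *spec.hidden_sizes, 1)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            if spec.activation == "relu":
                scale = np.sqrt(2.0 / fan_in)
            else:
                scale = np.sqrt(1.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.parameters()])

    def set_flat(self, flat: np.ndarray) -> None:
        i = 0
        for p in self.parameters():
            p[...] = flat[i : i + p.size].reshape(p.shape)
            i += p.size

    # -- forward / backward -------------------------------------------------

    def _act(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(x, 0.0) if self.spec.activation == "relu" else np.tanh(x)

    def forward(self, X: np.ndarray, cache: bool = False):
        """Raw score ``z`` of shape (n,); optionally the activation cache."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"expected input of width {self.spec.n_inputs}, got shape {X.shape}"
            )
        activations = [X]
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = self._act(a @ W + b)
            activations.append(a)
        z = (a @ self.weights[-1] + self.biases[-1]).ravel()
        if cache:
            return z, activations
        return z

    def backward(self, activations: list[np.ndarray], d_z: np.ndarray):
        """Gradients of a scalar loss given d loss / d z (shape (n,))."""
        grads_W = [np.empty_like(W) for W in self.weights]
        grads_b = [np.empty_like(b) for b in self.biases]
        delta = np.asarray(d_z, dtype=float).reshape(-1, 1)
        for layer in range(len(self.weights) - 1, -1, -1):
            a_in = activations[layer]
            grads_W[layer] = a_in.T @ delta
            grads_b[layer] = delta.sum(axis=0)
            if layer > 0:
                delta = delta @ self.weights[layer].T
                if self.spec.activation == "relu":
                    delta = delta * (activations[layer] > 0)
                else:
                    delta = delta * (1.0 - activations[layer] ** 2)
        return grads_W + grads_b


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def build_network(spec: NetworkSpec, seed: int = 0) -> MLP:
    return MLP(spec, seed=seed)


def _resolve_columns(X, priors: Sequence[PriorEffect], columns) -> list[int]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
    elif columns is not None:
        names = list(columns)
    else:
        names = None
    idx = []
    for p in priors:
        if names is None:
            raise ValueError("column names are required to map priors to columns")
        if p.variable not in names:
            raise KeyError(f"prior variable {p.variable!r} not among columns {names}")
        idx.append(names.index(p.variable))
    return idx


def make_perturbed_inputs(
    X, priors: Sequence[PriorEffect], columns: Sequence[str] | None = None
) -> PerturbedBatch:
    """One single-column-shifted copy of ``X`` per prior.

    SRC and RR constraints shift their column by ``+h``; OR constraints by
    ``-h`` (their loss is written in terms of the ``x - h`` batch).
    """
    idx = _resolve_columns(X, priors, columns)
    base = np.asarray(X, dtype=float)
    perturbed, directions, steps = [], [], []
    for p, j in zip(priors, idx):
        Xp = base.copy()
        Xp[:, j] += p.direction * p.step
        perturbed.append(Xp)
        directions.append(p.direction)
        steps.append(p.step)
    return PerturbedBatch(
        base=base,
        perturbed=tuple(perturbed),
        directions=tuple(directions),
        columns=tuple(idx),
        steps=tuple(steps),
    )


# ---------------------------------------------------------------------------
# Output transforms and prediction losses (gradients w.r.t. the raw score z)
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _output(task: str, z: np.ndarray) -> np.ndarray:
    if task == "regression":
        return z
    if task == "binary_classification":
        return _sigmoid(z)
    return np.exp(np.clip(z, -50, 50))


def _output_jac(task: str, f: np.ndarray) -> np.ndarray:
    """d output / d z, expressed through the output value f."""
    if task == "regression":
        return np.ones_like(f)
    if task == "binary_classification":
        return f * (1.0 - f)
    return f


def _pred_loss_grads(task: str, z: np.ndarray, y: np.ndarray):
    """Prediction loss and its gradient w.r.t. z.  MSE for the regression
    tasks, binary cross-entropy for classification."""
    n = z.size
    if task == "binary_classification":
        p = _sigmoid(z)
        eps = 1e-12
        loss = float(-np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
        return loss, (p - y) / n
    f = _output(task, z)
    resid = f - y
    loss = float(np.mean(resid**2))
    return loss, 2.0 * resid * _output_jac(task, f) / n


def predict(model: MLP, X) -> np.ndarray:
    """Task-scale predictions: identity / probability / positive rate."""
    return _output(model.spec.task, model.forward(np.asarray(X, dtype=float)))


def _constraint_terms(model: MLP, pb: PerturbedBatch, priors, want_grads: bool):
    """Constraint losses (and output-space gradients) for one batch."""
    task = model.spec.task
    z_base, cache_base = model.forward(pb.base, cache=True)
    f_base = _output(task, z_base)
    terms = []
    for p, Xp in zip(priors, pb.perturbed):
        z_p, cache_p = model.forward(Xp, cache=True)
        f_p = _output(task, z_p)
        loss, d_base, d_pert = constraint_loss_grads(p, f_base, f_p)
        if want_grads:
            terms.append((loss, d_base * _output_jac(task, f_base), d_pert * _output_jac(task, f_p), cache_p))
        else:
            terms.append((loss, None, None, None))
    return z_base, f_base, cache_base, terms


def _validation_losses(model, X_val, y_val, priors, weights, pb_val):
    z_val = model.forward(pb_val.base if pb_val is not None else X_val)
    pred, _ = _pred_loss_grads(model.spec.task, z_val, y_val)
    metas = []
    if priors:
        f_base = _output(model.spec.task, z_val)
        for p, Xp in zip(priors, pb_val.perturbed):
            f_p = _output(model.spec.task, model.forward(Xp))
            metas.append(constraint_loss_grads(p, f_base, f_p)[0])
    comp = composite_loss(pred, metas, weights)
    return pred, metas, comp


def fit(
    model: MLP,
    X_train,
    y_train,
    X_val,
    y_val,
    priors: Sequence[PriorEffect] = (),
    weights: ConstraintWeights | None = None,
    config: TrainConfig = TrainConfig(),
    columns: Sequence[str] | None = None,
) -> FitResult:
    """Minimise the composite objective with Adam and early stopping.

    Inputs are expected pre-standardized and priors pre-converted to the
    standardized scale.  Per batch, the prediction loss is evaluated on the
    base inputs and each constraint on the base plus its perturbed copy;
    perturbed copies are rebuilt per batch so any upstream degradation of
    the inputs is reflected in them.  Early stopping monitors the
    validation composite loss (or prediction loss alone if configured),
    restores the best-epoch parameters and stops after ``patience`` epochs
    without improvement.
    """
    if isinstance(X_train, pd.DataFrame) and columns is None:
        columns = list(X_train.columns)
    Xtr = np.asarray(X_train, dtype=float)
    ytr = np.asarray(y_train, dtype=float).ravel()
    Xva = np.asarray(X_val, dtype=float)
    yva = np.asarray(y_val, dtype=float).ravel()
    priors = list(priors)
    if weights is None:
        if priors:
            raise ValueError("weights are required when priors are given")
        weights = ConstraintWeights(lambda0=1.0)
    if weights.n_priors != len(priors):
        raise ValueError("weights are not aligned with the prior list")

    col_idx = _resolve_columns(pd.DataFrame(Xtr, columns=columns) if columns else Xtr, priors, columns)
    pb_val = make_perturbed_inputs(pd.DataFrame(Xva, columns=columns), priors) if priors else None

    rng = np.random.default_rng(config.seed)
    opt = _Adam(model.parameters(), lr=config.learning_rate)
    n = Xtr.shape[0]
    task = model.spec.task

    best_val = np.inf
    best_params = model.get_flat()
    best_epoch = 0
    bad_epochs = 0
    rows = []
    epoch = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        ep_pred, ep_meta, n_batches = 0.0, np.zeros(len(priors)), 0
        for start in range(0, n, config.batch_size):
            take = order[start : start + config.batch_size]
            if take.size < 2:
                continue
            Xb, yb = Xtr[take], ytr[take]
            pb = PerturbedBatch(
                base=Xb,
                perturbed=tuple(
                    _shift(Xb, j, p.direction * p.step) for p, j in zip(priors, col_idx)
                ),
                directions=tuple(p.direction for p in priors),
                columns=tuple(col_idx),
                steps=tuple(p.step for p in priors),
            )
            z_base, f_base, cache_base, terms = _constraint_terms(model, pb, priors, True)
            pred_loss, d_pred = _pred_loss_grads(task, z_base, yb)

            d_base_total = weights.lambda0 * d_pred
            grads = None
            for lam, (loss, d_b, d_p, cache_p) in zip(weights.lambdas, terms):
                d_base_total = d_base_total + lam * d_b
                g = model.backward(cache_p, lam * d_p)
                grads = g if grads is None else [a + b for a, b in zip(grads, g)]
            g_base = model.backward(cache_base, d_base_total)
            grads = g_base if grads is None else [a + b for a, b in zip(grads, g_base)]

            total = composite_loss(pred_loss, [t[0] for t in terms], weights)
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: pred={pred_loss}, "
                    f"meta={[t[0] for t in terms]}"
                )
            opt.step(grads)
            ep_pred += pred_loss
            ep_meta += [t[0] for t in terms] if priors else 0.0
            n_batches += 1

        val_pred, val_metas, val_comp = _validation_losses(
            model, Xva, yva, priors, weights, pb_val
        )
        monitored = val_comp if config.monitor == "composite" else val_pred
        row = {
            "epoch": epoch,
            "train_pred": ep_pred / n_batches,
            "val_pred": val_pred,
            "val_monitored": monitored,
        }
        for i in range(len(priors)):
            row[f"train_meta_{i}"] = ep_meta[i] / n_batches
            row[f"val_meta_{i}"] = val_metas[i]
        rows.append(row)

        if monitored < best_val - 1e-12:
            best_val = monitored
            best_params = model.get_flat()
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break

    model.set_flat(best_params)
    return FitResult(
        model=model,
        history=pd.DataFrame(rows),
        best_epoch=best_epoch,
        stopped_epoch=epoch,
    )


def _shift(X: np.ndarray, col: int, delta: float) -> np.ndarray:
    Xp = X.copy()
    Xp[:, col] += delta
    return Xp
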