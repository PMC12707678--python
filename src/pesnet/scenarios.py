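"""Synthetic exposome-style scenarios and data-degradation operators.

The study design mimics a classic confounding triangle from environmental
epidemiology: fish intake is protective for the outcome while the mercury
it carries is harmful, and the two exposures are strongly correlated
(corr 0.8).  Two further predictors -- perceived stress (linear effect) and
BMI (nonlinear cosine effect, linear case only) -- are independent of the
pair.  Predictors are multivariate Gaussian with zero mean and unit
variances.

Two generative links are provided:

* linear:    Y = b0 + b1*x1 + b2*x2 + b3*x3 + b4*cos(x4),
             with b = (1, 1, -2, 5, 10); Y is deterministic given X.
* logistic:  p = sigmoid(b0 + b1*x1 + b2*x2 + b3*x3), b = (0, 1, -2, 5);
             the binary label is y = 1{p > 0.5} by default (the generative
             probability is itself deterministic in X), with Bernoulli
             sampling available via ``label_rule="bernoulli"``.

Degradations (Gaussian measurement noise, MCAR masking with mean
imputation, dropping a confounder while duplicating its correlate) apply
to training and validation splits only; the test split is never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LINEAR_BETAS",
    "LOGISTIC_BETAS",
    "LINEAR_COLUMNS",
    "LOGISTIC_COLUMNS",
    "Scenario",
    "Splits",
    "Standardizer",
    "linear_scenario",
    "logistic_scenario",
    "generate",
    "generate_splits",
    "add_gaussian_noise",
    "mcar_mean_impute",
    "drop_and_duplicate",
]

LINEAR_BETAS = (1.0, 1.0, -2.0, 5.0, 10.0)
LOGISTIC_BETAS = (0.0, 1.0, -2.0, 5.0)
LINEAR_COLUMNS = ("mercury", "fish_intake", "stress", "bmi")
LOGISTIC_COLUMNS = ("mercury", "fish_intake", "stress")


def _covariance(p: int, rho: float = 0.8) -> np.ndarray:
    cov = np.eye(p)
    cov[0, 1] = cov[1, 0] = rho
    return cov


@dataclass(frozen=True)
class Scenario:
    """A generative specification that emits named train/val/test splits."""

    link: str  # "linear" or "logistic"
    betas: tuple[float, ...]
    covariance: np.ndarray
    columns: tuple[str, ...]
    n_total: int = 1000
    split: tuple[int, int, int] = (600, 200, 200)
    seed: int = 0
    y_noise_sd: float = 0.0  # optional residual on the linear outcome
    label_rule: str = "threshold"  # logistic labels: "threshold" or "bernoulli"

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariance, dtype=float)
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("covariance must be positive definite")
        object.__setattr__(self, "covariance", cov)
        if sum(self.split) != self.n_total:
            raise ValueError("split must sum to n_total")
        if len(self.betas) != cov.shape[0] + 1:
            raise ValueError("betas must have one entry per predictor plus intercept")
        if self.link not in ("linear", "logistic"):
            raise ValueError("link must be 'linear' or 'logistic'")
        if self.label_rule not in ("threshold", "bernoulli"):
            raise ValueError("label_rule must be 'threshold' or 'bernoulli'")

    @property
    def n_predictors(self) -> int:
        return self.covariance.shape[0]

    # -- generative (reference) functions ----------------------------------

    def response(self, X) -> np.ndarray:
        """The noiseless generative function on raw inputs.

        Linear link: the outcome itself.  Logistic link: the Bernoulli
        probability.  This is the reference function Shapley attributions
        are computed against.
        """
        X = np.asarray(X, dtype=float)
        b = self.betas
        if self.link == "linear":
            return (
                b[0]
                + b[1] * X[:, 0]
                + b[2] * X[:, 1]
                + b[3] * X[:, 2]
                + b[4] * np.cos(X[:, 3])
            )
        logit = b[0] + X[:, :3] @ np.asarray(b[1:])
        return 1.0 / (1.0 + np.exp(-logit))

    def term_function(self, variable: str) -> Callable[[np.ndarray], np.ndarray]:
        """The additive term of one predictor (linear link only)."""
        if self.link != "linear":
            raise ValueError("per-term decomposition only defined for the linear link")
        j = self.columns.index(variable)
        coef = self.betas[j + 1]
        if variable == "bmi":
            return lambda x: coef * np.cos(x)
        return lambda x: coef * x


def linear_scenario(seed: int = 0, **overrides) -> Scenario:
    return Scenario(
        link="linear",
        betas=LINEAR_BETAS,
        covariance=_covariance(4),
        columns=LINEAR_COLUMNS,
        seed=seed,
        **overrides,
    )


def logistic_scenario(seed: int = 0, **overrides) -> Scenario:
    return Scenario(
        link="logistic",
        betas=LOGISTIC_BETAS,
        covariance=_covariance(3),
        columns=LOGISTIC_COLUMNS,
        seed=seed,
        **overrides,
    )


def generate(scenario: Scenario) -> tuple[pd.DataFrame, pd.Series]:
    """Draw (X, Y) for a scenario; bitwise reproducible given the seed."""
    rng = np.random.default_rng(scenario.seed)
    X = rng.multivariate_normal(
        mean=np.zeros(scenario.n_predictors),
        cov=scenario.covariance,
        size=scenario.n_total,
        method="cholesky",
    )
    if scenario.link == "linear":
        y = scenario.response(X)
        if scenario.y_noise_sd > 0:
            y = y + rng.normal(0.0, scenario.y_noise_sd, size=y.shape)
    else:
        p = scenario.response(X)
        if scenario.label_rule == "bernoulli":
            y = (rng.uniform(size=p.shape) < p).astype(float)
        else:
            y = (p > 0.5).astype(float)
    Xdf = pd.DataFrame(X, columns=list(scenario.columns))
    return Xdf, pd.Series(y, name="y")


@dataclass
class Splits:
    """Named train/validation/test partitions of one generated dataset."""

    X_train: pd.DataFrame
    y_train: pd.Series
    X_val: pd.DataFrame
    y_val: pd.Series
    X_test: pd.DataFrame
    y_test: pd.Series

    def map_X(self, fn, include_test: bool = False) -> "Splits":
        """Apply an input-matrix transform to train and validation (never test
        unless the transform is purely structural and include_test is set)."""
        return Splits(
            X_train=fn(self.X_train),
            y_train=self.y_train,
            X_val=fn(self.X_val),
            y_val=self.y_val,
            X_test=fn(self.X_test) if include_test else self.X_test,
            y_test=self.y_test,
        )


def generate_splits(scenario: Scenario) -> Splits:
    """Generate and partition by shuffled index with the scenario seed."""
    X, y = generate(scenario)
    rng = np.random.default_rng(scenario.seed + 1)
    order = rng.permutation(scenario.n_total)
    n_tr, n_va, _ = scenario.split
    idx_tr = order[:n_tr]
    idx_va = order[n_tr : n_tr + n_va]
    idx_te = order[n_tr + n_va :]
    take = lambda idx: (X.iloc[idx].reset_index(drop=True), y.iloc[idx].reset_index(drop=True))
    Xtr, ytr = take(idx_tr)
    Xva, yva = take(idx_va)
    Xte, yte = take(idx_te)
    return Splits(Xtr, ytr, Xva, yva, Xte, yte)


# ---------------------------------------------------------------------------
# Degradation operators (train/validation only; callers keep test pristine)
# ---------------------------------------------------------------------------


def add_gaussian_noise(
    X: pd.DataFrame,
    columns: Sequence[str],
    sd: float,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Additive N(0, sd^2) measurement noise on the listed columns."""
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    out = X.copy()
    for c in columns:
        if c not in X.columns:
            raise KeyError(f"unknown column {c!r}")
        if sd > 0:
            out[c] = out[c].to_numpy() + rng.normal(0.0, sd, size=len(out))
    return out


def mcar_mean_impute(
    X: pd.DataFrame,
    fraction: float,
    rng: np.random.Generator | int,
    means: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Mask cells completely at random and fill with column means.

    Each cell is masked independently with probability ``fraction``.  The
    imputation means are the per-column means of the *observed* cells; pass
    the means learned on the training split when degrading validation data
    so both splits share the same imputation model.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    values = X.to_numpy(dtype=float, copy=True)
    mask = rng.uniform(size=values.shape) < fraction
    if means is None:
        observed = np.where(mask, np.nan, values)
        if np.isnan(observed).all(axis=0).any():
            raise ValueError("a column was fully masked; cannot learn imputation means")
        means = pd.Series(np.nanmean(observed, axis=0), index=X.columns)
    values[mask] = np.broadcast_to(means.to_numpy(), values.shape)[mask]
    return pd.DataFrame(values, columns=X.columns, index=X.index), means


def drop_and_duplicate(
    X: pd.DataFrame,
    drop: str,
    duplicate: str,
    suffixes: tuple[str, str] = ("_constrained", "_free"),
) -> pd.DataFrame:
    """Remove one variable and present another twice.

    Emulates an unmeasured confounder: the dropped column is hidden from
    the model while its correlate appears as a constrained copy (to carry
    the literature effect) and a free copy (to absorb whatever the hidden
    confounder contributed).  Apply to every split so widths agree; it is
    structural, not a noise process.
    """
    if drop == duplicate:
        raise ValueError("drop and duplicate must differ")
    for c in (drop, duplicate):
        if c not in X.columns:
            raise KeyError(f"unknown column {c!r}")
    out = X.drop(columns=[drop]).copy()
    cols = list(out.columns)
    j = cols.index(duplicate)
    out = out.rename(columns={duplicate: duplicate + suffixes[0]})
    out.insert(j + 1, duplicate + suffixes[1], X[duplicate].to_numpy(copy=True))
    return out


class Standardizer:
    """Column-wise z-scoring with statistics learned on the training split.

    For regression the outcome is standardized as well; classification
    labels are left untouched.  The learned scales are also what converts
    raw-scale effect sizes into the network's standardized space.
    """

    def __init__(self, standardize_y: bool = True) -> None:
        self.standardize_y = standardize_y
        self.x_mean: pd.Series | None = None
        self.x_sd: pd.Series | None = None
        self.y_mean = 0.0
        self.y_sd = 1.0

    def fit(self, X_train: pd.DataFrame, y_train: pd.Series) -> "Standardizer":
        self.x_mean = X_train.mean()
        sd = X_train.std(ddof=0)
        if (sd <= 0).any():
            raise ValueError("a training column has zero variance")
        self.x_sd = sd
        if self.standardize_y:
            self.y_mean = float(y_train.mean())
            self.y_sd = float(y_train.std(ddof=0))
            if self.y_sd <= 0:
                raise ValueError("training outcome has zero variance")
        return self

    def transform_X(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.x_mean) / self.x_sd

    def transform_y(self, y: pd.Series) -> pd.Series:
        return (y - self.y_mean) / self.y_sd if self.standardize_y else y

    def inverse_y(self, y_std: np.ndarray) -> np.ndarray:
        return y_std * self.y_sd + self.y_mean if self.standardize_y else y_std

    def transform(self, splits: Splits) -> Splits:
        return Splits(
            X_train=self.transform_X(splits.X_train),
            y_train=self.transform_y(splits.y_train),
            X_val=self.transform_X(splits.X_val),
            y_val=self.transform_y(splits.y_val),
            X_test=self.transform_X(splits.X_test),
            y_test=self.transform_y(splits.y_test),
        )
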