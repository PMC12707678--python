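"""Literature effect-size constraints and the composite training loss.

A pooled effect size (PES) summarises an exposure--outcome association
aggregated across studies in a meta-analysis.  Three forms are supported:

* ``SRC`` -- standardized regression coefficient: a unit increase of the
  predictor shifts the (continuous) outcome by ``v``.
* ``OR`` -- odds ratio: a unit increase shifts the outcome log-odds by the
  log-OR ``v``.
* ``RR`` -- risk ratio: a unit increase multiplies the outcome rate by
  ``exp(v)`` (``v`` is the log-RR).

Each constraint is enforced as a *soft* penalty on the difference between a
network's predictions on a batch and on a copy of the batch in which the
constrained column is shifted by a perturbation step ``h``.  The penalties
are combined with the prediction loss through a convex weight vector, by
default derived from log-scaled confidence scores (meta-analysis sample
sizes for the priors, ``n_rows * n_cols`` for the data term).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EffectType",
    "PriorEffect",
    "ConstraintWeights",
    "PerturbedBatch",
    "compute_lambda_weights",
    "manual_lambda_weights",
    "default_perturbation",
    "perturbation_direction",
    "src_constraint_loss",
    "or_constraint_loss",
    "rr_constraint_loss",
    "odds_shift",
    "composite_loss",
    "standardize_priors",
    "load_prior_table",
    "priors_to_json",
    "priors_from_json",
    "weights_to_json",
    "weights_from_json",
]

PROB_EPS = 1e-6  # probabilities are clamped to [eps, 1-eps] before the odds transform


class EffectType(str, Enum):
    SRC = "SRC"
    OR = "OR"
    RR = "RR"


def default_perturbation(effect_type: EffectType | str, value: float) -> float:
    """Default perturbation step ``h`` for a constraint.

    SRC constraints use ``h = 1``; OR and RR constraints use ``1/v`` and
    ``-1/v`` respectively (``1`` when ``v = 0``) so that ``v * h`` stays of
    order one inside the exponential terms of the corresponding losses.
    """
    effect_type = EffectType(effect_type)
    if not np.isfinite(value):
        raise ValueError("effect-size value must be finite")
    if effect_type is EffectType.SRC:
        return 1.0
    if value == 0.0:
        return 1.0
    if effect_type is EffectType.OR:
        return 1.0 / value
    return -1.0 / value  # RR


def perturbation_direction(effect_type: EffectType | str) -> int:
    """Sign of the column shift: +h for SRC and RR, -h for OR.

    The OR loss is written in terms of the model's probability on inputs
    perturbed by ``-h``; the asymmetry is part of the loss definitions and
    must not be flipped silently.
    """
    return -1 if EffectType(effect_type) is EffectType.OR else 1


@dataclass(frozen=True)
class PriorEffect:
    """One literature-derived constraint on a single predictor.

    Parameters
    ----------
    variable:
        Column name of the constrained predictor.
    effect_type:
        One of :class:`EffectType`.  OR and RR values are stored on the log
        scale (an odds ratio of 1 is stored as ``value=0``).
    value:
        The pooled effect size on the scale of the data the network sees.
    confidence:
        Meta-analysis sample size; must exceed 1 for the log-confidence
        weighting to be defined.
    h:
        Perturbation step; derived from ``effect_type``/``value`` when None.
    ci_low, ci_high:
        Optional confidence-interval bounds, stored for provenance only.
    """

    variable: str
    effect_type: EffectType
    value: float
    confidence: float = 10_000.0
    h: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_type", EffectType(self.effect_type))
        if not np.isfinite(self.value):
            raise ValueError(f"prior on {self.variable!r}: value must be finite")
        if self.confidence <= 1:
            raise ValueError(
                f"prior on {self.variable!r}: confidence must exceed 1 "
                "(log-scale weighting requires ln(c) > 0)"
            )
        if self.h is not None and self.h == 0:
            raise ValueError(f"prior on {self.variable!r}: h must be nonzero")

    @property
    def step(self) -> float:
        """The perturbation step actually used (explicit ``h`` or default)."""
        if self.h is not None:
            return self.h
        return default_perturbation(self.effect_type, self.value)

    @property
    def direction(self) -> int:
        return perturbation_direction(self.effect_type)


@dataclass(frozen=True)
class ConstraintWeights:
    """Convex weights over {prediction task} U {priors}."""

    lambda0: float
    lambdas: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambdas", tuple(float(x) for x in self.lambdas))
        total = self.lambda0 + sum(self.lambdas)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {total!r}")
        if self.lambda0 <= 0 or any(l <= 0 for l in self.lambdas):
            raise ValueError("all weights must be strictly positive")

    @property
    def n_priors(self) -> int:
        return len(self.lambdas)


def compute_lambda_weights(
    priors: Sequence[PriorEffect], n_rows: int, n_cols: int
) -> ConstraintWeights:
    """Log-confidence weights: ``lambda_j = ln(c_j) / sum_k ln(c_k)``.

    The data term's confidence ``c_0`` is ``n_rows * n_cols``.  The log
    scale keeps small-confidence terms from being drowned out entirely.
    """
    c0 = float(n_rows) * float(n_cols)
    if c0 <= 1:
        raise ValueError("n_rows * n_cols must exceed 1")
    for p in priors:
        if p.confidence <= 1:
            raise ValueError(f"prior on {p.variable!r}: confidence must exceed 1")
    logs = np.array([np.log(c0)] + [np.log(p.confidence) for p in priors])
    w = logs / logs.sum()
    return ConstraintWeights(lambda0=float(w[0]), lambdas=tuple(w[1:]))


def manual_lambda_weights(lambda0: float, n_priors: int) -> ConstraintWeights:
    """Hyperparameter weighting: priors share ``1 - lambda0`` equally."""
    if n_priors == 0:
        return ConstraintWeights(lambda0=1.0)
    return ConstraintWeights(
        lambda0=lambda0, lambdas=(((1.0 - lambda0) / n_priors),) * n_priors
    )


@dataclass(frozen=True)
class PerturbedBatch:
    """A batch together with one single-column-shifted copy per prior."""

    base: np.ndarray
    perturbed: tuple[np.ndarray, ...]
    directions: tuple[int, ...]
    columns: tuple[int, ...]
    steps: tuple[float, ...]


# ---------------------------------------------------------------------------
# Constraint losses.  Each is the mean squared deviation from the identity a
# generalized linear model with coefficient v on the constrained column would
# satisfy exactly; the `_grads` variants additionally return d loss / d output
# for the base and perturbed batches (used by the training loop).
# ---------------------------------------------------------------------------


def _check_lengths(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"batch shapes differ: {a.shape} vs {b.shape}")
    return a, b


def src_constraint_loss(
    model_outputs_base: np.ndarray,
    model_outputs_perturbed: np.ndarray,
    value: float,
    h: float,
) -> float:
    """Mean of ``(f(X_{x+h}) - v*h - f(X))^2`` over the batch."""
    base, pert = _check_lengths(model_outputs_base, model_outputs_perturbed)
    resid = pert - value * h - base
    return float(np.mean(resid**2))


def _src_grads(base, pert, value, h):
    base, pert = _check_lengths(base, pert)
    resid = pert - value * h - base
    n = base.size
    return float(np.mean(resid**2)), -2.0 * resid / n, 2.0 * resid / n


def odds_shift(p_minus: np.ndarray, vh: float) -> np.ndarray:
    """Map a probability through a log-odds shift of ``+vh``.

    ``exp(vh) p / (exp(vh) p - p + 1)`` equals ``sigmoid(logit(p) + vh)``;
    it is the probability the model *should* assign to the unperturbed
    input if its log-odds respond to the constrained column with slope v.
    """
    a = np.exp(vh)
    p = np.asarray(p_minus, dtype=float)
    return a * p / ((a - 1.0) * p + 1.0)


def or_constraint_loss(
    probs_base: np.ndarray,
    probs_perturbed_minus_h: np.ndarray,
    value: float,
    h: float,
) -> float:
    """Mean squared gap between the odds-shifted perturbed probability and the base one.

    The perturbed batch must have been built with ``-h`` on the constrained
    column.  Probabilities are clamped away from {0, 1} before the odds
    transform to keep the denominator bounded.
    """
    p, pm = _check_lengths(probs_base, probs_perturbed_minus_h)
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    pm = np.clip(pm, PROB_EPS, 1.0 - PROB_EPS)
    resid = odds_shift(pm, value * h) - p
    return float(np.mean(resid**2))


def _or_grads(p, pm, value, h):
    p, pm = _check_lengths(p, pm)
    p = np.clip(p, PROB_EPS, 1.0 - PROB_EPS)
    pm = np.clip(pm, PROB_EPS, 1.0 - PROB_EPS)
    a = np.exp(value * h)
    denom = (a - 1.0) * pm + 1.0
    resid = a * pm / denom - p
    n = p.size
    d_p = -2.0 * resid / n
    d_pm = 2.0 * resid * a / denom**2 / n
    return float(np.mean(resid**2)), d_p, d_pm


def rr_constraint_loss(
    outputs_base: np.ndarray,
    outputs_perturbed_plus_h: np.ndarray,
    value: float,
    h: float,
) -> float:
    """Mean of ``(exp(-v*h) f(X_{x+h}) - f(X))^2`` for positive rate outputs."""
    base, pert = _check_lengths(outputs_base, outputs_perturbed_plus_h)
    bad = np.flatnonzero((base <= 0) | (pert <= 0))
    if bad.size:
        raise ValueError(
            f"rate outputs must be strictly positive (first offending batch index {bad[0]})"
        )
    resid = np.exp(-value * h) * pert - base
    return float(np.mean(resid**2))


def _rr_grads(base, pert, value, h):
    base, pert = _check_lengths(base, pert)
    scale = np.exp(-value * h)
    resid = scale * pert - base
    n = base.size
    return float(np.mean(resid**2)), -2.0 * resid / n, 2.0 * resid * scale / n


def constraint_loss_grads(prior: PriorEffect, base: np.ndarray, pert: np.ndarray):
    """Dispatch to the loss/gradient pair for a prior's effect type."""
    if prior.effect_type is EffectType.SRC:
        return _src_grads(base, pert, prior.value, prior.step)
    if prior.effect_type is EffectType.OR:
        return _or_grads(base, pert, prior.value, prior.step)
    return _rr_grads(base, pert, prior.value, prior.step)


def composite_loss(
    pred_loss: float,
    meta_losses: Sequence[float],
    weights: ConstraintWeights,
) -> float:
    """``lambda0 * pred + sum_i lambda_i * meta_i``."""
    if len(meta_losses) != weights.n_priors:
        raise ValueError(
            f"{len(meta_losses)} constraint losses but {weights.n_priors} weights"
        )
    return float(
        weights.lambda0 * pred_loss
        + sum(l * m for l, m in zip(weights.lambdas, meta_losses))
    )


# ---------------------------------------------------------------------------
# Scale conversion and IO
# ---------------------------------------------------------------------------


def standardize_priors(
    priors: Iterable[PriorEffect],
    x_scale: Mapping[str, float],
    y_scale: float = 1.0,
) -> list[PriorEffect]:
    """Convert raw-scale effect sizes to the standardized space the network sees.

    For a predictor standardized by its (training-set) standard deviation
    ``s_x``, a one-standard-deviation move corresponds to ``s_x`` raw units,
    so a raw slope ``v`` becomes ``v * s_x``.  SRC values are additionally
    divided by the outcome scale ``s_y``; OR/RR act on log-odds / log-rates,
    which are unaffected by output standardization.  The perturbation step
    is re-derived from the converted value unless it was set explicitly.
    """
    out = []
    for p in priors:
        sx = float(x_scale[p.variable])
        if sx <= 0:
            raise ValueError(f"scale for {p.variable!r} must be positive")
        if p.effect_type is EffectType.SRC:
            v = p.value * sx / float(y_scale)
        else:
            v = p.value * sx
        out.append(replace(p, value=v))
    return out


_PRIOR_FIELDS = ("variable", "effect_type", "value", "confidence", "h", "ci_low", "ci_high")


def load_prior_table(path) -> list[PriorEffect]:
    """Read a prior table CSV.

    Expected columns: ``variable, effect_type, value`` plus optional
    ``ci_low, ci_high, confidence, scale``.  OR/RR rows with
    ``scale == 'raw'`` (or missing) are given on the natural ratio scale
    and are log-transformed on load; ``scale == 'log'`` rows are stored
    as-is.  SRC rows ignore the log convention.
    """
    df = pd.read_csv(path)
    required = {"variable", "effect_type", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"prior table missing columns: {sorted(missing)}")
    priors = []
    for _, row in df.iterrows():
        etype = EffectType(str(row["effect_type"]).strip())
        value = float(row["value"])
        scale = str(row.get("scale", "raw") or "raw").strip()
        ci_low = row.get("ci_low")
        ci_high = row.get("ci_high")
        if etype is not EffectType.SRC and scale != "log":
            if value <= 0:
                raise ValueError(
                    f"{etype.value} for {row['variable']!r} on the natural scale must be positive"
                )
            value = float(np.log(value))
            ci_low = np.log(ci_low) if pd.notna(ci_low) else None
            ci_high = np.log(ci_high) if pd.notna(ci_high) else None
        priors.append(
            PriorEffect(
                variable=str(row["variable"]),
                effect_type=etype,
                value=value,
                confidence=float(row.get("confidence", 10_000.0)),
                ci_low=None if pd.isna(ci_low) else float(ci_low),
                ci_high=None if pd.isna(ci_high) else float(ci_high),
            )
        )
    return priors


def priors_to_json(priors: Sequence[PriorEffect]) -> str:
    records = []
    for p in priors:
        rec = {f: getattr(p, f) for f in _PRIOR_FIELDS}
        rec["effect_type"] = p.effect_type.value
        records.append(rec)
    return json.dumps(records, indent=2)


def priors_from_json(text: str) -> list[PriorEffect]:
    return [PriorEffect(**rec) for rec in json.loads(text)]


def weights_to_json(weights: ConstraintWeights) -> str:
    return json.dumps({"lambda0": weights.lambda0, "lambdas": list(weights.lambdas)})


def weights_from_json(text: str) -> ConstraintWeights:
    d = json.loads(text)
    return ConstraintWeights(lambda0=d["lambda0"], lambdas=tuple(d["lambdas"]))
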