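"""Explanation-fidelity and predictive metrics.

The fidelity score compares two dose-response profiles expressed as
Shapley attributions: one from a trained model, one from the generative
(reference) function, both estimated on the *same* background set with the
*same* sampling draws.  The per-variable distance is the mean absolute
difference of the attributions over the evaluation rows (lower = more
faithful).  Sharing draws between the two profiles makes the estimator's
Monte-Carlo error cancel in the difference, so a model that equals the
reference scores exactly zero.

Attributions are estimated with interventional permutation sampling: for
each evaluation row, features are revealed one at a time in a random
order on top of a randomly drawn background row, and each feature is
credited with the change in the function value when it is revealed.  This
is model-agnostic and satisfies the efficiency (local accuracy) axiom
exactly for every sampled permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import r2_score, roc_auc_score

__all__ = [
    "ShapSettings",
    "ShapProfile",
    "DeltaShapReport",
    "shap_profile",
    "delta_shap",
    "delta_shap_report",
    "predictive_metrics",
]


@dataclass(frozen=True)
class ShapSettings:
    """Sampling-estimator settings; keep identical across compared profiles."""

    n_samples: int = 256
    seed: int = 0


@dataclass
class ShapProfile:
    """Per-observation Shapley attributions over a fixed background set."""

    columns: tuple[str, ...]
    values: np.ndarray  # (n_eval, p)
    base_values: np.ndarray  # (n_eval,)
    predictions: np.ndarray  # f evaluated on the full rows, (n_eval,)
    background_id: str
    settings: ShapSettings

    def attributions(self, variable: str) -> np.ndarray:
        return self.values[:, self.columns.index(variable)]


def shap_profile(
    fn: Callable[[np.ndarray], np.ndarray],
    X_eval,
    X_background,
    settings: ShapSettings = ShapSettings(),
    background_id: str = "",
) -> ShapProfile:
    """Permutation-sampling Shapley attributions of ``fn`` on ``X_eval``.

    ``fn`` maps an (m, p) array to an (m,) output on the model's natural
    scale (probability for classifiers).  The random permutations and
    background draws depend only on ``settings.seed`` and the problem
    shape, so two profiles built with identical settings, evaluation and
    background sets use identical coalitions.
    """
    if isinstance(X_eval, pd.DataFrame):
        columns = tuple(X_eval.columns)
    else:
        columns = tuple(f"x{j}" for j in range(np.asarray(X_eval).shape[1]))
    Xe = np.asarray(X_eval, dtype=float)
    Xb = np.asarray(X_background, dtype=float)
    if Xe.ndim != 2 or Xb.ndim != 2 or Xe.shape[1] != Xb.shape[1]:
        raise ValueError("evaluation and background sets must share columns")
    n, p = Xe.shape
    M = settings.n_samples
    rng = np.random.default_rng(settings.seed)

    perms = rng.permuted(np.tile(np.arange(p), (n, M, 1)), axis=-1)
    bg_idx = rng.integers(0, Xb.shape[0], size=(n, M))

    Z = Xb[bg_idx]  # (n, M, p) -- start from pure background rows
    prev = fn(Z.reshape(-1, p)).reshape(n, M)
    base_values = prev.mean(axis=1)
    diffs = np.empty((n, M, p))
    x_expand = np.broadcast_to(Xe[:, None, :], (n, M, p))
    for s in range(p):
        j = perms[:, :, s]  # feature revealed at this step, (n, M)
        np.put_along_axis(Z, j[:, :, None], np.take_along_axis(x_expand, j[:, :, None], axis=-1), axis=-1)
        cur = fn(Z.reshape(-1, p)).reshape(n, M)
        diffs[:, :, s] = cur - prev
        prev = cur
    contrib = np.zeros((n, M, p))
    np.put_along_axis(contrib, perms, diffs, axis=-1)
    values = contrib.mean(axis=1)
    return ShapProfile(
        columns=columns,
        values=values,
        base_values=base_values,
        predictions=fn(Xe),
        background_id=background_id,
        settings=settings,
    )


def _pair(variable) -> tuple[str, str]:
    if isinstance(variable, str):
        return variable, variable
    a, b = variable
    return a, b


def delta_shap(profile_model: ShapProfile, profile_reference: ShapProfile, variable) -> float:
    """Mean absolute attribution difference for one variable.

    ``variable`` is a column name present in both profiles, or a pair
    ``(name_in_model, name_in_reference)`` when the model's inputs are
    renamed relative to the generative function (e.g. a duplicated
    predictor standing in for a hidden confounder).  Profiles must have
    been computed on the same background (checked via ``background_id``)
    and with identical estimator settings.
    """
    if profile_model.background_id != profile_reference.background_id:
        raise ValueError(
            "profiles are not comparable: backgrounds differ "
            f"({profile_model.background_id!r} vs {profile_reference.background_id!r})"
        )
    if profile_model.settings != profile_reference.settings:
        raise ValueError("profiles are not comparable: estimator settings differ")
    va, vb = _pair(variable)
    a = profile_model.attributions(va)
    b = profile_reference.attributions(vb)
    if a.shape != b.shape:
        raise ValueError("profiles cover different numbers of evaluation rows")
    return float(np.mean(np.abs(a - b)))


@dataclass
class DeltaShapReport:
    per_variable: dict[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.per_variable.values()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"variable": list(self.per_variable), "delta_shap": list(self.per_variable.values())}
        )
        return df


def delta_shap_report(
    profile_model: ShapProfile,
    profile_reference: ShapProfile,
    pairs: Mapping[str, str] | None = None,
) -> DeltaShapReport:
    """Per-variable fidelity scores plus their sum.

    ``pairs`` maps model column -> reference column; by default columns are
    matched by name.
    """
    if pairs is None:
        pairs = {c: c for c in profile_model.columns}
    per = {
        model_col: delta_shap(profile_model, profile_reference, (model_col, ref_col))
        for model_col, ref_col in pairs.items()
    }
    return DeltaShapReport(per_variable=per)


def predictive_metrics(y_true, y_pred, task: str) -> dict[str, float]:
    """R^2 for the regression tasks, ROC AUC for binary classification."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must be aligned")
    if task == "binary_classification":
        if np.unique(y_true).size < 2:
            raise ValueError("ROC AUC is undefined for single-class y_true")
        return {"auc": float(roc_auc_score(y_true, y_pred))}
    return {"r2": float(r2_score(y_true, y_pred))}
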