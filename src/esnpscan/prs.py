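"""Polygenic risk score: weight fitting, scoring, cross-validation, and
control-quantile enrichment.

The PRS is the weighted sum of risk-allele dosages, with weights taken from a
multivariate linear regression of case/control status on the dosage matrix (a
linear probability model solved by pseudoinverse, so collinear or constant
columns are handled).  Predictive value is summarized by the share of test
cases falling above the controls' upper (1-q) score quantile and below the
lower q quantile (q = 0.2 by default: top/bottom 20 percentiles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PrsModel",
    "QuantileEnrichment",
    "fit",
    "score",
    "quantile_enrichment",
    "kfold_evaluate",
    "transfer_evaluate",
    "mean_impute",
]


@dataclass
class PrsModel:
    """Per-variant weights + intercept mapping dosage vectors to risk scores."""

    variant_ids: list[str]
    weights: np.ndarray
    intercept: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.variant_ids),):
            raise ValueError("one weight per variant id required")


@dataclass
class QuantileEnrichment:
    """Share of cases in the control score distribution's outer quantiles."""

    top_fraction: float
    bottom_fraction: float
    q: float


def fit(
    dosages: np.ndarray,
    labels: Sequence[int],
    variant_ids: Sequence[str] | None = None,
    ridge: float = 0.0,
) -> PrsModel:
    """Least-squares linear probability model on a dosage matrix.

    Dosages are centered before solving, so constant columns receive weight
    exactly 0 (pseudoinverse convention) and the intercept absorbs the mean.
    ``ridge`` adds an optional L2 penalty for p ~ n settings.
    """
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(labels, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("dosages must be individuals x variants, one label each")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; cannot fit")
    if np.any((y != 0) & (y != 1)):
        raise ValueError("labels must be 0/1")
    for cls in (0, 1):
        if (y == cls).sum() < 2:
            raise ValueError(f"need >= 2 individuals with label {cls}")
    if variant_ids is None:
        variant_ids = [f"v{j}" for j in range(X.shape[1])]
    if len(variant_ids) != X.shape[1]:
        raise ValueError("variant_ids length must match dosage columns")

    mu = X.mean(axis=0)
    Xc = X - mu
    if ridge > 0.0:
        # ridge solution on centered predictors
        A = Xc.T @ Xc + ridge * np.eye(X.shape[1])
        w = np.linalg.solve(A, Xc.T @ (y - y.mean()))
    else:
        w = np.linalg.pinv(Xc) @ (y - y.mean())
    w[Xc.std(axis=0) == 0] = 0.0  # constant columns get exactly zero
    intercept = float(y.mean() - mu @ w)
    return PrsModel(list(variant_ids), w, intercept)


def score(model: PrsModel, dosages: np.ndarray,
          variant_ids: Sequence[str] | None = None) -> np.ndarray:
    """PRS = intercept + dosages @ weights (columns aligned by variant id)."""
    X = np.asarray(dosages, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosages must be a 2-D matrix")
    if variant_ids is not None:
        variant_ids = list(variant_ids)
        if set(variant_ids) != set(model.variant_ids):
            missing = sorted(set(model.variant_ids) - set(variant_ids))
            extra = sorted(set(variant_ids) - set(model.variant_ids))
            raise ValueError(
                f"dosage columns do not match model: missing {missing}, "
                f"extra {extra}"
            )
        order = [variant_ids.index(v) for v in model.variant_ids]
        X = X[:, order]
    elif X.shape[1] != len(model.variant_ids):
        raise ValueError(
            f"dosage matrix has {X.shape[1]} columns, model expects "
            f"{len(model.variant_ids)}"
        )
    return model.intercept + X @ model.weights


def quantile_enrichment(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    q: float = 0.2,
) -> QuantileEnrichment:
    """Fractions of cases strictly above/below the control (1-q)/q quantiles."""
    cases = np.asarray(case_scores, dtype=float)
    controls = np.asarray(control_scores, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score lists must be non-empty")
    if not 0.0 < q < 0.5 + 1e-12:
        raise ValueError(f"q must be in (0, 0.5], got {q}")
    lo, hi = np.quantile(controls, [q, 1.0 - q])
    return QuantileEnrichment(
        top_fraction=float(np.mean(cases > hi)),
        bottom_fraction=float(np.mean(cases < lo)),
        q=q,
    )


def kfold_evaluate(
    dosages: np.ndarray,
    labels: Sequence[int],
    k: int = 10,
    q: float = 0.2,
    seed: int = 0,
    ridge: float = 0.0,
) -> dict:
    """Stratified k-fold cross-validated quantile enrichment.

    Per fold: fit on the other k-1 folds, score the held-out fold, and
    compute quantile enrichment of that fold's cases against its controls.
    Returns the per-fold results plus mean/sd summaries.
    """
    X = np.asarray(dosages, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_min = min((y == 0).sum(), (y == 1).sum())
    if k > n_min:
        raise ValueError(f"k={k} exceeds the smaller class size ({n_min})")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: list[QuantileEnrichment] = []
    for train_idx, test_idx in skf.split(X, y):
        model = fit(X[train_idx], y[train_idx], ridge=ridge)
        s = score(model, X[test_idx])
        y_te = y[test_idx]
        folds.append(quantile_enrichment(s[y_te == 1], s[y_te == 0], q=q))
    tops = np.array([f.top_fraction for f in folds])
    bottoms = np.array([f.bottom_fraction for f in folds])
    return {
        "folds": folds,
        "mean_top": float(tops.mean()),
        "sd_top": float(tops.std(ddof=1)),
        "mean_bottom": float(bottoms.mean()),
        "sd_bottom": float(bottoms.std(ddof=1)),
        "k": k,
        "q": q,
    }


def transfer_evaluate(
    train_dosages: np.ndarray,
    train_labels: Sequence[int],
    test_dosages: np.ndarray,
    test_labels: Sequence[int],
    subsample: float = 0.9,
    reps: int = 10,
    q: float = 0.2,
    seed: int = 0,
    ridge: float = 0.0,
) -> dict:
    """Train on one cohort, evaluate on repeated subsamples of another.

    The model is fit once on the full training cohort; the test cohort is
    subsampled (without replacement, ``subsample`` fraction) ``reps`` times
    and quantile enrichment computed per replicate.
    """
    model = fit(train_dosages, train_labels, ridge=ridge)
    X_te = np.asarray(test_dosages, dtype=float)
    y_te = np.asarray(test_labels, dtype=int)
    rng = np.random.default_rng(seed)
    m = int(round(subsample * X_te.shape[0]))
    reps_out: list[QuantileEnrichment] = []
    for _ in range(reps):
        idx = rng.choice(X_te.shape[0], size=m, replace=False)
        s = score(model, X_te[idx])
        y_s = y_te[idx]
        if (y_s == 1).sum() == 0 or (y_s == 0).sum() == 0:
            continue
        reps_out.append(quantile_enrichment(s[y_s == 1], s[y_s == 0], q=q))
    tops = np.array([r.top_fraction for r in reps_out])
    bottoms = np.array([r.bottom_fraction for r in reps_out])
    return {
        "reps": reps_out,
        "mean_top": float(tops.mean()),
        "mean_bottom": float(bottoms.mean()),
        "model": model,
    }


def mean_impute(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Replace NaN dosages by their column mean; returns (matrix, imputed mask)."""
    X = np.asarray(dosages, dtype=float).copy()
    mask = np.isnan(X)
    if mask.any():
        means = np.nanmean(X, axis=0)
        X[mask] = np.take(means, np.nonzero(mask)[1])
    return X, mask
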