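"""Classifiers, metrics, and the randomized hyperparameter search.

Handcrafted features are classified with gradient-boosted trees
(XGBoost) — a nonlinear learner over simple scalar descriptors; deep
image features are classified with L2-regularised logistic regression,
on the assumption that the backbone already captured the nonlinear
structure and a high-dimensional linear model overfits least.

Hyperparameters are tuned by uniform randomized search over fixed
candidate grids, scored by mean balanced accuracy (BACC) under
stratified k-fold cross-validation.  All preprocessing that can leak —
median imputation of missing features, standardisation for the linear
model — lives inside an sklearn Pipeline so it is refitted on each
training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

__all__ = [
    "Metrics",
    "compute_metrics",
    "metrics_from_predictions",
    "ModelSpec",
    "CVPlan",
    "XGB_SEARCH_SPACE",
    "LR_SEARCH_SPACE",
    "default_model_spec",
    "make_estimator",
    "random_search",
]

POSITIVE_LABEL = "PD"


# ------------------------------------------------------------------ metrics


@dataclass(frozen=True)
class Metrics:
    """Binary-classification metrics with their confusion counts.

    sen = TP/(TP+FN), spe = TN/(TN+FP), bacc = (sen+spe)/2,
    f1 = 2TP/(2TP+FP+FN).  A ratio with an empty class is NaN, never 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sen: float
    spe: float
    bacc: float
    f1: float


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> Metrics:
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + tn + fp + fn == 0:
        raise ValueError("empty confusion table")
    sen = tp / (tp + fn) if (tp + fn) > 0 else np.nan
    spe = tn / (tn + fp) if (tn + fp) > 0 else np.nan
    bacc = (sen + spe) / 2
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else np.nan
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn, sen=sen, spe=spe,
                   bacc=bacc, f1=f1)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return compute_metrics(tp, tn, fp, fn)


# ------------------------------------------------------- model search space

XGB_SEARCH_SPACE: dict[str, list] = {
    "learning_rate": [0.001, 0.01, 0.1, 0.2, 0.3],
    "gamma": [0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.5],
    "max_depth": [6, 8, 10, 12, 15],
    "subsample": [0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "colsample_bylevel": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "colsample_bytree": [0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0],
    "min_child_weight": [0.5, 1.0, 3.0, 5.0, 7.0, 10.0],
    "scale_pos_weight": [1, 2, 3, 4],
}

LR_SEARCH_SPACE: dict[str, list] = {
    "C": [0.001, 0.01, 0.1, 1, 10, 100, 1000],
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family with its hyperparameter candidate grid."""

    family: str  # gradient_boosted_trees | l2_logistic
    search_space: dict[str, list] = field(default_factory=dict)
    n_search: int = 500
    n_estimators: int = 100  # boosting rounds, fixed (not searched)

    def with_budget(self, n_search: int) -> "ModelSpec":
        return replace(self, n_search=n_search)


def default_model_spec(feature_kind: str, n_search: int = 500) -> ModelSpec:
    """gradient-boosted trees for handcrafted features, L2 logistic for deep."""
    if feature_kind == "handcrafted":
        return ModelSpec("gradient_boosted_trees", dict(XGB_SEARCH_SPACE),
                         n_search)
    if feature_kind == "deep":
        return ModelSpec("l2_logistic", dict(LR_SEARCH_SPACE), n_search)
    raise ValueError(f"unknown feature kind {feature_kind!r}")


@dataclass(frozen=True)
class CVPlan:
    """Stratified repeated k-fold plan: outer evaluation 5x5 by default,
    inner tuning folds for the nested hyperparameter search."""

    n_folds: int = 5
    n_repeats: int = 5
    inner_folds: int = 5
    inner_repeats: int = 1
    seed: int = 0


# ---------------------------------------------------------------- pipeline


def make_estimator(spec: ModelSpec, params: dict, seed: int) -> Pipeline:
    """Leakage-safe pipeline: fold-internal median imputation, then the
    classifier (plus standardisation for the linear model)."""
    steps = [
        ("impute", SimpleImputer(strategy="median", keep_empty_features=True))
    ]
    if spec.family == "gradient_boosted_trees":
        steps.append((
            "clf",
            XGBClassifier(
                n_estimators=spec.n_estimators,
                random_state=seed,
                n_jobs=1,
                tree_method="hist",
                eval_metric="logloss",
                **params,
            ),
        ))
    elif spec.family == "l2_logistic":
        steps.append(("scale", StandardScaler()))
        steps.append((
            "clf",
            LogisticRegression(max_iter=5000, random_state=seed, **params),
        ))
    else:
        raise ValueError(f"unknown model family {spec.family!r}")
    return Pipeline(steps)


def _draw_params(space: dict[str, list], rng: np.random.Generator) -> dict:
    return {k: v[rng.integers(len(v))] for k, v in space.items()}


def random_search(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    spec: ModelSpec,
    plan: CVPlan,
    seed: int,
) -> tuple[dict, pd.DataFrame]:
    """Uniform randomized search scored by mean cross-validated BACC.

    Draws ``spec.n_search`` configurations (with replacement) from the
    grid, scores each by mean BACC over stratified inner folds, and
    returns the argmax; ties break in favour of the earlier draw.
    Degenerate single-class folds are skipped.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    rng = np.random.default_rng(seed)
    est_seed = int(rng.integers(2**31))

    splits = []
    for rep in range(plan.inner_repeats):
        skf = StratifiedKFold(
            n_splits=plan.inner_folds, shuffle=True,
            random_state=(est_seed + rep) % 2**31,
        )
        splits.extend(skf.split(X, y))
    # skip folds whose training part is single-class
    splits = [(tr, te) for tr, te in splits if len(np.unique(y[tr])) == 2]

    draws = [_draw_params(spec.search_space, rng) for _ in range(spec.n_search)]
    scores = np.empty(len(draws))
    cache: dict[tuple, float] = {}  # identical draws are scored once
    for i, params in enumerate(draws):
        key = tuple(sorted(params.items()))
        if key not in cache:
            fold_scores = []
            for tr, te in splits:
                est = make_estimator(spec, params, est_seed)
                est.fit(X[tr], y[tr])
                m = metrics_from_predictions(y[te], est.predict(X[te]))
                fold_scores.append(m.bacc)
            cache[key] = np.nanmean(fold_scores) if fold_scores else np.nan
        scores[i] = cache[key]
    best = int(np.nanargmax(scores))
    log = pd.DataFrame({
        "draw": np.arange(len(draws)),
        "mean_bacc": scores,
        "params": [repr(p) for p in draws],
    })
    return draws[best], log
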