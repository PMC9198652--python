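"""Multilingual evaluation scenarios: SL, LOLO, and ALC.

Three scenarios probe how handwriting-based PD classification transfers
across languages:

* single language (SL) — train and test within one language; internal
  validation of the features.
* leave one language out (LOLO) — train on the pooled remaining
  languages, test once on the held-out language; external validation
  with a single confusion table (no variance estimate).
* all languages combined (ALC) — pool everything and run the SL
  protocol on the mixed cohort.

SL and ALC use nested evaluation: stratified 5-fold cross-validation
with 5 repetitions on the outside, and inside each outer training fold
a randomized hyperparameter search scored by inner cross-validated
balanced accuracy.  All decisions are per subject (one recording per
subject and task).  Every run is bit-reproducible given its seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import Pipeline

from .evaluation import (
    CVPlan,
    Metrics,
    ModelSpec,
    default_model_spec,
    make_estimator,
    metrics_from_predictions,
    random_search,
)

__all__ = [
    "ScenarioResult",
    "run_single_language",
    "run_all_languages_combined",
    "run_leave_one_language_out",
    "feature_importance",
    "summarize_tables",
]

META_COLUMNS = ("subject_id", "label", "language", "task")
MIN_SUBJECTS = 10


@dataclass
class ScenarioResult:
    scenario: str  # SL | LOLO | ALC
    task: str
    feature_kind: str
    language: str  # language analysed (SL), held out (LOLO), or 'ALL'
    per_split: list[Metrics]
    importance: list[tuple[str, float]] = field(default_factory=list)
    chosen_params: list[dict] = field(default_factory=list)
    seed: int = 0

    def mean(self, metric: str = "bacc") -> float:
        return float(np.nanmean([getattr(m, metric) for m in self.per_split]))

    def sd(self, metric: str = "bacc") -> float:
        return float(np.nanstd([getattr(m, metric) for m in self.per_split],
                               ddof=1)) if len(self.per_split) > 1 else np.nan

    def summary(self) -> dict[str, float]:
        out = {}
        for m in ("bacc", "f1", "sen", "spe"):
            out[f"{m}_mean"] = self.mean(m)
            out[f"{m}_sd"] = self.sd(m)
        return out


def _split_features(dataset: pd.DataFrame):
    feature_cols = [c for c in dataset.columns if c not in META_COLUMNS]
    X = dataset[feature_cols].to_numpy(dtype=float)
    y = (dataset["label"] == "PD").to_numpy().astype(int)
    return X, y, feature_cols


def _nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec,
    plan: CVPlan,
    seed: int,
) -> tuple[list[Metrics], list[dict]]:
    """Outer repeated stratified CV; per-split nested randomized search."""
    outer = RepeatedStratifiedKFold(
        n_splits=plan.n_folds, n_repeats=plan.n_repeats,
        random_state=seed % 2**31,
    )
    ss = np.random.SeedSequence(seed)
    split_seeds = ss.generate_state(outer.get_n_splits(X, y) * 2)
    per_split: list[Metrics] = []
    chosen: list[dict] = []
    for k, (tr, te) in enumerate(outer.split(X, y)):
        s_search = int(split_seeds[2 * k] % 2**31)
        s_fit = int(split_seeds[2 * k + 1] % 2**31)
        params, _ = random_search(X[tr], y[tr], spec, plan, s_search)
        est = make_estimator(spec, params, s_fit)
        est.fit(X[tr], y[tr])
        per_split.append(metrics_from_predictions(y[te], est.predict(X[te])))
        chosen.append(params)
    return per_split, chosen


def _final_model(
    X: np.ndarray, y: np.ndarray, spec: ModelSpec, plan: CVPlan, seed: int
) -> Pipeline:
    """Model fitted on all rows with searched hyperparameters; used only
    for feature-importance reporting."""
    params, _ = random_search(X, y, spec, plan, seed)
    est = make_estimator(spec, params, seed % 2**31)
    est.fit(X, y)
    return est


def _run_pooled(
    dataset: pd.DataFrame,
    scenario: str,
    language: str,
    task: str,
    feature_kind: str,
    seed: int,
    spec: ModelSpec | None,
    plan: CVPlan,
) -> ScenarioResult:
    if len(dataset) < MIN_SUBJECTS:
        raise ValueError(
            f"{scenario} needs at least {MIN_SUBJECTS} subjects, "
            f"got {len(dataset)}"
        )
    spec = spec or default_model_spec(feature_kind)
    X, y, names = _split_features(dataset)
    per_split, chosen = _nested_cv(X, y, spec, plan, seed)
    final = _final_model(X, y, spec, plan, seed + 1)
    imp = feature_importance(final, names)
    return ScenarioResult(
        scenario=scenario, task=task, feature_kind=feature_kind,
        language=language, per_split=per_split, importance=imp,
        chosen_params=chosen, seed=seed,
    )


def run_single_language(
    dataset: pd.DataFrame,
    language: str,
    task: str,
    feature_kind: str = "handcrafted",
    seed: int = 0,
    spec: ModelSpec | None = None,
    plan: CVPlan = CVPlan(),
) -> ScenarioResult:
    """Internal validation within one language (stratified 5x5 CV)."""
    subset = dataset[
        (dataset["language"] == language) & (dataset["task"] == task)
    ].reset_index(drop=True)
    return _run_pooled(subset, "SL", language, task, feature_kind, seed,
                       spec, plan)


def run_all_languages_combined(
    dataset: pd.DataFrame,
    task: str,
    feature_kind: str = "handcrafted",
    seed: int = 0,
    spec: ModelSpec | None = None,
    plan: CVPlan = CVPlan(),
) -> ScenarioResult:
    """The SL protocol on the pooled multilingual cohort."""
    subset = dataset[dataset["task"] == task].reset_index(drop=True)
    return _run_pooled(subset, "ALC", "ALL", task, feature_kind, seed,
                       spec, plan)


def run_leave_one_language_out(
    dataset: pd.DataFrame,
    held_out_language: str,
    task: str,
    feature_kind: str = "handcrafted",
    seed: int = 0,
    spec: ModelSpec | None = None,
    plan: CVPlan = CVPlan(),
) -> ScenarioResult:
    """External validation: tune and fit on the other languages, evaluate
    once on the held-out language (single confusion table)."""
    subset = dataset[dataset["task"] == task]
    langs = set(subset["language"])
    if held_out_language not in langs:
        raise ValueError(f"held-out language {held_out_language!r} absent")
    if len(langs) < 2:
        raise ValueError("LOLO requires at least 2 languages")
    train = subset[subset["language"] != held_out_language].reset_index(drop=True)
    test = subset[subset["language"] == held_out_language].reset_index(drop=True)
    spec = spec or default_model_spec(feature_kind)
    Xtr, ytr, names = _split_features(train)
    Xte, yte, _ = _split_features(test)
    params, _ = random_search(Xtr, ytr, spec, plan, seed)
    est = make_estimator(spec, params, seed % 2**31)
    est.fit(Xtr, ytr)
    m = metrics_from_predictions(yte, est.predict(Xte))
    imp = feature_importance(est, names)
    return ScenarioResult(
        scenario="LOLO", task=task, feature_kind=feature_kind,
        language=held_out_language, per_split=[m], importance=imp,
        chosen_params=[params], seed=seed,
    )


def feature_importance(
    model: Pipeline, feature_names: list[str], k: int = 10
) -> list[tuple[str, float]]:
    """Top-k features, weights normalised to sum 1 over the k.

    Tree ensembles rank by total gain; the logistic path uses absolute
    standardised coefficients as a proxy (features are standardised in
    the pipeline, so coefficients are directly comparable).
    """
    clf = model.named_steps["clf"]
    if hasattr(clf, "get_booster"):
        gain = clf.get_booster().get_score(importance_type="total_gain")
        weights = np.zeros(len(feature_names))
        for key, val in gain.items():
            weights[int(key[1:])] = val  # keys look like 'f12'
    elif hasattr(clf, "coef_"):
        weights = np.abs(clf.coef_).ravel()
    else:
        raise ValueError("model exposes neither gain nor coefficients")
    order = np.argsort(weights)[::-1][: min(k, len(feature_names))]
    top = [(feature_names[i], float(weights[i])) for i in order]
    total = sum(w for _, w in top)
    if total > 0:
        top = [(n, w / total) for n, w in top]
    else:
        warnings.warn("all importance weights are zero")
    return top


def summarize_tables(results: list[ScenarioResult]) -> dict[str, pd.DataFrame]:
    """Per-scenario report tables plus cross-scenario means (2 decimals).

    SL/ALC rows show mean +- sd over the 25 outer splits; LOLO rows are
    point values from the single held-out confusion table.  Missing
    metrics render as '-' in the formatted columns.
    """
    rows = []
    for r in results:
        row = {
            "scenario": r.scenario, "task": r.task, "language": r.language,
            "features": r.feature_kind,
        }
        for m in ("bacc", "f1", "sen", "spe"):
            mean, sd = r.mean(m), r.sd(m)
            row[m] = mean
            if r.scenario == "LOLO":
                row[f"{m}_fmt"] = "-" if np.isnan(mean) else f"{mean:.2f}"
            else:
                row[f"{m}_fmt"] = (
                    "-" if np.isnan(mean) else f"{mean:.2f} ± {sd:.2f}"
                )
        rows.append(row)
    detail = pd.DataFrame(rows)
    tables = {"detail": detail}
    if len(detail):
        cross = (
            detail.groupby(["scenario", "task", "features"])[
                ["bacc", "f1", "sen", "spe"]
            ]
            .mean()
            .round(2)
            .reset_index()
        )
        tables["cross_language_means"] = cross
    return tables
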