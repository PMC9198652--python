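"""Metrics identities, randomized search, scenario protocol, importance."""

import numpy as np
import pandas as pd
import pytest

from graphomotor.evaluation import (
    CVPlan,
    ModelSpec,
    compute_metrics,
    default_model_spec,
    make_estimator,
    metrics_from_predictions,
    random_search,
)
from graphomotor.scenarios import (
    ScenarioResult,
    feature_importance,
    run_single_language,
    summarize_tables,
)

SMALL_PLAN = CVPlan(n_folds=3, n_repeats=1, inner_folds=3, inner_repeats=1)


def _toy_dataset(n=40, n_features=6, informative=0, sep=3.0, seed=0,
                 language="CZ"):
    """Balanced PD/HC table where one column optionally carries signal."""
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    X = rng.normal(size=(n, n_features))
    if informative is not None:
        X[:, informative] += sep * y
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)])
    df.insert(0, "subject_id", [f"s{i}" for i in range(n)])
    df.insert(1, "label", np.where(y == 1, "PD", "HC"))
    df.insert(2, "language", language)
    df.insert(3, "task", "spiral")
    return df


class TestMetrics:
    def test_basic_confusion(self):
        m = compute_metrics(tp=8, fn=2, tn=6, fp=4)
        assert m.sen == pytest.approx(0.8)
        assert m.spe == pytest.approx(0.6)
        assert m.bacc == pytest.approx(0.7)

    def test_degenerate_all_positive_prediction(self):
        # predicting every subject as PD: SEN 1.00, SPE 0.00 -> BACC 0.50
        m = compute_metrics(tp=17, fn=0, tn=0, fp=10)
        assert m.sen == 1.0
        assert m.spe == 0.0
        assert m.bacc == 0.5

    def test_perfect_classifier(self):
        m = compute_metrics(tp=10, fn=0, tn=10, fp=0)
        assert m.bacc == 1.0
        assert m.f1 == 1.0

    def test_empty_class_is_missing_not_zero(self):
        m = compute_metrics(tp=5, fn=5, tn=0, fp=0)
        assert np.isnan(m.spe)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)

    def test_identities_hold_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(1, 30, size=4)
            m = compute_metrics(tp, tn, fp, fn)
            assert m.bacc == pytest.approx((m.sen + m.spe) / 2)
            assert m.f1 == pytest.approx(2 * tp / (2 * tp + fp + fn))


class TestRandomSearch:
    def test_single_configuration_returned(self):
        df = _toy_dataset()
        X = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
        y = (df["label"] == "PD").to_numpy().astype(int)
        spec = ModelSpec("l2_logistic", {"C": [1.0]}, n_search=20)
        params, log = random_search(X, y, spec, SMALL_PLAN, seed=0)
        assert params == {"C": 1.0}
        assert len(log) == 20

    def test_separating_configuration_wins(self):
        # C = 1e-12 is so regularised it predicts near-constant labels;
        # C = 10 separates the informative column cleanly
        df = _toy_dataset(sep=8.0)
        X = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
        y = (df["label"] == "PD").to_numpy().astype(int)
        spec = ModelSpec("l2_logistic", {"C": [1e-12, 10.0]}, n_search=30)
        params, _ = random_search(X, y, spec, SMALL_PLAN, seed=1)
        assert params == {"C": 10.0}

    def test_same_seed_same_log(self):
        df = _toy_dataset()
        X = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
        y = (df["label"] == "PD").to_numpy().astype(int)
        spec = default_model_spec("handcrafted", n_search=6)
        _, log_a = random_search(X, y, spec, SMALL_PLAN, seed=42)
        _, log_b = random_search(X, y, spec, SMALL_PLAN, seed=42)
        pd.testing.assert_frame_equal(log_a, log_b)


class TestLeakageControl:
    def test_training_unaffected_by_test_rows(self):
        """Sentinel audit: rows outside the training fold cannot change
        the tuned hyperparameters, the fitted model, or the imputation."""
        df = _toy_dataset(n=40, seed=5)
        X = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
        y = (df["label"] == "PD").to_numpy().astype(int)
        train_idx = np.arange(0, 30)
        probe = X[:10]

        X_b = X.copy()
        X_b[30:, 0] = 1e6  # sentinel values in the held-out rows only
        X_b[30:, 1] = np.nan

        spec = default_model_spec("handcrafted", n_search=4)
        p_a, log_a = random_search(X[train_idx], y[train_idx], spec,
                                   SMALL_PLAN, seed=9)
        p_b, log_b = random_search(X_b[train_idx], y[train_idx], spec,
                                   SMALL_PLAN, seed=9)
        assert p_a == p_b
        pd.testing.assert_frame_equal(log_a, log_b)

        est_a = make_estimator(spec, p_a, seed=9)
        est_a.fit(X[train_idx], y[train_idx])
        est_b = make_estimator(spec, p_b, seed=9)
        est_b.fit(X_b[train_idx], y[train_idx])
        np.testing.assert_array_equal(
            est_a.named_steps["impute"].statistics_,
            est_b.named_steps["impute"].statistics_,
        )
        np.testing.assert_array_equal(est_a.predict(probe), est_b.predict(probe))


class TestScenarioProtocol:
    def test_refuses_tiny_cohort(self):
        df = _toy_dataset(n=8)
        with pytest.raises(ValueError, match="at least"):
            run_single_language(df, "CZ", "spiral", seed=0, plan=SMALL_PLAN)

    def test_deterministic_rerun(self):
        df = _toy_dataset(n=30, seed=2)
        spec = default_model_spec("handcrafted", n_search=3)
        a = run_single_language(df, "CZ", "spiral", seed=7, spec=spec,
                                plan=SMALL_PLAN)
        b = run_single_language(df, "CZ", "spiral", seed=7, spec=spec,
                                plan=SMALL_PLAN)
        assert a.per_split == b.per_split
        assert a.chosen_params == b.chosen_params
        assert a.importance == b.importance

    def test_stratification_of_outer_folds(self):
        from sklearn.model_selection import RepeatedStratifiedKFold

        y = np.array([1] * 13 + [0] * 17)
        outer = RepeatedStratifiedKFold(n_splits=5, n_repeats=5,
                                        random_state=0)
        global_prop = y.mean()
        for _, te in outer.split(np.zeros((30, 1)), y):
            # class proportion off by at most one subject per fold
            assert abs(y[te].sum() - global_prop * len(te)) <= 1

    def test_label_permutation_hits_chance_band(self):
        df = _toy_dataset(n=60, sep=8.0, seed=4)
        rng = np.random.default_rng(0)
        df["label"] = rng.permutation(df["label"].to_numpy())
        spec = default_model_spec("handcrafted", n_search=3)
        res = run_single_language(df, "CZ", "spiral", seed=3, spec=spec,
                                  plan=CVPlan(n_folds=5, n_repeats=2,
                                              inner_folds=3))
        assert 0.35 <= res.mean("bacc") <= 0.65


class TestImportance:
    def test_single_informative_feature_ranks_first(self):
        df = _toy_dataset(n=60, sep=6.0, seed=6)
        X = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
        y = (df["label"] == "PD").to_numpy().astype(int)
        spec = default_model_spec("handcrafted")
        est = make_estimator(spec, {"max_depth": 3, "learning_rate": 0.3},
                             seed=0)
        est.fit(X, y)
        names = [c for c in df.columns if c.startswith("f")]
        imp = feature_importance(est, names, k=10)
        assert imp[0][0] == "f0"
        assert sum(w for _, w in imp) == pytest.approx(1.0, abs=1e-9)

    def test_k_larger_than_feature_count(self):
        df = _toy_dataset(n=40, seed=8)
        X = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
        y = (df["label"] == "PD").to_numpy().astype(int)
        spec = default_model_spec("deep")
        est = make_estimator(spec, {"C": 1.0}, seed=0)
        est.fit(X, y)
        names = [c for c in df.columns if c.startswith("f")]
        imp = feature_importance(est, names, k=50)
        assert len(imp) == len(names)


class TestSummaries:
    def _result(self, scenario, language, baccs):
        splits = []
        for bacc in baccs:
            tp = tn = int(round(bacc * 10))
            fp = fn = 10 - tp
            splits.append(metrics_from_predictions(
                np.array([1] * 10 + [0] * 10),
                np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp),
            ))
        return ScenarioResult(scenario=scenario, task="sentence",
                              feature_kind="handcrafted", language=language,
                              per_split=splits)

    def test_lolo_cross_language_mean(self):
        results = [
            self._result("LOLO", lang, [b])
            for lang, b in zip(["CZ", "CO", "HU", "US"],
                               [0.6, 0.6, 0.7, 0.7])
        ]
        tables = summarize_tables(results)
        cross = tables["cross_language_means"]
        assert cross.loc[0, "bacc"] == pytest.approx(0.65)

    def test_rounding_to_two_decimals(self):
        results = [self._result("ALC", "ALL", [0.6, 0.6, 0.6, 0.6, 0.7])]
        tables = summarize_tables(results)
        assert tables["cross_language_means"].loc[0, "bacc"] == 0.62

    def test_single_result_single_row(self):
        tables = summarize_tables([self._result("SL", "CZ", [0.8, 0.9])])
        assert len(tables["detail"]) == 1
        assert "±" in tables["detail"].loc[0, "bacc_fmt"]
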