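"""Error metrics, grouped CV, selection searches and SHAP explanations."""

import numpy as np
import pandas as pd
import pytest

import ovresponse as ov
from ovresponse.model import ModelConfig

from conftest import make_cohort


class TestErrorMetrics:
    def test_hand_example(self):
        m = ov.error_metrics([3, 3], [2, 4])
        assert m.rmse == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)
        assert m.mape == pytest.approx(0.375)

    def test_perfect_predictions(self):
        m = ov.error_metrics([2, 5, 9], [2, 5, 9])
        assert (m.rmse, m.mae, m.mape) == (0.0, 0.0, 0.0)

    def test_zero_actuals_excluded_from_mape_only(self):
        m = ov.error_metrics([1, 3], [0, 4])
        assert m.mape == pytest.approx(0.25)
        assert m.n_mape_excluded == 1
        assert m.rmse == pytest.approx(np.sqrt((1 + 1) / 2))

    def test_rmse_dominates_mae(self):
        rng = np.random.default_rng(0)
        pred, act = rng.normal(5, 2, 50), rng.integers(0, 12, 50)
        m = ov.error_metrics(pred, act)
        assert m.rmse >= m.mae >= 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ov.error_metrics([], [])


class TestTrivialBaseline:
    def test_closed_form(self):
        m = ov.trivial_baseline([2, 4, 6])
        assert m.rmse == pytest.approx(np.sqrt(8 / 3))

    def test_constant_outcomes(self):
        assert ov.trivial_baseline([5, 5, 5]).rmse == 0.0


class TestGroupedCV:
    def data(self, n=200, seed=0, signal=True):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"x1": rng.normal(size=n), "x2": rng.normal(size=n)},
            index=[f"pr{i}" for i in range(n)],
        )
        y = (
            np.clip(10 + 3 * X["x1"].to_numpy() + rng.normal(0, 0.3, n), 0, None)
            if signal
            else rng.poisson(5, n).astype(float)
        )
        patients = [f"pt{i // 2}" for i in range(n)]
        return X, y, patients

    def test_no_patient_spans_folds(self):
        _, _, patients = self.data()
        folds = ov.assign_grouped_folds(patients, 5, seed=1)
        df = pd.DataFrame({"p": patients, "f": folds})
        assert (df.groupby("p")["f"].nunique() == 1).all()
        assert set(folds) == set(range(5))

    def test_strong_predictor_beats_baseline(self):
        X, y, patients = self.data()
        res = ov.train_gbm_cv(X, y, patients, ModelConfig(seed=3))
        assert res.metrics.rmse < 0.5 * ov.trivial_baseline(y).rmse

    def test_seed_determinism(self):
        X, y, patients = self.data()
        a = ov.train_gbm_cv(X, y, patients, ModelConfig(seed=3))
        b = ov.train_gbm_cv(X, y, patients, ModelConfig(seed=3))
        assert a.metrics.rmse == b.metrics.rmse
        pd.testing.assert_series_equal(a.oof_predictions, b.oof_predictions)

    def test_missing_features_handled_natively(self):
        X, y, patients = self.data()
        X.loc[X.index[:40], "x2"] = np.nan
        res = ov.train_gbm_cv(X, y, patients, ModelConfig(seed=1))
        assert np.isfinite(res.metrics.rmse)

    def test_tiny_fold_rejected(self):
        X, y, patients = self.data(n=12)
        with pytest.raises(ValueError, match="fewer than 5"):
            ov.train_gbm_cv(X, y, patients, ModelConfig(seed=0))


class TestForwardSelect:
    def test_planted_predictor_accepted_nulls_rejected(self):
        rng = np.random.default_rng(4)
        n = 400
        X = pd.DataFrame(
            {f"n{i}": rng.normal(size=n) for i in range(4)}
            | {"signal": rng.normal(size=n)},
            index=[f"pr{i}" for i in range(n)],
        )
        y = np.clip(12 + 4 * X["signal"].to_numpy() + rng.normal(0, 0.5, n), 0, None)
        patients = [f"pt{i // 2}" for i in range(n)]
        trace = ov.forward_select(X, y, patients, ModelConfig(seed=2))
        assert "signal" in trace.selected
        assert trace.iterations.iloc[0]["candidate"] == "signal"
        accepted = trace.iterations[trace.iterations["accepted"]]
        assert (accepted["rmse_with"] < accepted["rmse_without"]).all()

    def test_empty_candidates_gives_baseline_trace(self):
        y = [1, 5, 3, 7] * 3
        trace = ov.forward_select(
            pd.DataFrame(index=range(12)), y, [f"p{i}" for i in range(12)],
            ModelConfig(seed=0, n_folds=2),
        )
        assert trace.selected == []
        assert trace.baseline_rmse == pytest.approx(ov.trivial_baseline(y).rmse)


class TestCombinationSearch:
    def run_search(self, n_genetic, seed=0):
        rng = np.random.default_rng(seed)
        n = 120
        clin = pd.DataFrame({"amh": rng.normal(3, 1, n)},
                            index=[f"pr{i}" for i in range(n)])
        gen = pd.DataFrame(
            {f"g{i}": rng.binomial(1, 0.5, n).astype(float)
             for i in range(n_genetic)},
            index=clin.index,
        )
        y = 2 * clin["amh"].to_numpy() + rng.normal(0, 1, n)
        patients = [f"pt{i // 2}" for i in range(n)]
        return ov.genetic_combination_search(
            gen, clin, y, patients, ModelConfig(seed=1)
        )

    def test_enumeration_sizes(self):
        _, table = self.run_search(1)
        assert len(table) == 1
        _, table = self.run_search(3)
        assert len(table) == 7  # 2^3 - 1

    def test_full_seven_feature_search_has_127_rows(self):
        _, table = self.run_search(7)
        assert len(table) == 127  # 2^7 - 1

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(9)
        n = 500
        clin = pd.DataFrame({"amh": rng.normal(3, 1, n)},
                            index=[f"pr{i}" for i in range(n)])
        gen = pd.DataFrame(
            {f"g{i}": rng.binomial(1, 0.5, n).astype(float) for i in range(5)},
            index=clin.index,
        )
        y = (2 * clin["amh"] + 3 * gen["g1"] + 3 * gen["g3"]
             + rng.normal(0, 0.5, n)).to_numpy()
        best, _ = ov.genetic_combination_search(
            gen, clin, y, [f"pt{i // 2}" for i in range(n)], ModelConfig(seed=4)
        )
        assert {"g1", "g3"} <= set(best)


class TestShap:
    def toy_model(self, seed=0, constant_col=False):
        rng = np.random.default_rng(seed)
        n = 400
        X = pd.DataFrame(
            {
                "a": rng.binomial(1, 0.5, n).astype(float),
                "b": rng.binomial(1, 0.5, n).astype(float),
            }
        )
        if constant_col:
            X["c"] = 1.0
        y = 3 * X["a"].to_numpy() + X["b"].to_numpy()
        res = ov.train_gbm_cv(
            X, y, [f"pt{i // 2}" for i in range(n)],
            ModelConfig(seed=1, min_child_samples=5),
        )
        return res.model, X, y

    def test_constant_feature_has_zero_importance(self):
        model, X, _ = self.toy_model(constant_col=True)
        imp = ov.shap_importance(model, X)
        assert imp["c"] == pytest.approx(0.0, abs=1e-12)

    def test_additivity_everywhere(self):
        model, X, _ = self.toy_model()
        contrib, base = ov.shap_values(model, X)
        pred = model.predict(X)
        np.testing.assert_allclose(base + contrib.sum(axis=1), pred, atol=1e-6)

    def test_matches_exhaustive_coalition_shapley(self):
        # two balanced independent binary features: TreeSHAP equals the
        # brute-force Shapley value over the 2^2 coalitions with the
        # empirical background distribution
        model, X, _ = self.toy_model()

        def v(coalition, x):
            # expected prediction with features outside the coalition
            # marginalised over the training background
            Xb = X.copy()
            for f in coalition:
                Xb[f] = x[f]
            return model.predict(Xb).mean()

        x = pd.Series({"a": 1.0, "b": 0.0})
        phi_a = 0.5 * (v(["a"], x) - v([], x)) + 0.5 * (
            v(["a", "b"], x) - v(["b"], x)
        )
        phi_b = 0.5 * (v(["b"], x) - v([], x)) + 0.5 * (
            v(["a", "b"], x) - v(["a"], x)
        )
        contrib, base = ov.shap_values(model, x.to_frame().T)
        np.testing.assert_allclose(contrib[0], [phi_a, phi_b], atol=0.02)

    def test_explain_patient_decomposition(self):
        model, X, _ = self.toy_model()
        exp = ov.explain_patient(model, X.iloc[7])
        assert exp.base_value + exp.contributions.sum() == pytest.approx(
            exp.prediction, abs=1e-6
        )
        assert exp.cumulative_genetic_impact(["b"]) == pytest.approx(
            exp.contributions["b"]
        )

    def test_constant_model_all_zero_contributions(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame({"a": rng.normal(size=100)})
        y = np.full(100, 4.0)
        res = ov.train_gbm_cv(
            X, y, [f"pt{i // 2}" for i in range(100)], ModelConfig(seed=0)
        )
        contrib, base = ov.shap_values(res.model, X)
        np.testing.assert_allclose(contrib, 0.0, atol=1e-9)
        np.testing.assert_allclose(base, 4.0, atol=1e-9)

    def test_schema_mismatch_rejected(self):
        model, X, _ = self.toy_model()
        with pytest.raises(ValueError, match="schema"):
            ov.shap_importance(model, X.rename(columns={"a": "z"}))
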