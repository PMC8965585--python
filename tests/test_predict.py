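"""Selection, normalisation, LOOCV leakage, fusion, and suite contracts."""

import numpy as np
import pytest

from painfusion import synthetic as syn
from painfusion.containers import FeatureTable, ModelSpec
from painfusion.model import (
    CorrelationSelector,
    SingleTypeRegressor,
    correlation_pvalues,
    make_backend,
)
from painfusion.predict import (
    SUITE_DEFINITIONS,
    fuse_predictions,
    loocv_predict,
    run_model_suite,
    select_features,
    zscore_apply,
    zscore_fit,
)


class TestSelectFeatures:
    def test_target_copy_is_selected(self, rng):
        y = rng.normal(size=50)
        X = np.column_stack([y, rng.normal(size=(50, 5))])
        sel = select_features(X, y, 0.001)
        assert 0 in sel

    def test_constant_column_excluded(self, rng):
        y = rng.normal(size=30)
        X = np.column_stack([np.full(30, 2.0), y])
        sel = select_features(X, y, 0.05)
        assert 0 not in sel and 1 in sel

    def test_planted_support_recall(self):
        """Strong planted weights, n=200: recall of the support >= 0.9 at
        p < 0.01."""
        recalls = []
        for seed in range(5):
            cfg = syn.GeneratorConfig(
                n_subjects=200, n_regional_features=100,
                n_connectivity_features=100, n_planted=10, seed=seed,
            )
            tables, y = syn.simulate_feature_tables(cfg)
            for t, tab in tables.items():
                support = np.flatnonzero(tab.feature_meta["planted"].to_numpy())
                sel = select_features(tab.matrix, y.threshold_J, 0.01)
                recalls.append(np.isin(support, sel).mean())
        assert np.mean(recalls) >= 0.9

    def test_constant_target_rejected(self, rng):
        with pytest.raises(ValueError, match="constant target"):
            select_features(rng.normal(size=(20, 3)), np.ones(20), 0.05)

    def test_pvalues_match_scipy(self, rng):
        from scipy.stats import pearsonr

        X = rng.normal(size=(40, 8))
        y = rng.normal(size=40)
        r, p = correlation_pvalues(X, y)
        for j in range(8):
            rr = pearsonr(X[:, j], y)
            assert r[j] == pytest.approx(rr.statistic, abs=1e-12)
            assert p[j] == pytest.approx(rr.pvalue, rel=1e-9)


class TestZscore:
    def test_standard_column_unchanged(self, rng):
        x = rng.normal(size=(200, 1))
        x = (x - x.mean()) / x.std()
        stats = zscore_fit(x)
        assert np.allclose(zscore_apply(stats, x), x, atol=1e-10)

    def test_train_statistics_property(self, rng):
        X = rng.normal(loc=3, scale=2, size=(50, 4))
        z = zscore_apply(zscore_fit(X), X)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0), 1, atol=1e-12)

    def test_test_rows_use_train_stats(self):
        train = np.array([[0.0], [2.0]])
        z = zscore_apply(zscore_fit(train), np.array([[2.0]]))
        assert z[0, 0] == pytest.approx(1.0)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero-sd"):
            zscore_fit(np.ones((10, 1)))


class TestBackends:
    def test_linear_svr_epsilon_tube(self, rng):
        x = rng.normal(size=(80, 1))
        y = 2.0 + 3.0 * x[:, 0]
        m = make_backend("svr_linear", {"epsilon": 0.01}).fit(x, y)
        assert np.abs(m.predict(x) - y).max() < 0.02

    def test_rf_seeded_determinism(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        a = make_backend("rf", {"n_estimators": 20}, seed=5).fit(X, y).predict(X)
        b = make_backend("rf", {"n_estimators": 20}, seed=5).fit(X, y).predict(X)
        assert np.array_equal(a, b)

    def test_plsr_rank_one_recovery(self, rng):
        w = rng.normal(size=5)
        X = rng.normal(size=(60, 5))
        y = X @ w
        m = make_backend("plsr", {"n_components": 1}, n_features=5, n_samples=60)
        # PLSR with enough components fits exactly; 1 component on a
        # rank-1 relation already explains nearly everything after
        # deflation of the single predictive direction
        m = make_backend("plsr", {"n_components": 5}, n_features=5, n_samples=60)
        m.fit(X, y)
        pred = np.asarray(m.predict(X)).ravel()
        ss_res = ((pred - y) ** 2).sum()
        ss_tot = ((y - y.mean()) ** 2).sum()
        assert 1 - ss_res / ss_tot > 0.99

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            make_backend("boost")


class TestSingleTypeRegressor:
    def test_sklearn_estimator_contract(self, rng):
        """clone/get_params round-trip, NotFittedError before fit, and
        feature-count validation at predict time."""
        from sklearn.base import clone
        from sklearn.exceptions import NotFittedError

        est = SingleTypeRegressor(algorithm="svr_rbf", selection_p=0.05, seed=1)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        with pytest.raises(NotFittedError):
            est.predict(np.zeros((2, 3)))
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + 0.1 * rng.normal(size=30)
        est.fit(X, y)
        with pytest.raises(ValueError):
            est.predict(np.zeros((2, 3)))  # wrong feature count

    def test_works_inside_sklearn_model_selection(self, rng):
        from sklearn.model_selection import cross_val_predict

        X = rng.normal(size=(40, 6))
        y = X[:, 1] + 0.2 * rng.normal(size=40)
        pred = cross_val_predict(SingleTypeRegressor(selection_p=0.05), X, y, cv=5)
        assert np.corrcoef(pred, y)[0, 1] > 0.5

    def test_fitted_attributes(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 2] + 0.1 * rng.normal(size=40)
        est = SingleTypeRegressor(selection_p=0.01).fit(X, y)
        assert 2 in est.selected_idx_
        assert not est.empty_selection_
        assert est.predict(X).shape == (40,)

    def test_empty_selection_falls_back_to_mean(self, rng):
        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        est = SingleTypeRegressor(selection_p=1e-12).fit(X, y)
        assert est.empty_selection_
        assert np.allclose(est.predict(X[:3]), y.mean())

    def test_get_set_params_round_trip(self):
        est = SingleTypeRegressor(algorithm="svr_rbf", selection_p=0.05, seed=3)
        clone = SingleTypeRegressor(**est.get_params())
        assert clone.get_params() == est.get_params()


class TestLoocv:
    def test_fold_count_equals_subjects(self, small_cohort):
        _, tables, y = small_cohort
        spec = ModelSpec(("reho",), {"reho": "svr_linear"}, {"reho": 0.01})
        res = loocv_predict(tables["reho"], y, spec)
        assert res.n_subjects == 80
        assert len(res.per_fold_selected) == 80

    def test_no_label_leakage(self, small_cohort):
        """Perturbing a held-out subject's threshold leaves that fold's
        selection and prediction bit-identical."""
        _, tables, y = small_cohort
        spec = ModelSpec(("fa",), {"fa": "svr_rbf"}, {"fa": 0.05})
        res1 = loocv_predict(tables["fa"], y, spec)
        k = 17
        y2 = y.threshold_J.copy()
        y2[k] += 10.0
        res2 = loocv_predict(tables["fa"], y2, spec)
        assert res1.predicted[k] == res2.predicted[k]
        assert np.array_equal(res1.per_fold_selected[k]["fa"], res2.per_fold_selected[k]["fa"])

    def test_noise_only_predictions_have_no_positive_skill(self):
        """Out-of-fold correlation on pure-noise tables shows no spurious
        skill. Fold-wise screening is anti-selective on null features (a
        column enters exactly in the folds whose held-out subject weakens
        it), so the null distribution of r is centred at or below zero,
        never above."""
        rs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 60))
            y = 2.5 + 0.5 * rng.normal(size=100)
            import pandas as pd

            meta = pd.DataFrame({"type": ["reho"] * 60, "vx": 0, "vy": 0, "vz": 0})
            tab = FeatureTable(X, meta)
            spec = ModelSpec(("reho",), {"reho": "svr_linear"}, {"reho": 0.01})
            res = loocv_predict(tab, y, spec)
            if np.ptp(res.predicted) > 0:
                rs.append(np.corrcoef(res.predicted, y)[0, 1])
        assert np.mean(rs) < 0.1  # no spurious positive skill

    def test_reproducibility(self, small_cohort):
        _, tables, y = small_cohort
        spec = ModelSpec(("sc",), {"sc": "svr_rbf"}, {"sc": 0.01}, seed=5)
        a = loocv_predict(tables["sc"], y, spec)
        b = loocv_predict(tables["sc"], y, spec)
        assert np.array_equal(a.predicted, b.predicted)


class TestFusion:
    def _make_result(self, pred, y, ftype="reho"):
        from painfusion.containers import PredictionResult

        n = len(pred)
        return PredictionResult(
            predicted=np.asarray(pred, float),
            true=np.asarray(y, float),
            per_fold_selected=[{ftype: np.array([0])} for _ in range(n)],
            model_spec=ModelSpec((ftype,)),
        )

    def test_identical_constituents_idempotent(self):
        y = [2.0, 3.0, 2.5, 2.25, 3.5]
        a = self._make_result([2.1, 2.9, 2.4, 2.5, 3.0], y, "reho")
        b = self._make_result([2.1, 2.9, 2.4, 2.5, 3.0], y, "fa")
        fused = fuse_predictions([a, b])
        assert np.array_equal(fused.predicted, a.predicted)

    def test_mean_of_two(self):
        y = [2.0] * 5
        a = self._make_result([2.0] * 5, y, "reho")
        b = self._make_result([4.0] * 5, y, "fa")
        assert np.all(fuse_predictions([a, b]).predicted == 3.0)

    def test_mismatched_subjects_rejected(self):
        a = self._make_result([1.0] * 5, [2.0] * 5, "reho")
        b = self._make_result([1.0] * 5, [2.1] * 5, "fa")
        with pytest.raises(ValueError, match="disagree"):
            fuse_predictions([a, b])

    def test_selection_log_union(self):
        y = [2.0] * 5
        a = self._make_result([2.0] * 5, y, "reho")
        b = self._make_result([4.0] * 5, y, "fc")
        fused = fuse_predictions([a, b])
        assert set(fused.per_fold_selected[0]) == {"reho", "fc"}


class TestModelSuite:
    def test_nine_models_and_fusion_identities(self, small_cohort):
        _, tables, y = small_cohort
        suite = run_model_suite(tables, y, seed=2)
        assert set(suite) == set(SUITE_DEFINITIONS)
        singles = {t: suite[n] for n, t in
                   [("ReHo", "reho"), ("FC", "fc"), ("FA", "fa"), ("SC", "sc")]}
        fused = np.mean([singles[t].predicted for t in ("reho", "fc", "fa", "sc")], axis=0)
        assert np.allclose(suite["Fused"].predicted, fused, atol=1e-12)
        regional = (singles["reho"].predicted + singles["fa"].predicted) / 2
        assert np.allclose(suite["Regional"].predicted, regional, atol=1e-12)

    def test_missing_table_named(self, small_cohort):
        _, tables, y = small_cohort
        partial = {k: v for k, v in tables.items() if k != "sc"}
        with pytest.raises(ValueError, match="'sc'"):
            run_model_suite(partial, y)

    def test_suite_reproducible(self, small_cohort):
        _, tables, y = small_cohort
        a = run_model_suite(tables, y, seed=9)
        b = run_model_suite(tables, y, seed=9)
        for name in a:
            assert np.array_equal(a[name].predicted, b[name].predicted)
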