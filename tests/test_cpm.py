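"""CPM: exclusion, fold residualization, bootstrap selection, LOOCV, metrics."""

import numpy as np
import numpy.testing as npt
import pandas as pd
import pytest

from conncpm.cpm import (
    CPM,
    CPMConfig,
    _run_fold,
    bootstrap_select,
    consistent_features,
    cpm_permutation,
    critical_r,
    edge_correlations,
    evaluate_predictions,
    exclude_missing,
    fit_predict_fold,
    intersect_features,
    loocv_cpm,
    residualize_scores_fold,
    strengths,
)
from conncpm.synthetic import SynthConfig, simulate_cohort
from conftest import conditioned_planted_cohort


def planted_cohort(seed=11, n_rois=60):
    """Cohort whose two planted edges carry a strong negative score signal.

    sigma_score is set from the closed form of the per-edge correlation
    r = g su^2 / (sqrt(su^2 + sw^2) sqrt(P g^2 su^2 + ss^2)) so |r| = 0.6
    in expectation.  Recovery assertions use
    :func:`conftest.conditioned_planted_cohort` so the realized strength is
    actually near 0.6.
    """
    cfg = SynthConfig(n_rois=n_rois, planted_edge_count=2,
                      planted_weight_mean=6000.0, planted_weight_sd=0.0,
                      sigma_score=1881.0, seed=seed)
    return simulate_cohort(cfg)


class TestExcludeMissing:
    def test_default_cohort_52_of_55(self):
        lat = simulate_cohort(SynthConfig(n_rois=10, seed=0))
        edges, cohort = exclude_missing(lat.fingerprint_matrix(0), lat.cohort)
        assert edges.shape[0] == 52
        assert len(cohort) == 52

    def test_none_missing_identity(self, rng):
        cohort = pd.DataFrame({"subject_id": list("abc"), "mvic": [1.0, 2.0, 3.0]})
        edges = rng.normal(size=(3, 4))
        out, kept = exclude_missing(edges, cohort)
        npt.assert_array_equal(out, edges)
        assert len(kept) == 3

    def test_order_preserved(self, rng):
        mvic = [1.0, np.nan, 3.0, np.nan, 5.0, 6.0, np.nan, 8.0, 9.0, np.nan]
        cohort = pd.DataFrame({"subject_id": [f"s{k}" for k in range(10)],
                               "mvic": mvic})
        _, kept = exclude_missing(rng.normal(size=(10, 2)), cohort)
        assert kept.subject_id.tolist() == ["s0", "s2", "s4", "s5", "s7", "s8"]

    def test_all_missing_raises(self, rng):
        cohort = pd.DataFrame({"subject_id": ["a", "b"], "mvic": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="all subjects"):
            exclude_missing(rng.normal(size=(2, 2)), cohort)


class TestFoldResidualization:
    def test_zero_covariate_effects_reduce_to_mean_removal(self, rng):
        scores = rng.normal(size=20)
        cov = np.zeros((20, 2))  # degenerate design; least-norm warning expected
        with pytest.warns(UserWarning, match="singular"):
            train_res, test_res = residualize_scores_fold(cov[1:], scores[1:],
                                                          cov[:1], scores[0])
        npt.assert_allclose(train_res, scores[1:] - scores[1:].mean(), atol=1e-10)
        assert test_res[0] == pytest.approx(scores[0] - scores[1:].mean())

    def test_exactly_linear_scores_residual_zero(self, rng):
        cov = rng.normal(size=(30, 2))
        scores = 4.0 + 2.0 * cov[:, 0] - 1.5 * cov[:, 1]
        train_res, test_res = residualize_scores_fold(cov[1:], scores[1:],
                                                      cov[:1], scores[0])
        npt.assert_allclose(train_res, 0.0, atol=1e-9)
        assert test_res[0] == pytest.approx(0.0, abs=1e-9)

    def test_test_subject_never_influences_training(self, rng):
        cov = rng.normal(size=(15, 2))
        scores = rng.normal(size=15)
        a, _ = residualize_scores_fold(cov[1:], scores[1:], cov[:1], scores[0])
        b, _ = residualize_scores_fold(cov[1:], scores[1:], cov[:1], scores[0] + 1e6)
        npt.assert_array_equal(a, b)

    def test_single_sex_fold_warns_not_fails(self, rng):
        cov = np.column_stack([rng.normal(size=12), np.ones(12)])
        with pytest.warns(UserWarning, match="singular"):
            residualize_scores_fold(cov, rng.normal(size=12), cov[:1], 0.0)


class TestEdgeCorrelations:
    def test_perfect_correlations(self, rng):
        y = rng.normal(size=10)
        edges = np.column_stack([y, -y])
        r, p = edge_correlations(edges, y)
        npt.assert_allclose(r, [1.0, -1.0], atol=1e-12)
        assert p[0] < 1e-10

    def test_matches_scipy_pearsonr(self, rng):
        from scipy import stats

        edges = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        r, p = edge_correlations(edges, y)
        for e in range(6):
            rr, pp = stats.pearsonr(edges[:, e], y)
            assert r[e] == pytest.approx(rr, abs=1e-12)
            assert p[e] == pytest.approx(pp, abs=1e-10)

    def test_constant_edge_never_selected(self, rng):
        edges = np.column_stack([np.full(10, 3.0), rng.normal(size=10)])
        r, p = edge_correlations(edges, rng.normal(size=10))
        assert np.isnan(r[0]) and p[0] == 1.0

    def test_critical_r_equivalence(self, rng):
        """p < alpha exactly when |r| > critical_r(n, alpha)."""
        for n in (10, 25, 40):
            edges = rng.normal(size=(n, 200))
            y = rng.normal(size=n)
            r, p = edge_correlations(edges, y)
            for alpha in (0.01, 0.005, 0.001):
                npt.assert_array_equal(p < alpha, np.abs(r) > critical_r(n, alpha))


class TestBootstrapSelect:
    def test_planted_edges_retained_negative(self):
        lat = conditioned_planted_cohort(11)
        edges, cohort = exclude_missing(lat.fingerprint_matrix(0), lat.cohort)
        y = cohort.mvic.to_numpy()
        X = np.column_stack([np.ones(len(y)), cohort.age, cohort.sex])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        cfg = CPMConfig(fst=0.01, n_boot=200, seed=0)
        pos, neg, _ = bootstrap_select(edges, resid, cfg, np.random.default_rng(0))
        assert np.all(neg[lat.planted_edges])
        assert not pos[lat.planted_edges].any()

    def test_noise_edges_rarely_retained(self, rng):
        edges = rng.normal(size=(40, 500))
        y = rng.normal(size=40)
        cfg = CPMConfig(fst=0.001, n_boot=100, seed=0)
        pos, neg, _ = bootstrap_select(edges, y, cfg, np.random.default_rng(1))
        assert (pos.sum() + neg.sum()) <= 5  # <= 1% of 500 edges

    def test_deterministic_under_seed(self, rng):
        edges = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        cfg = CPMConfig(fst=0.05, n_boot=50)
        out1 = bootstrap_select(edges, y, cfg, np.random.default_rng(9))
        out2 = bootstrap_select(edges, y, cfg, np.random.default_rng(9))
        for a, b in zip(out1, out2):
            npt.assert_array_equal(a, b)

    def test_empty_selection_is_not_an_error(self, rng):
        edges = rng.normal(size=(15, 20))
        y = rng.normal(size=15)
        cfg = CPMConfig(fst=0.0001, n_boot=20)
        pos, neg, _ = bootstrap_select(edges, y, cfg, np.random.default_rng(2))
        assert not pos.any() and not neg.any()


class TestStrengths:
    def test_single_negative_edge(self, rng):
        edges = rng.normal(size=(5, 3))
        pos = np.zeros(3, dtype=bool)
        neg = np.array([False, True, False])
        _, neg_s, flags = strengths(edges, pos, neg)
        npt.assert_allclose(neg_s, edges[:, 1])
        assert flags["positive_empty"] and not flags["negative_empty"]

    def test_mean_of_two_edges(self):
        edges = np.array([[1.0, 3.0]])
        pos = np.array([True, True])
        pos_s, _, _ = strengths(edges, pos, np.zeros(2, dtype=bool))
        assert pos_s[0] == pytest.approx(2.0)

    def test_matches_bruteforce(self, rng):
        edges = rng.normal(size=(8, 12))
        pos = rng.uniform(size=12) < 0.4
        neg = ~pos & (rng.uniform(size=12) < 0.4)
        pos_s, neg_s, _ = strengths(edges, pos, neg)
        npt.assert_allclose(pos_s, edges[:, pos].mean(axis=1))
        npt.assert_allclose(neg_s, edges[:, neg].mean(axis=1))


class TestFitPredictFold:
    def test_noiseless_linear_exact(self, rng):
        d = rng.normal(size=20)
        y = 3.0 - 2.0 * d
        pred, flagged = fit_predict_fold(d, y, 0.7)
        assert pred[0] == pytest.approx(3.0 - 1.4, abs=1e-10)
        assert not flagged

    def test_constant_predictor_falls_back_to_mean(self):
        pred, flagged = fit_predict_fold(np.zeros(10), np.arange(10.0), 0.0)
        assert pred[0] == pytest.approx(4.5)
        assert flagged


class TestEvaluatePredictions:
    def test_perfect_prediction(self, rng):
        y = rng.normal(size=15)
        m = evaluate_predictions(y, y)
        assert m["r"] == pytest.approx(1.0)
        assert m["r_squared"] == pytest.approx(1.0)
        assert m["rmse"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_prediction(self, rng):
        y = rng.normal(size=15)
        m = evaluate_predictions(np.full(15, y.mean()), y)
        assert m["r_squared"] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(m["r"])

    def test_matches_direct_formulas(self, rng):
        from scipy import stats

        pred, obs = rng.normal(size=20), rng.normal(size=20)
        m = evaluate_predictions(pred, obs)
        assert m["r"] == pytest.approx(stats.pearsonr(pred, obs)[0], abs=1e-12)
        sse = ((obs - pred) ** 2).sum()
        sst = ((obs - obs.mean()) ** 2).sum()
        assert m["r_squared"] == pytest.approx(1 - sse / sst, abs=1e-12)
        assert m["rmse"] == pytest.approx(np.sqrt(((obs - pred) ** 2).mean()),
                                          abs=1e-12)

    def test_r_squared_one_iff_exact(self, rng):
        y = rng.normal(size=12)
        off = y + 0.01 * rng.normal(size=12)
        assert evaluate_predictions(off, y)["r_squared"] < 1.0
        assert evaluate_predictions(y.copy(), y)["r_squared"] == 1.0

    def test_prediction_r2_can_be_negative(self, rng):
        y = rng.normal(size=12)
        m = evaluate_predictions(-3 * y + 10, y)
        assert m["r_squared"] < 0


@pytest.fixture(scope="module")
def fitted():
    lat = conditioned_planted_cohort(21, n_rois=40)
    model = CPM.from_dataframe(lat.fingerprint_matrix(0), lat.cohort,
                               config=CPMConfig(fst=0.01, n_boot=60, seed=3))
    return lat, model, model.fit()


class TestLOOCV:

    def test_recovers_planted_negative_network(self, fitted):
        lat, _, res = fitted
        assert np.isin(lat.planted_edges, res.consistent_negative).all()
        assert res.metrics["r"] > 0.3

    def test_deterministic_results(self, fitted):
        lat, model, res = fitted
        res2 = model.fit()
        npt.assert_array_equal(res.predictions, res2.predictions)
        npt.assert_array_equal(res.observed, res2.observed)
        for f1, f2 in zip(res.folds, res2.folds):
            npt.assert_array_equal(f1.positive, f2.positive)
            npt.assert_array_equal(f1.retention, f2.retention)

    def test_leakage_freedom_bitwise(self, fitted):
        """Changing the held-out subject's score changes nothing on the
        training side of that fold: covariate coefficients, residuals and
        selected features are bit-identical."""
        lat, model, _ = fitted
        scores = model.scores.copy()
        fold_a = _run_fold(model.edges, scores, model.covariates, 5,
                           model.config, 3)
        scores[5] += 12345.0
        fold_b = _run_fold(model.edges, scores, model.covariates, 5,
                           model.config, 3)
        npt.assert_array_equal(fold_a.cov_beta, fold_b.cov_beta)
        npt.assert_array_equal(fold_a.train_residuals, fold_b.train_residuals)
        npt.assert_array_equal(fold_a.positive, fold_b.positive)
        npt.assert_array_equal(fold_a.negative, fold_b.negative)
        npt.assert_array_equal(fold_a.retention, fold_b.retention)
        assert fold_a.prediction == fold_b.prediction

    def test_summary_renders(self, fitted):
        _, _, res = fitted
        text = res.summary()
        assert "prediction r" in text and "consistent negative" in text


class TestConsistentFeatures:
    def _mask(self, idx, n=10):
        m = np.zeros(n, dtype=bool)
        m[list(idx)] = True
        return m

    def test_everywhere_negative_edge_kept(self):
        folds = [(self._mask([]), self._mask([2, 5])) for _ in range(4)]
        pos, neg, mixed = consistent_features(folds)
        assert neg.tolist() == [2, 5] and pos.size == 0 and mixed.size == 0

    def test_edge_missing_in_one_fold_dropped(self):
        folds = [(self._mask([]), self._mask([2]))] * 3 + [(self._mask([]),
                                                            self._mask([]))]
        _, neg, _ = consistent_features(folds)
        assert neg.size == 0

    def test_sign_conflict_excluded_and_reported(self):
        folds = [(self._mask([4]), self._mask([])),
                 (self._mask([]), self._mask([4]))]
        pos, neg, mixed = consistent_features(folds)
        assert pos.size == 0 and neg.size == 0 and mixed.tolist() == [4]


class TestIntersectFeatures:
    def test_disjoint_empty(self):
        out = intersect_features((np.array([1]), np.array([2])),
                                 (np.array([3]), np.array([4])))
        assert out[0].size == 0 and out[1].size == 0

    def test_identical_sets_identity(self):
        a = (np.array([1, 2]), np.array([7]))
        pos, neg = intersect_features(a, a)
        assert pos.tolist() == [1, 2] and neg.tolist() == [7]

    def test_sign_respected(self):
        out = intersect_features((np.array([5]), np.array([])),
                                 (np.array([]), np.array([5])))
        assert out[0].size == 0 and out[1].size == 0

    def test_shared_planted_edges_recovered_across_tasks(self):
        """Two sessions built from the same subject effects recover the
        planted edges in their intersection."""
        lat = conditioned_planted_cohort(31, n_rois=40)
        cfg = CPMConfig(fst=0.01, n_boot=60, seed=1)
        sets = []
        for k in range(2):
            res = CPM.from_dataframe(lat.fingerprint_matrix(k), lat.cohort,
                                     config=cfg).fit()
            sets.append((res.consistent_positive, res.consistent_negative))
        _, neg = intersect_features(sets[0], sets[1])
        assert np.isin(lat.planted_edges, neg).all()


class TestPermutation:
    def test_planted_cohort_significant(self):
        lat = planted_cohort(seed=41, n_rois=30)
        model = CPM.from_dataframe(lat.fingerprint_matrix(0), lat.cohort,
                                   config=CPMConfig(fst=0.01, n_boot=40, seed=2))
        res = model.fit()
        null, p = res.permutation_test(n_perm=39)
        assert p <= 0.05
        assert null.size <= 39

    def test_shuffled_scores_not_significant(self):
        lat = planted_cohort(seed=51, n_rois=30)
        cohort = lat.cohort.copy()
        rng = np.random.default_rng(0)
        cohort["mvic"] = rng.permutation(cohort["mvic"].to_numpy())
        model = CPM.from_dataframe(lat.fingerprint_matrix(0), cohort,
                                   config=CPMConfig(fst=0.01, n_boot=40, seed=2))
        res = model.fit()
        null, p, _ = cpm_permutation(model.edges, model.scores, model.covariates,
                                     model.config, observed_r=res.metrics["r"],
                                     n_perm=39, seed=2)
        assert p > 0.05

    def test_too_few_subjects_raise(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            loocv_cpm(rng.normal(size=(5, 8)), rng.normal(size=5),
                      rng.normal(size=(5, 2)))
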