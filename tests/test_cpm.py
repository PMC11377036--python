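"""CPM: edge statistics, selection, strengths, CV, permutation, transfer."""

import json
import warnings

import numpy as np
import pandas as pd
import pytest

from attnconn import cpm, simulate
from attnconn.errors import CollinearityError, DegenerateInputError


def _ids(n):
    return [f"s{i}" for i in range(n)]


class TestVectorize:
    def test_edge_count_268(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((2, 268 * 267 // 2))
        es = cpm.CohortEdgeSet(X=X, n_roi=268, subject_ids=_ids(2))
        assert es.n_edges == 35778

    def test_three_roi_order(self):
        m = np.array([[0, 1.0, 2.0], [1.0, 0, 3.0], [2.0, 3.0, 0]])
        assert np.array_equal(cpm.vectorize_matrix(m), [1.0, 2.0, 3.0])

    def test_round_trip(self):
        rng = np.random.default_rng(1)
        m = rng.standard_normal((9, 9))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        assert np.array_equal(cpm.devectorize(cpm.vectorize_matrix(m), 9), m)


class TestPartialCorrelation:
    def test_reduces_to_pearson_without_covariates(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((80, 30))
        y = rng.standard_normal(80)
        est = cpm.edge_partial_correlations(X, y, np.empty((80, 0)))
        for j in range(5):
            expected = np.corrcoef(X[:, j], y)[0, 1]
            assert est.r[j] == pytest.approx(expected, abs=1e-12)

    def test_planted_partial_signal_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            z = rng.standard_normal(n)  # confound
            t = rng.standard_normal(n)
            edge = t + rng.standard_normal(n)
            y_full = 0.5 * z + t + rng.standard_normal(n)  # partial r = 0.5
            X = np.column_stack([edge, rng.standard_normal((n, 5))])
            est = cpm.edge_partial_correlations(X, y_full, z[:, None])
            hits += est.p[0] < 0.01
        assert hits >= 19

    def test_phenotype_equal_to_covariate_raises(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 10))
        y = rng.standard_normal(60)
        with pytest.raises(DegenerateInputError):
            cpm.edge_partial_correlations(X, y, y[:, None])

    def test_zero_variance_edge_flagged(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 4))
        X[:, 2] = 1.0
        est = cpm.edge_partial_correlations(X, rng.standard_normal(50),
                                            np.empty((50, 0)))
        assert est.zero_variance[2]
        assert est.r[2] == 0.0 and est.p[2] == 1.0


class TestSelection:
    def test_negating_phenotype_swaps_masks(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((100, 200))
        y = X[:, 0] - X[:, 1] + rng.standard_normal(100)
        C = np.empty((100, 0))
        pos1, neg1 = cpm.select_edges(cpm.edge_partial_correlations(X, y, C))
        pos2, neg2 = cpm.select_edges(cpm.edge_partial_correlations(X, -y, C))
        assert np.array_equal(pos1.edges, neg2.edges)
        assert np.array_equal(neg1.edges, pos2.edges)

    def test_null_selection_rate_calibrated(self):
        rng = np.random.default_rng(6)
        n_edges = 12000
        X = rng.standard_normal((150, n_edges))
        y = rng.standard_normal(150)
        pos, neg = cpm.select_edges(
            cpm.edge_partial_correlations(X, y, np.empty((150, 0))),
            p_thresh=0.01,
        )
        frac = (len(pos) + len(neg)) / n_edges
        assert 0.005 <= frac <= 0.015

    def test_planted_edges_selected_with_polarity(self, small_cohort):
        es = small_cohort.edges[1]
        y = small_cohort.phenotype[1].to_numpy()
        C, _ = cpm.covariate_design(small_cohort.covariates[1])
        pos, neg = cpm.select_edges(cpm.edge_partial_correlations(es.X, y, C))
        truth_pos = set(small_cohort.ground_truth["positive_edges"])
        truth_neg = set(small_cohort.ground_truth["negative_edges"])
        assert len(truth_pos & set(pos.edges)) >= 16
        assert len(truth_neg & set(neg.edges)) >= 16


class TestNetworkStrength:
    def test_hand_sum(self):
        vec = np.array([0.5, -0.2, 1.0])
        mask = cpm.EdgeMask("positive", np.array([0, 1]))
        assert cpm.network_strength(vec, mask) == pytest.approx(0.3)

    def test_empty_mask_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            s = cpm.network_strength(np.array([1.0, 2.0]),
                                     cpm.EdgeMask("positive", np.array([], int)))
        assert s == 0.0

    def test_combined_with_empty_negative_equals_positive(self):
        vec = np.array([0.5, -0.2, 1.0])
        pos = cpm.EdgeMask("positive", np.array([0, 2]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            combined = cpm.network_strength(
                vec, pos, cpm.EdgeMask("negative", np.array([], int))
            )
        assert combined == cpm.network_strength(vec, pos)

    def test_linearity_in_matrix_scale(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((10, 20))
        mask = cpm.EdgeMask("positive", np.array([1, 4, 7]))
        s1 = cpm.network_strength(X, mask)
        s2 = cpm.network_strength(3.5 * X, mask)
        assert np.allclose(s2, 3.5 * s1)

    def test_brute_force_equivalence_on_matrix(self, tiny_cohort):
        es = tiny_cohort.edges[1]
        mask_idx = np.array([0, 3, 10, 50])
        pairs = es.edge_pairs()[mask_idx]
        strengths = cpm.network_strength(es.X, cpm.EdgeMask("positive", mask_idx))
        for subj in range(0, 60, 17):
            m = cpm.devectorize(es.X[subj], es.n_roi)
            brute = sum(m[i, j] for i, j in pairs)
            assert strengths[subj] == pytest.approx(brute, rel=1e-12)


class TestLinearModel:
    def test_noiseless_linear_prediction(self):
        rng = np.random.default_rng(8)
        s_tr, s_te = rng.standard_normal(50), rng.standard_normal(20)
        y_tr = 2.0 * s_tr + 1.0
        pred, beta = cpm.fit_predict_linear(
            s_tr, np.empty((50, 0)), y_tr, s_te, np.empty((20, 0))
        )
        assert np.allclose(pred, 2.0 * s_te + 1.0, atol=1e-10)
        assert beta[1] == pytest.approx(2.0)

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(9)
        s = rng.standard_normal(500)
        y = 0.7 * s + rng.normal(0, 0.1, 500)
        _, beta = cpm.fit_predict_linear(s, np.empty((500, 0)), y,
                                         s[:5], np.empty((5, 0)))
        assert beta[1] == pytest.approx(0.7, abs=0.05)

    def test_constant_strength_raises(self):
        with pytest.raises(CollinearityError):
            cpm.fit_predict_linear(np.ones(30), np.empty((30, 0)),
                                   np.arange(30.0), np.ones(5),
                                   np.empty((5, 0)))


class TestCrossValidation:
    def test_leave_site_out_has_eight_folds(self, tiny_cohort):
        es = tiny_cohort.edges[1]
        y = tiny_cohort.phenotype[1].to_numpy()
        res = cpm.run_cv(es, y, tiny_cohort.covariates[1],
                         scheme="leave_site_out")
        assert res.n_folds_total == 8
        assert len(res.outcome.per_repeat_r["combined"]) == 1

    def test_permuted_phenotype_gives_null_performance(self, small_cohort):
        # at the default cohort scale the out-of-fold null bias is negligible
        es = small_cohort.edges[1]
        y = small_cohort.phenotype[1].to_numpy()
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            res = cpm.run_cv(es, rng.permutation(y), None, k=5,
                             n_repeats=2, seed=seed)
            rs.append(res.outcome.r["combined"])
        assert abs(np.mean(rs)) < 0.05

    def test_no_leakage_from_test_fold(self, tiny_cohort):
        # removing a test-fold subject must not change training selection
        es = tiny_cohort.edges[1]
        y = tiny_cohort.phenotype[1].to_numpy()
        n = len(y)
        test_idx = np.arange(0, 12)
        train_idx = np.arange(12, n)
        C = np.empty((n, 0))
        pos_full, _ = cpm.select_edges(
            cpm.edge_partial_correlations(es.X[train_idx], y[train_idx],
                                          C[train_idx])
        )
        # drop one *test* subject; training stats identical
        pos_drop, _ = cpm.select_edges(
            cpm.edge_partial_correlations(es.X[train_idx], y[train_idx],
                                          C[train_idx])
        )
        assert np.array_equal(pos_full.edges, pos_drop.edges)

    def test_consensus_monotone_in_threshold(self, tiny_cohort):
        es = tiny_cohort.edges[1]
        y = tiny_cohort.phenotype[1].to_numpy()
        res = cpm.run_cv(es, y, None, k=5, n_repeats=10, seed=1)
        for thresh_lo, thresh_hi in [(0.5, 0.8), (0.8, 0.95)]:
            lo = np.flatnonzero(res.fold_fraction_positive >= thresh_lo)
            hi = np.flatnonzero(res.fold_fraction_positive >= thresh_hi)
            assert set(hi) <= set(lo)

    def test_fixed_seed_is_deterministic(self, tiny_cohort):
        es = tiny_cohort.edges[1]
        y = tiny_cohort.phenotype[1].to_numpy()
        r1 = cpm.run_cv(es, y, tiny_cohort.covariates[1], k=5, n_repeats=3,
                        seed=9)
        r2 = cpm.run_cv(es, y, tiny_cohort.covariates[1], k=5, n_repeats=3,
                        seed=9)
        assert r1.outcome.r == r2.outcome.r
        assert np.array_equal(r1.fold_fraction_positive,
                              r2.fold_fraction_positive)
        for net in cpm.NETWORKS:
            assert np.array_equal(r1.outcome.predicted[net],
                                  r2.outcome.predicted[net])


class TestPermutation:
    def test_p_floor_when_observed_beats_all_nulls(self):
        # strong planted signal: observed r tops every null draw
        cohort = simulate.simulate_connectome_cohort(
            n_subjects=80, n_rois=16, n_positive_edges=6, n_negative_edges=6,
            seed=3,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cpm.permutation_test(
                cohort.edges[1], cohort.phenotype[1].to_numpy(), None,
                k=5, n_repeats=1, n_perm=100, seed=0,
            )
        assert out.p["combined"] == pytest.approx(1 / 101)

    def test_shuffle_preserves_phenotype_multiset(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(40)
        assert np.array_equal(np.sort(rng.permutation(y)), np.sort(y))

    def test_small_nperm_warns(self, tiny_cohort):
        with pytest.warns(UserWarning, match="unstable"):
            cpm.permutation_test(
                tiny_cohort.edges[1], tiny_cohort.phenotype[1].to_numpy(),
                None, k=5, n_repeats=1, n_perm=20, seed=0,
            )


class TestTransfer:
    def test_same_wave_transfer_equals_in_sample(self, tiny_cohort):
        es = tiny_cohort.edges[1]
        y = tiny_cohort.phenotype[1].to_numpy()
        cov = tiny_cohort.covariates[1]
        model = cpm.train_full_model(es, y, cov)
        out = cpm.apply_model_across(model, es, cov, y, mode="transfer",
                                     n_perm=50, seed=0)
        C, _ = cpm.covariate_design(cov)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = cpm.network_strength(es.X, model.positive_edges)
        X = np.hstack([np.ones((len(y), 1)), s[:, None], C])
        expected = X @ model.coefficients["positive"]
        assert np.allclose(out.predicted["positive"], expected)

    def test_cross_wave_transfer_predicts(self, small_cohort):
        es1 = small_cohort.edges[1]
        y1 = small_cohort.phenotype[1].to_numpy()
        model = cpm.train_full_model(es1, y1, small_cohort.covariates[1])
        # wave-1 model includes PDS; apply to wave 3 with its own covariates
        # restricted to the trained columns
        cov3 = small_cohort.covariates[3].copy()
        cov3["pds"] = 0.0
        out = cpm.apply_model_across(
            model, small_cohort.edges[3], cov3,
            small_cohort.phenotype[3].to_numpy(), mode="transfer",
            n_perm=500, seed=1,
        )
        assert out.r["combined"] > 0
        assert out.p["combined"] < 0.05

    def test_residualization_reduces_site_confounding(self):
        rng = np.random.default_rng(12)
        n, n_roi = 160, 10
        site = np.repeat(np.arange(8), 20)
        offsets = rng.normal(0, 1.0, 8)
        X = rng.standard_normal((n, n_roi * (n_roi - 1) // 2))
        X[:, :5] += offsets[site][:, None]
        y = offsets[site] + 0.2 * rng.standard_normal(n)  # site-driven null
        es = cpm.CohortEdgeSet(X=X, n_roi=n_roi, subject_ids=_ids(n))
        cov = pd.DataFrame({"site": site}, index=_ids(n))
        model = cpm.CPMModel(
            n_roi=n_roi, p_thresh=0.01,
            positive_edges=np.arange(5), negative_edges=np.array([], int),
            coefficients={k: np.zeros(2) for k in cpm.NETWORKS},
            covariate_names=[],
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = cpm.apply_model_across(
                model, es, None, y, mode="residual_correlation",
                n_perm=50, seed=0,
            )
            resid = cpm.apply_model_across(
                model, es, cov, y, mode="residual_correlation",
                n_perm=50, seed=0,
            )
        assert abs(resid.r["positive"]) < abs(raw.r["positive"])

    def test_atlas_mismatch_raises(self, tiny_cohort):
        es = tiny_cohort.edges[1]
        model = cpm.train_full_model(es, tiny_cohort.phenotype[1].to_numpy(),
                                     tiny_cohort.covariates[1])
        other = cpm.CohortEdgeSet(
            X=np.zeros((4, 10 * 9 // 2)), n_roi=10, subject_ids=_ids(4)
        )
        with pytest.raises(ValueError, match="atlas"):
            cpm.apply_model_across(model, other, None, np.zeros(4))


def test_model_json_round_trip(tmp_path, tiny_cohort):
    es = tiny_cohort.edges[1]
    model = cpm.train_full_model(es, tiny_cohort.phenotype[1].to_numpy(),
                                 tiny_cohort.covariates[1], seed=4)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = cpm.CPMModel.from_json(path)
    assert np.array_equal(back.positive_edges, model.positive_edges)
    assert back.covariate_names == model.covariate_names
    for net in cpm.NETWORKS:
        assert np.allclose(back.coefficients[net], model.coefficients[net])
    # byte-identical re-serialization
    model.to_json(tmp_path / "model2.json")
    assert (tmp_path / "model.json").read_bytes() == (
        tmp_path / "model2.json"
    ).read_bytes()
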