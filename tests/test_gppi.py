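"""gPPI design construction, deconvolution, and pair/matrix estimation."""

import numpy as np
import pandas as pd
import pytest

from attnconn import gppi, simulate
from attnconn.errors import CollinearityError

TR = 2.2
N_TIME = 300


@pytest.fixture(scope="module")
def hrf():
    return gppi.canonical_hrf(TR, oversampling=16)


@pytest.fixture(scope="module")
def confounds():
    return simulate.simulate_confounds(N_TIME, np.random.default_rng(0))


class TestHRF:
    def test_peak_location(self, hrf):
        t_peak = np.argmax(hrf.kernel) * hrf.dt
        assert 4.0 <= t_peak <= 8.0

    def test_zero_at_origin(self, hrf):
        assert hrf.kernel[0] == 0.0

    def test_impulse_convolution_is_identity(self, hrf):
        impulse = np.zeros(len(hrf.kernel))
        impulse[0] = 1.0
        conv = np.convolve(impulse, hrf.kernel)[: len(hrf.kernel)]
        assert np.allclose(conv, hrf.kernel)

    def test_invalid_tr(self):
        with pytest.raises(ValueError):
            gppi.canonical_hrf(0.0)


class TestDesign:
    def test_nuisance_block_has_36_columns(self, confounds):
        block = gppi.expand_confounds(confounds)
        assert block.shape == (N_TIME, 36)
        assert len(gppi.confound_labels()) == 36

    def test_derivative_and_square_structure(self, confounds):
        block = gppi.expand_confounds(confounds)
        base = confounds.to_numpy()
        assert np.allclose(block[1:, 9], np.diff(base[:, 0]))
        assert block[0, 9] == 0.0
        assert np.allclose(block[:, 18], base[:, 0] ** 2)

    def test_task_regressor_causality(self, hrf):
        events = pd.DataFrame(
            {"onset": [100.0], "duration": [1.0], "trial_type": ["go"]}
        )
        reg, names = gppi.task_regressors(events, N_TIME, TR, "go_trials", hrf)
        go = reg[:, names.index("psycho_go")]
        pre = go[: int(100.0 / TR)]
        assert np.allclose(pre, 0.0)
        assert go.max() > 0

    @pytest.mark.parametrize(
        "n_time,tr", [(300, 2.2), (200, 2.0), (120, 3.0), (64, 1.0)]
    )
    def test_dct_column_count_matches_cutoff_rule(self, n_time, tr):
        basis = gppi.dct_highpass_basis(n_time, tr)
        assert basis.shape[1] == int(np.floor(2 * n_time * tr / 128.0))

    def test_full_design_columns(self, dense_events, confounds):
        X, names = gppi.build_design(dense_events, confounds, N_TIME, TR,
                                     "go_trials")
        n_dct = int(np.floor(2 * N_TIME * TR / 128.0))
        assert X.shape == (N_TIME, 3 + 36 + n_dct)
        assert names[:3] == ["psycho_stop_success", "psycho_stop_fail",
                             "psycho_go"]

    def test_rank_deficient_design_names_columns(self, dense_events):
        bad = pd.DataFrame(
            np.zeros((N_TIME, 9)), columns=list(gppi.BASE_CONFOUNDS)
        )
        with pytest.raises(CollinearityError, match="trans_x"):
            gppi.build_design(dense_events, bad, N_TIME, TR, "go_trials")


class TestDeconvolution:
    def test_noiseless_recovery(self, hrf):
        dec = gppi.Deconvolver(N_TIME, TR, hrf)
        rng = np.random.default_rng(1)
        neural = dec.B[:, 1:60] @ rng.standard_normal(59)
        bold = dec.convolve(neural)
        rec = dec(bold)
        assert np.corrcoef(rec, neural)[0, 1] > 0.99

    def test_zero_in_zero_out(self, hrf):
        dec = gppi.Deconvolver(N_TIME, TR, hrf)
        assert np.all(dec(np.zeros(N_TIME)) == 0.0)

    def test_round_trip_reconvolution(self, hrf):
        dec = gppi.Deconvolver(N_TIME, TR, hrf)
        rng = np.random.default_rng(2)
        neural = dec.B[:, 1:40] @ rng.standard_normal(39)
        y = dec.convolve(neural)
        back = dec.reconvolve(dec(y))
        assert np.linalg.norm(back - y) / np.linalg.norm(y) < 0.05


class TestPairFit:
    def test_planted_coefficient_zero_noise(self, dense_events):
        bold, conf, _ = simulate.simulate_ppi_timeseries(
            2, dense_events, tr=TR, n_time=N_TIME,
            couplings={(0, 1, "go"): 0.8}, physio_couplings={(0, 1): 0.3},
            intrinsic_sd=[0.0, 1.0], noise_sd=0.0, rng=1,
        )
        fit = gppi.fit_gppi_pair(bold[:, 0], bold[:, 1], dense_events, conf,
                                 TR, model="go_trials")
        assert fit.ppi_edge_value == pytest.approx(0.8, abs=1e-6)

    def test_go_model_has_eight_coefficients(self, dense_events):
        bold, conf, _ = simulate.simulate_ppi_timeseries(
            2, dense_events, tr=TR, n_time=N_TIME, rng=2
        )
        fit = gppi.fit_gppi_pair(bold[:, 0], bold[:, 1], dense_events, conf,
                                 TR, model="go_trials")
        assert len(fit.coefficients) == 8

    def test_stop_model_has_six_coefficients(self, dense_events):
        bold, conf, _ = simulate.simulate_ppi_timeseries(
            2, dense_events, tr=TR, n_time=N_TIME, rng=2
        )
        fit = gppi.fit_gppi_pair(bold[:, 0], bold[:, 1], dense_events, conf,
                                 TR, model="successful_stop")
        assert len(fit.coefficients) == 6
        assert fit.coefficient_names[-1] == "ppi_stop_fail"
        assert "ppi_stop_success" in fit.coefficient_names

    def test_null_pair_coefficient_within_error_bars(self, dense_events):
        # independent target: |estimate| < 2 SE in >= 95% of replicates
        inside = 0
        n_rep = 60
        for seed in range(n_rep):
            bold, conf, _ = simulate.simulate_ppi_timeseries(
                2, dense_events, tr=TR, n_time=N_TIME,
                intrinsic_sd=[0.0, 1.0], noise_sd=1.0, rng=1000 + seed,
            )
            fit = gppi.fit_gppi_pair(bold[:, 0], bold[:, 1], dense_events,
                                     conf, TR, model="go_trials")
            inside += abs(fit.ppi_edge_value) < 2 * fit.ppi_se
        assert inside >= 0.9 * n_rep

    def test_constant_target_raises(self, dense_events, confounds):
        rng = np.random.default_rng(0)
        with pytest.raises(CollinearityError):
            gppi.fit_gppi_pair(rng.standard_normal(N_TIME),
                               np.ones(N_TIME), dense_events, confounds, TR)

    def test_rescaling_both_series_rescales_coefficient(self, dense_events):
        bold, conf, _ = simulate.simulate_ppi_timeseries(
            2, dense_events, tr=TR, n_time=N_TIME,
            couplings={(0, 1, "go"): 0.8}, intrinsic_sd=[0.0, 1.0],
            noise_sd=0.0, rng=3,
        )
        f1 = gppi.fit_gppi_pair(bold[:, 0], bold[:, 1], dense_events, conf, TR)
        f2 = gppi.fit_gppi_pair(5.0 * bold[:, 0], 5.0 * bold[:, 1],
                                dense_events, conf, TR)
        # seed and target scaled together: PPI coefficient is unchanged
        assert f2.ppi_edge_value == pytest.approx(f1.ppi_edge_value, rel=1e-6)


class TestMatrix:
    def test_symmetry_and_shape(self, dense_events):
        bold, conf, _ = simulate.simulate_ppi_timeseries(
            8, dense_events, tr=TR, n_time=N_TIME, rng=4
        )
        gm = gppi.build_gppi_matrix(
            gppi.ROITimeSeries(bold, tr=TR), dense_events, conf
        )
        assert gm.matrix.shape == (8, 8)
        assert np.array_equal(gm.matrix, gm.matrix.T)
        assert np.all(np.diag(gm.matrix) == 0)

    def test_symmetrize_idempotent(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((12, 12))
        once = gppi.symmetrize(m)
        assert np.array_equal(gppi.symmetrize(once), once)

    def test_group_mean_recovers_planted_network(self, dense_events):
        # planted couplings top the subject-averaged symmetrized matrix
        n_roi, n_sub = 8, 20
        planted = {}
        for i, j, k in [(0, 1, 0.8), (3, 4, -0.8)]:
            planted[(i, j, "go")] = k
            planted[(j, i, "go")] = k
        mats = []
        for s in range(n_sub):
            bold, conf, _ = simulate.simulate_ppi_timeseries(
                n_roi, dense_events, tr=TR, n_time=N_TIME,
                couplings=planted, rng=500 + s,
            )
            mats.append(
                gppi.build_gppi_matrix(
                    gppi.ROITimeSeries(bold, tr=TR), dense_events, conf
                ).matrix
            )
        mean = np.mean(mats, axis=0)
        iu = np.triu_indices(n_roi, 1)
        vals = np.abs(mean[iu])
        top2 = {
            (iu[0][i], iu[1][i]) for i in np.argsort(vals)[-2:]
        }
        assert top2 == {(0, 1), (3, 4)}
        assert mean[0, 1] > 0 and mean[3, 4] < 0

    def test_null_coupling_distribution_centered(self, dense_events):
        # no interactions planted: edge values centered at zero
        vals = []
        for s in range(6):
            bold, conf, _ = simulate.simulate_ppi_timeseries(
                12, dense_events, tr=TR, n_time=N_TIME, rng=700 + s
            )
            gm = gppi.build_gppi_matrix(
                gppi.ROITimeSeries(bold, tr=TR), dense_events, conf
            )
            iu = np.triu_indices(12, 1)
            vals.extend(gm.matrix[iu])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert len(vals) >= 300
        assert abs(vals.mean()) < 3 * se + 0.05


def test_h5_round_trip(tmp_path, dense_events):
    bold, conf, _ = simulate.simulate_ppi_timeseries(
        5, dense_events, tr=TR, n_time=N_TIME, rng=9
    )
    gms = [
        gppi.build_gppi_matrix(
            gppi.ROITimeSeries(bold, tr=TR, subject_id=f"s{i}"),
            dense_events, conf, model=m,
        )
        for i, m in enumerate(["go_trials", "successful_stop"])
    ]
    path = tmp_path / "mats.h5"
    gppi.save_matrices_h5(path, gms)
    back = gppi.load_matrices_h5(path, "go_trials")
    assert len(back) == 1
    assert np.array_equal(back[0].matrix, gms[0].matrix)
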