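"""Variational-Laplace fitting, priors and the VOI utilities."""

import warnings

import numpy as np
import pytest

import bidcm
from bidcm.estimation import (BilinearDCM, adjust_timeseries, default_priors,
                              extract_eigenvariate, params_to_theta,
                              theta_to_params)
from conftest import simulate_noisy


class TestEigenvariate:
    def test_single_voxel_returns_demeaned_series(self):
        rng = np.random.default_rng(0)
        y = rng.normal(5, 2, 60)
        out = extract_eigenvariate(y[:, None])
        np.testing.assert_allclose(out, y - y.mean(), atol=1e-9)

    def test_rank_one_recovery(self):
        """Exact rank-1 data g w^T: the eigenvariate recovers g up to
        positive scale (checked against the SVD of the data)."""
        rng = np.random.default_rng(1)
        g = rng.normal(0, 1, 80)
        w = np.abs(rng.normal(1, 0.2, 25))
        Y = np.outer(g, w)
        out = extract_eigenvariate(Y)
        r = np.corrcoef(out, g - g.mean())[0, 1]
        assert abs(r) > 1 - 1e-10

    def test_sign_correlates_with_voxel_mean(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(0, 1, (100, 12)) + rng.normal(0, 2, 100)[:, None]
        out = extract_eigenvariate(Y)
        assert np.corrcoef(out, Y.mean(axis=1))[0, 1] > 0

    def test_rms_scaling(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(0, 3, (50, 8))
        out = extract_eigenvariate(Y)
        Yd = Y - Y.mean(axis=0)
        assert np.sqrt(np.mean(out ** 2)) == pytest.approx(
            np.sqrt(np.mean(Yd ** 2)), rel=1e-9)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            extract_eigenvariate(np.zeros((10, 3)))
        with pytest.raises(ValueError):
            extract_eigenvariate(np.ones((1, 3)))


class TestAdjustTimeseries:
    def test_pure_confound_is_annihilated(self, design):
        R = bidcm.build_regressors(design)
        y = R.X[:, R.names.index("dct_001")] * 3.0
        out = adjust_timeseries(y, R)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_task_signal_is_retained(self, design):
        """y = task + constant -> adjusted series equals the demeaned task
        regressor (least-squares oracle)."""
        R = bidcm.build_regressors(design)
        task = R.X[:, 0]
        y = task + 5.0
        out = adjust_timeseries(y, R)
        drop = [j for j in range(R.X.shape[1]) if j >= R.n_task]
        X0 = R.X[:, drop]
        ref = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        ref -= ref.mean()
        np.testing.assert_allclose(out, ref, atol=1e-10)
        # most of the task variance survives adjustment
        assert np.corrcoef(out, task)[0, 1] > 0.9

    def test_idempotence(self, design):
        R = bidcm.build_regressors(design)
        rng = np.random.default_rng(4)
        y = rng.normal(0, 1, design.n_scans)
        once = adjust_timeseries(y, R)
        twice = adjust_timeseries(once, R)
        np.testing.assert_allclose(once, twice, atol=1e-10)

    def test_collinear_confounds_raise_with_names(self, design):
        R = bidcm.build_regressors(design)
        X = np.column_stack([R.X, R.X[:, -1]])  # duplicate the constant
        R2 = bidcm.RegressorMatrix(X=X, names=R.names + ("constant_dup",),
                                   tr=R.tr, n_task=R.n_task)
        with pytest.raises(ValueError, match="rank"):
            adjust_timeseries(np.ones(design.n_scans), R2)


class TestPriors:
    def test_full_model_parameter_count(self, space):
        st = space.model(space.find(((True, True), (True, True)),
                                    (True, True, True, True)))
        pr = default_priors(st)
        # 2 self + 2 off-diag + 4 B + 8 C + 6 haemo + 2 lambda
        assert pr.n_params == 24
        assert np.all(pr.var > 0)

    def test_masked_entries_absent(self, space, winner_structure):
        pr = default_priors(winner_structure)
        # winner: inputs to DLPFC only -> 4 C entries, full B -> 4 entries
        assert pr.n_params == 2 + 2 + 4 + 4 + 6 + 2
        assert not any("C_EN->Striatum" == n for n in pr.names)
        nomod = space.model(space.find(((False, False), (False, False)),
                                       (True, False, True, False)))
        assert not any(n.startswith("B_") for n in default_priors(nomod).names)

    def test_documented_default_variances(self, winner_structure):
        pr = default_priors(winner_structure)
        assert pr.var[pr.index("A_self_DLPFC")] == pytest.approx(1 / 256)
        assert pr.var[pr.index("A_DLPFC->Striatum")] == pytest.approx(1 / 16)
        assert pr.var[pr.index("B_EN_DLPFC->Striatum")] == 1.0
        assert pr.var[pr.index("C_EN->DLPFC")] == 1.0
        assert pr.mean[pr.index("lambda_DLPFC")] == 6.0
        assert pr.var[pr.index("lambda_DLPFC")] == pytest.approx(1 / 128)

    def test_theta_params_round_trip(self, winner_structure, winner_params):
        theta = params_to_theta(winner_structure, winner_params)
        back = theta_to_params(winner_structure, theta)
        np.testing.assert_allclose(back.A, winner_params.A, atol=1e-12)
        np.testing.assert_allclose(back.C, winner_params.C, atol=1e-12)
        for k in ("EN", "EP"):
            np.testing.assert_allclose(back.B[k], winner_params.B[k],
                                       atol=1e-12)
        np.testing.assert_allclose(back.kappa, winner_params.kappa,
                                   atol=1e-12)


@pytest.fixture(scope="module")
def winner_fits(space, inputs, winner_structure, winner_params):
    """Fits of the generating model to 8 seeded noisy replicates (SNR 1)."""
    results = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for seed in range(8):
            noisy, _ = simulate_noisy(winner_params, inputs,
                                      winner_structure, snr=1.0, seed=seed)
            results.append(
                BilinearDCM(noisy, winner_structure, inputs).fit())
    return results


class TestFitDcm:
    def test_free_energy_trace_is_increasing(self, winner_fits):
        for res in winner_fits:
            assert np.all(np.diff(res.f_trace) > 0)

    def test_posterior_covariance_is_pd(self, winner_fits):
        for res in winner_fits:
            cov = res.posterior.cov
            np.testing.assert_allclose(cov, cov.T, atol=1e-10)
            w = np.linalg.eigvalsh(cov)
            assert w.min() > 1e-10

    def test_b_en_topdown_sign_recovery(self, winner_fits):
        """The strongest effect (EN modulation of DLPFC -> striatum,
        true value +0.5) has the correct posterior sign in >= 90% of
        replicates at SNR 1."""
        signs = [res.posterior.mean[
            res.posterior.names.index("B_EN_DLPFC->Striatum")] > 0
            for res in winner_fits]
        assert np.mean(signs) >= 0.9

    def test_noise_precision_recovered(self, winner_fits):
        """At SNR 1 on the calibrated scale the true log-precision is 6."""
        for res in winner_fits:
            lam, _ = res.posterior.marginal("lambda_DLPFC")
            assert abs(lam - 6.0) < 0.5

    def test_pure_noise_shrinks_to_prior(self, winner_structure, inputs):
        rng = np.random.default_rng(42)
        rec = bidcm.BoldRecord(y=rng.normal(0, 1, (inputs.n_scans, 2)),
                               tr=inputs.tr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = BilinearDCM(rec, winner_structure, inputs).fit()
        pr = default_priors(winner_structure)
        n_model = len(res.model.entries)
        dev = np.abs(res.posterior.mean[:n_model] - pr.mean[:n_model])
        frac = np.mean(dev < np.sqrt(pr.var[:n_model]))
        assert frac >= 0.9

    def test_parameter_recovery_rmse_below_prior_sd(self, winner_fits,
                                                    winner_structure,
                                                    winner_params):
        """RMSE of the A off-diagonal and B entries across replicates stays
        below the corresponding prior SD at SNR 1."""
        theta_true = params_to_theta(winner_structure, winner_params)
        pr = default_priors(winner_structure)
        idx = [i for i, n in enumerate(pr.names)
               if n.startswith("A_DLPFC") or n.startswith("A_Striatum")
               or n.startswith("B_")]
        err = np.array([[res.posterior.mean[i] - theta_true[i] for i in idx]
                        for res in winner_fits])
        rmse = np.sqrt(np.mean(err ** 2, axis=0))
        assert np.all(rmse < np.sqrt(pr.var[idx]))

    def test_recovery_improves_with_snr(self, space, inputs,
                                        winner_structure, winner_params):
        """Doubling SNR reduces the average coupling RMSE."""
        theta_true = params_to_theta(winner_structure, winner_params)
        pr = default_priors(winner_structure)
        idx = [i for i, n in enumerate(pr.names)
               if n.startswith(("A_DLPFC", "A_Striatum", "B_", "C_"))]
        rmse = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for snr in (1.0, 2.0):
                errs = []
                for seed in range(4):
                    noisy, _ = simulate_noisy(winner_params, inputs,
                                              winner_structure, snr, seed)
                    res = BilinearDCM(noisy, winner_structure, inputs).fit()
                    errs.append([res.posterior.mean[i] - theta_true[i]
                                 for i in idx])
                rmse[snr] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[2.0] < rmse[1.0]

    def test_evidence_prefers_generating_model(self, space, inputs,
                                               winner_structure):
        """On strongly modulated data the generating (full-modulation)
        model has higher free energy than the no-modulation model in the
        majority of replicates."""
        params = bidcm.default_group_params(winner_structure)
        params.B["EN"][1, 0] = 0.9
        params.B["EN"][0, 1] = 0.8
        params.B["EP"][1, 0] = 0.8
        params.B["EP"][0, 1] = 0.7
        nomod = space.model(space.find(((False, False), (False, False)),
                                       (True, False, True, False)))
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for seed in range(5):
                noisy, _ = simulate_noisy(params, inputs, winner_structure,
                                          snr=1.0, seed=100 + seed)
                f_true = BilinearDCM(noisy, winner_structure,
                                     inputs).fit().free_energy
                f_null = BilinearDCM(noisy, nomod, inputs).fit().free_energy
                wins += f_true > f_null
        assert wins >= 3

    def test_occam_penalty_for_unused_inputs_is_bounded(self, space, inputs,
                                                        winner_structure):
        """Adding driving-input entries whose true value is zero (striatal
        routing) never raises the free energy by more than a small
        complexity-free tolerance, on average over replicates."""
        params = bidcm.default_group_params(winner_structure)
        bigger = space.model(space.find(((True, True), (True, True)),
                                        (True, True, True, True)))
        deltas = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for seed in range(4):
                noisy, _ = simulate_noisy(params, inputs, winner_structure,
                                          snr=1.0, seed=200 + seed)
                f_true = BilinearDCM(noisy, winner_structure,
                                     inputs).fit().free_energy
                f_big = BilinearDCM(noisy, bigger, inputs).fit().free_energy
                deltas.append(f_big - f_true)
        assert np.mean(deltas) <= 1.0

    def test_mismatched_lengths_raise(self, winner_structure, inputs):
        rec = bidcm.BoldRecord(y=np.zeros((10, 2)), tr=inputs.tr)
        with pytest.raises(ValueError, match="n_scans"):
            BilinearDCM(rec, winner_structure, inputs)

    def test_summary_lists_parameters(self, winner_fits):
        text = winner_fits[0].summary()
        assert "free energy" in text
        assert "B_EN_DLPFC->Striatum" in text


class TestVoiSphere:
    def test_sphere_eigenvariate_from_nifti(self):
        nib = pytest.importorskip("nibabel")
        rng = np.random.default_rng(7)
        g = rng.normal(0, 1, 40)
        data = rng.normal(0, 0.05, (8, 8, 8, 40))
        # coherent signal in a 2-voxel-radius blob around voxel (2, 2, 2)
        for idx in np.ndindex(3, 3, 3):
            data[1 + idx[0], 1 + idx[1], 1 + idx[2], :] += g
        img = nib.Nifti1Image(data, affine=np.diag([3.0, 3.0, 3.0, 1.0]))
        out = bidcm.estimation.extract_voi_sphere(img, center=(6.0, 6.0, 6.0),
                                                  radius=6.0)
        assert out.shape == (40,)
        assert abs(np.corrcoef(out, g)[0, 1]) > 0.99

    def test_empty_sphere_raises(self):
        nib = pytest.importorskip("nibabel")
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 5)), affine=np.eye(4))
        with pytest.raises(ValueError, match="no voxels"):
            bidcm.estimation.extract_voi_sphere(img, center=(500, 0, 0))

    def test_3d_image_rejected(self):
        nib = pytest.importorskip("nibabel")
        img = nib.Nifti1Image(np.zeros((4, 4, 4)), affine=np.eye(4))
        with pytest.raises(ValueError, match="4-D"):
            bidcm.estimation.extract_voi_sphere(img, center=(0, 0, 0))
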