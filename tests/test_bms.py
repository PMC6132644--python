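"""Random-effects BMS: Dirichlet inference, exceedance, PXP, families, BPA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from bidcm.bms import (EvidenceMatrix, RandomEffectsBMS, bpa, exceedance,
                       family_bms, protected_exceedance, rfx_bms)
from bidcm.estimation import Posterior


def _posterior(mean, cov, sid="s", names=None):
    mean = np.atleast_1d(np.asarray(mean, float))
    cov = np.atleast_2d(np.asarray(cov, float))
    names = names or tuple(f"p{i}" for i in range(mean.size))
    return Posterior(names=tuple(names), mean=mean, cov=cov, free_energy=0.0,
                     n_iterations=1, converged=True, subject_id=sid)


class TestRfxBms:
    def test_constant_evidence_gives_uniform_frequencies(self):
        F = np.full((7, 4), 3.14)
        res = rfx_bms(F)
        np.testing.assert_allclose(res.alpha, 1.0 + 7 / 4)
        np.testing.assert_allclose(res.r, 0.25)

    def test_dominant_model_wins(self):
        rng = np.random.default_rng(0)
        n = 40
        F = rng.normal(0, 1, (n, 5))
        F[:, 2] += 20.0  # dominates every subject by >= 20 nats
        res = rfx_bms(F)
        # fixed-point oracle: all responsibility goes to model 2, so
        # alpha = (1, 1, 1 + n, 1, 1) and r_2 = (1 + n)/(5 + n)
        np.testing.assert_allclose(res.alpha[2], 1 + n, atol=1e-6)
        assert res.r[2] == pytest.approx((1 + n) / (5 + n), abs=1e-6)
        assert res.r[2] > 0.9

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(2, 12),
           st.integers(2, 8))
    def test_count_conservation(self, seed, n, m):
        F = np.random.default_rng(seed).normal(0, 3, (n, m))
        res = rfx_bms(F)
        assert res.alpha.sum() - res.alpha0.sum() == pytest.approx(n)
        assert res.r.sum() == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            EvidenceMatrix(F=np.ones((3, 1)))
        with pytest.raises(ValueError):
            rfx_bms(np.zeros((3, 3)), a0=-1.0)
        with pytest.raises(ValueError):
            EvidenceMatrix(F=np.array([[np.inf, 0.0]]))


class TestExceedance:
    def test_two_models_match_beta_closed_form(self):
        alpha = np.array([6.3, 2.8])
        n = 100_000
        phi, _ = exceedance(alpha, n_samples=n, seed=1)
        p_true = stats.beta.sf(0.5, alpha[0], alpha[1])
        se = np.sqrt(p_true * (1 - p_true) / n)
        assert abs(phi[0] - p_true) < 3 * se

    def test_symmetric_counts_uniform(self):
        phi, _ = exceedance(np.full(4, 2.5), n_samples=200_000, seed=2)
        np.testing.assert_allclose(phi, 0.25, atol=0.01)
        assert phi.sum() == pytest.approx(1.0)

    def test_small_sample_warning_recorded(self):
        with pytest.warns(RuntimeWarning):
            _, warned = exceedance(np.ones(3), n_samples=500, seed=0)
        assert warned

    def test_seeded_reproducibility(self):
        a = exceedance(np.array([3.0, 2.0, 1.0]), seed=7)[0]
        b = exceedance(np.array([3.0, 2.0, 1.0]), seed=7)[0]
        np.testing.assert_array_equal(a, b)


class TestProtectedExceedance:
    def test_identical_evidence_gives_high_bor_and_uniform_pxp(self):
        """Identical evidences: the null (equal frequencies) is favoured,
        F1 < F0 by the Dirichlet KL, so BOR = 1/(1 + exp(F1 - F0)) is
        high and the protected exceedance collapses to 1/M."""
        F = np.zeros((8, 5))
        res = RandomEffectsBMS(F).fit(seed=0)
        assert res.F1 < res.F0
        assert res.bor > 0.8
        np.testing.assert_allclose(res.pxp, 0.2, atol=0.01)

    def test_strong_dominance_gives_low_bor(self):
        rng = np.random.default_rng(3)
        F = rng.normal(0, 1, (12, 4))
        F[:, 1] += 15.0
        res = RandomEffectsBMS(F).fit(seed=0)
        assert res.bor < 0.05
        np.testing.assert_allclose(res.pxp[1], res.xp[1], atol=0.05)

    def test_pxp_identity_and_normalisation(self):
        rng = np.random.default_rng(4)
        F = rng.normal(0, 2, (6, 3))
        res = RandomEffectsBMS(F).fit(seed=5)
        np.testing.assert_allclose(
            res.pxp, res.xp * (1 - res.bor) + res.bor / 3, atol=1e-12)
        assert res.pxp.sum() == pytest.approx(1.0, abs=1e-3)

    def test_requires_exceedance_first(self):
        F = np.zeros((3, 3))
        res = rfx_bms(F)
        with pytest.raises(ValueError):
            protected_exceedance(F, res)


class TestFamilyBms:
    def test_single_family_has_probability_one(self):
        F = np.random.default_rng(0).normal(0, 2, (5, 4))
        fr = family_bms(F, {"all": [0, 1, 2, 3]}, seed=0)
        assert fr.expected_freq[0] == pytest.approx(1.0)
        assert fr.exceedance[0] == pytest.approx(1.0)

    def test_symmetric_families_split_evenly(self):
        F = np.zeros((10, 4))
        fr = family_bms(F, {"a": [0, 1], "b": [2, 3]},
                        n_samples=200_000, seed=1)
        np.testing.assert_allclose(fr.exceedance, 0.5, atol=0.01)
        np.testing.assert_allclose(fr.expected_freq, 0.5, atol=1e-6)

    def test_prior_mass_equalised_across_unequal_families(self):
        F = np.zeros((1, 5))
        fr = family_bms(F, {"small": [0], "big": [1, 2, 3, 4]}, seed=0)
        a0 = fr.model_result.alpha0
        assert a0[0] == pytest.approx(1.0)
        np.testing.assert_allclose(a0[1:], 0.25)

    def test_dominant_family_wins(self):
        rng = np.random.default_rng(2)
        F = rng.normal(0, 1, (10, 6))
        F[:, [3, 4, 5]] += 12.0
        fr = family_bms(F, {"x": [0, 1, 2], "y": [3, 4, 5]}, seed=0)
        assert fr.winning_family == "y"
        assert fr.exceedance[1] > 0.95

    def test_bad_partitions_raise(self):
        F = np.zeros((3, 4))
        with pytest.raises(ValueError, match="empty"):
            family_bms(F, {"a": [], "b": [0, 1, 2, 3]})
        with pytest.raises(ValueError, match="disjoint"):
            family_bms(F, {"a": [0, 1], "b": [1, 2, 3]})
        with pytest.raises(ValueError, match="cover"):
            family_bms(F, {"a": [0, 1]})


class TestBpa:
    def test_single_subject_returned_unchanged(self):
        p = _posterior([1.0, -2.0], np.diag([0.5, 2.0]))
        res = bpa([p])
        np.testing.assert_allclose(res.mean, p.mean, atol=1e-12)
        np.testing.assert_allclose(res.cov, p.cov, atol=1e-12)

    def test_identical_posteriors_shrink_covariance_by_n(self):
        p = _posterior([0.3], [[0.8]])
        res = bpa([p] * 5)
        np.testing.assert_allclose(res.mean, [0.3], atol=1e-12)
        np.testing.assert_allclose(res.cov, [[0.8 / 5]], atol=1e-12)

    def test_two_unit_gaussians_closed_form(self):
        res = bpa([_posterior([0.0], [[1.0]]), _posterior([2.0], [[1.0]])])
        assert res.mean[0] == pytest.approx(1.0)
        assert res.cov[0, 0] == pytest.approx(0.5)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(6)
        posts = []
        for s in range(6):
            A = rng.normal(0, 1, (3, 3))
            posts.append(_posterior(rng.normal(0, 1, 3), A @ A.T + np.eye(3),
                                    sid=f"s{s}"))
        a = bpa(posts)
        b = bpa(posts[::-1])
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)
        np.testing.assert_allclose(a.cov, b.cov, atol=1e-12)

    def test_posterior_probability_range_and_flags(self):
        res = bpa([_posterior([3.0, 0.0], np.eye(2))])
        assert np.all(res.pp >= 0.5) and np.all(res.pp <= 1.0)
        assert res.significant[0]          # 3 SD from zero
        assert not res.significant[1]      # centred on zero -> Pp = 0.5

    def test_mismatched_names_raise(self):
        a = _posterior([0.0], [[1.0]], names=("x",))
        b = _posterior([0.0], [[1.0]], names=("y",))
        with pytest.raises(ValueError, match="name map"):
            bpa([a, b])

    def test_singular_covariance_names_subject(self):
        bad = _posterior([0.0, 0.0], np.zeros((2, 2)), sid="sub-07")
        good = _posterior([0.0, 0.0], np.eye(2))
        with pytest.raises(ValueError, match="sub-07"):
            bpa([good, bad])


def test_evidence_matrix_tsv_round_trip(tmp_path):
    F = np.random.default_rng(1).normal(0, 5, (4, 3))
    ev = EvidenceMatrix(F=F, model_ids=(10, 20, 30))
    ev.to_tsv(tmp_path / "F.tsv")
    back = EvidenceMatrix.from_tsv(tmp_path / "F.tsv")
    np.testing.assert_allclose(back.F, F)
    assert back.model_ids == (10, 20, 30)
    assert back.subject_ids == ev.subject_ids
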