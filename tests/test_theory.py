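"""Closed-form PSD/ePSD algebra: arithmetic cases, properties, MC oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from admixld import psd, theory


def _random_moments(rng):
    conc = rng.uniform(0.2, 10.0, size=2)
    return theory.PSDMoments.dirichlet(conc)


class TestMoments:
    def test_fixed_moments_consistency(self):
        m = theory.PSDMoments.fixed([0.5, 0.5])
        assert np.allclose(m.second.sum(axis=1), m.mean)
        assert m.second[0, 1] == 0.25

    def test_dirichlet_moments_match_sampling(self):
        m = theory.PSDMoments.dirichlet((8.0, 2.0))
        samp = np.random.default_rng(0).dirichlet((8.0, 2.0), size=200_000)
        emp = (samp[:, :, None] * samp[:, None, :]).mean(axis=0)
        assert np.allclose(m.second, emp, atol=3e-3)

    def test_inconsistent_moments_rejected(self):
        with pytest.raises(ValueError):
            theory.PSDMoments(mean=[0.5, 0.5], second=np.eye(2))


class TestVarAtt:
    def test_homogeneous_frequencies(self):
        m = theory.PSDMoments.dirichlet((3.0, 5.0))
        assert theory.var_att_marker(m, np.array([0.3, 0.3])) == pytest.approx(2 * 0.3 * 0.7)

    def test_single_ancestry(self):
        m = theory.PSDMoments.fixed([1.0, 0.0])
        assert theory.var_att_marker(m, np.array([0.2, 0.9])) == pytest.approx(2 * 0.2 * 0.8)

    def test_worked_value(self):
        m = theory.PSDMoments.fixed([0.5, 0.5])
        assert theory.var_att_marker(m, np.array([0.2, 0.8])) == pytest.approx(0.5)

    def test_two_ancestry_specialization_matches_general_form(self):
        # 2 sum g(1-g)E[P] + 2 (g1-g2)^2 E[P1 P2]
        rng = np.random.default_rng(11)
        for _ in range(50):
            m = _random_moments(rng)
            g = rng.uniform(0.05, 0.95, 2)
            special = 2 * np.sum(g * (1 - g) * m.mean) + 2 * (g[0] - g[1]) ** 2 * m.second[0, 1]
            assert theory.var_att_marker(m, g) == pytest.approx(special, rel=1e-12)


class TestVarTractor:
    def test_diagonal_values_and_structure(self):
        m = theory.PSDMoments.fixed([0.5, 0.5])
        V = theory.var_tractor_matrix(m, np.array([0.2, 0.8]))
        assert np.allclose(V, np.diag([0.16, 0.16]))

    def test_trace_bounded_by_att_variance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = _random_moments(rng)
            g = rng.uniform(0.05, 0.95, 2)
            assert np.trace(theory.var_tractor_matrix(m, g)) <= theory.var_att_marker(m, g) + 1e-12

    def test_empirical_covariance_of_centered_dosages(self):
        # PSD draws at one locus: covariance of the partitioned dosages
        # centred on local ancestry matches the diagonal matrix
        n = 100_000
        g = np.array([0.2, 0.8])
        P = psd.draw_global_ancestry(n, ("dirichlet", (2.0, 2.0)), seed=5)
        la = psd.draw_local_ancestry(P, 1, seed=6)
        geno = psd.partition_dosage(psd.draw_genotypes(la, psd.FreqTable(g[:, None]), seed=7), la)
        L = la.counts()[:, 0, :].astype(float)
        M = geno.partitioned[:, 0, :].astype(float)
        centered = M - L * g[None, :]  # E[M_l | L] = L_l g_l
        emp = centered.T @ centered / n
        pred = theory.var_tractor_matrix(P.moments(), g)
        se = 3.0 / np.sqrt(n)
        assert abs(emp[0, 1]) < 3 * se
        assert np.allclose(np.diag(emp), np.diag(pred), atol=0.01)


class TestPredictedSE:
    def test_single_ancestry_arithmetic(self):
        m = theory.PSDMoments.fixed([1.0, 0.0])
        se = theory.predicted_se("att", m, np.array([0.5, 0.5]), 1.0, 5000)
        assert se == pytest.approx(np.sqrt(1.0 / (5000 * 0.5)))

    def test_tractor_se_is_single_continental_inflated(self):
        # se_l = single-continental se / sqrt(E[P_l])
        m = theory.PSDMoments.fixed([0.3, 0.7])
        g = np.array([0.4, 0.4])
        tr = theory.predicted_se("tractor", m, g, 1.0, 1000)
        single = np.sqrt(1.0 / (1000 * 2 * 0.4 * 0.6))
        assert tr[0] == pytest.approx(single / np.sqrt(0.3))
        assert tr[1] == pytest.approx(single / np.sqrt(0.7))

    def test_monomorphic_rejected(self):
        m = theory.PSDMoments.fixed([0.5, 0.5])
        with pytest.raises(ValueError):
            theory.predicted_se("att", m, np.array([0.0, 0.0]), 1.0, 100)


class TestExpectedStatistics:
    def test_equality_when_frequencies_match(self):
        m = theory.PSDMoments.dirichlet((4.0, 4.0))
        per, combined, att = theory.expected_statistics(0.5, m, np.array([0.3, 0.3]), 1.0)
        assert combined == pytest.approx(att)

    def test_null_effect(self):
        m = theory.PSDMoments.fixed([0.5, 0.5])
        per, combined, att = theory.expected_statistics(0.0, m, np.array([0.2, 0.8]), 1.0)
        assert combined == 0.0 and att == 0.0 and np.all(per == 0.0)

    def test_strict_ordering_worked_case(self):
        m = theory.PSDMoments.fixed([0.5, 0.5])
        per, combined, att = theory.expected_statistics(1.0, m, np.array([0.2, 0.8]), 1.0)
        assert np.allclose(per, [0.16, 0.16])
        assert combined == pytest.approx(0.32)
        assert att == pytest.approx(0.5)

    @settings(max_examples=300, derandomize=True)
    @given(
        a1=st.floats(0.1, 20.0), a2=st.floats(0.1, 20.0),
        g1=st.floats(0.01, 0.99), g2=st.floats(0.01, 0.99),
        beta=st.floats(-3.0, 3.0),
    )
    def test_ordering_property(self, a1, a2, g1, g2, beta):
        """per-ancestry <= combined <= ATT for any simplex moments/frequencies."""
        m = theory.PSDMoments.dirichlet((a1, a2))
        per, combined, att = theory.expected_statistics(beta, m, np.array([g1, g2]), 1.0)
        assert per.max() <= combined + 1e-9
        assert combined <= att + 1e-9


class TestEpsdCoefficients:
    def test_marker_is_causal_variant(self):
        g = np.array([0.3, 0.7])
        ld = theory.LDParams(f=g[:, None], g=g, h=g[:, None])
        beta = theory.beta_tractor_epsd(ld, [1.3])
        assert np.allclose(beta, 1.3)
        assert np.allclose(theory.gamma_tractor_epsd(ld, [1.3]), 0.0)

    def test_unlinked_set_gives_zero(self):
        g = np.array([0.5, 0.5])
        f = np.array([[0.4], [0.4]])
        ld = theory.LDParams(f=f, g=g, h=f * 0.5)  # D = 0
        assert theory.beta_tractor_epsd(ld, [2.0])[0] == 0.0

    def test_weighted_sum_arithmetic(self):
        g = np.array([0.5, 0.5])
        f = np.full((2, 2), 0.5)
        D = np.array([[0.08, -0.04], [0.08, -0.04]])
        ld = theory.LDParams(f=f, g=g, h=D + 0.25)
        beta = theory.beta_tractor_epsd(ld, [1.0, 0.5])
        assert beta[0] == pytest.approx((0.08 - 0.02) / 0.25)

    def test_gamma_arithmetic(self):
        ld = theory.LDParams(f=[[0.3], [0.3]], g=np.array([0.3, 0.3]), h=[[0.3], [0.25]])
        gamma = theory.gamma_tractor_epsd(ld, [1.0])
        assert gamma[0] == pytest.approx((0.3 - 0.25) / 0.7 - 0.0, rel=1e-9)

    def test_frechet_violation_rejected(self):
        with pytest.raises(ValueError):
            theory.LDParams(f=[[0.1], [0.1]], g=np.array([0.1, 0.1]), h=[[0.2], [0.1]])


class TestBetaAttEpsd:
    def test_reduces_to_tractor_weighting_when_homogeneous(self):
        g = np.array([0.4, 0.4])
        f = np.array([[0.3], [0.3]])
        h = f * g[:, None] + 0.05
        ld = theory.LDParams(f=f, g=g, h=h)
        m = theory.PSDMoments.fixed([0.6, 0.4])
        att = theory.beta_att_epsd(ld, [1.0], m, la_cov=None)
        assert att == pytest.approx(theory.beta_tractor_epsd(ld, [1.0])[0])

    def test_marker_is_sole_causal_with_la_cov(self):
        g = np.array([0.3, 0.7])
        ld = theory.LDParams(f=g[:, None], g=g, h=g[:, None])
        p = np.array([0.5, 0.5])
        m = theory.PSDMoments.fixed(p)

        def la_cov(l, lp, j):
            return theory.la_covariance_pulse(p, l, lp, 0.0, 12)

        assert theory.beta_att_epsd(ld, [1.0], m, la_cov) == pytest.approx(1.0)

    def test_remote_causal_contributes_nothing(self):
        g = np.array([0.4, 0.6])
        f = np.array([[0.3], [0.5]])
        ld = theory.LDParams(f=f, g=g, h=f * g[:, None])  # D = 0
        m = theory.PSDMoments.dirichlet((8.0, 2.0))
        assert theory.beta_att_epsd(ld, [5.0], m, la_cov=None) == 0.0


class TestLaCovariancePulse:
    def test_zero_distance_same_ancestry(self):
        assert theory.la_covariance_pulse([0.5, 0.5], 0, 0, 0.0, 12) == pytest.approx(0.25)

    def test_zero_distance_cross_ancestry(self):
        assert theory.la_covariance_pulse([0.5, 0.5], 0, 1, 0.0, 12) == pytest.approx(-0.25)

    def test_exponential_decay_matches_mosaic_process(self):
        # Monte-Carlo over the Poisson-breakpoint ancestry process
        rng = np.random.default_rng(8)
        g_gen, d = 12, 0.05
        n = 200_000
        # ancestry at 0 and at d: same iff no breakpoint (prob e^{-g d});
        # otherwise redrawn independently
        a0 = rng.random(n) < 0.5
        redraw = rng.random(n) > np.exp(-g_gen * d)
        a1 = np.where(redraw, rng.random(n) < 0.5, a0)
        emp = np.cov(a0.astype(float), a1.astype(float))[0, 1]
        pred = theory.la_covariance_pulse([0.5, 0.5], 0, 0, d, g_gen)
        assert pred == pytest.approx(0.25 * np.exp(-0.6), rel=1e-12)
        assert abs(emp - pred) < 3 * 0.25 / np.sqrt(n)


class TestLdWeights:
    def test_perfect_ld_equal_freqs(self):
        f = g = 0.4
        D = g * (1 - g)
        assert theory.epsd_ld_weight(D, g) == pytest.approx(1.0)
        assert theory.epsd_ld_corr(D, g, f) == pytest.approx(1.0)

    def test_null_ld(self):
        assert theory.epsd_ld_weight(0.0, 0.3) == 0.0
        assert theory.epsd_ld_corr(0.0, 0.3, 0.6) == 0.0

    def test_arithmetic(self):
        assert theory.epsd_ld_weight(0.08, 0.5) == pytest.approx(0.32)
        assert theory.epsd_ld_corr(0.08, 0.5, 0.5) == pytest.approx(0.32)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            theory.epsd_ld_weight(0.0, 1.0)


class TestEffectiveN:
    @pytest.mark.parametrize("p,deflation", [(1.0, 1.0), (0.25, 0.5)])
    def test_factors(self, p, deflation):
        inflation, z_defl, mult = theory.effective_n_factor(p)
        assert z_defl == pytest.approx(deflation)
        assert inflation == pytest.approx(1.0 / deflation)
        assert mult == pytest.approx(deflation)

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            theory.effective_n_factor(0.0)
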