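import numpy as np
import pytest

import hypersis as hs
from hypersis.meanfield import count_fixed_points

G = 2.0


def params(**kw):
    base = dict(gamma=G, beta2=0.0, beta3=0.0)
    base.update(kw)
    return hs.EpidemicParams(**base)


class TestRHS:
    def test_disease_free_state_is_an_equilibrium(self, pl4):
        x = np.zeros(pl4.support.size)
        for rule in ("collective", "individual"):
            d = hs.rhs_general(x, pl4, params(beta2=0.05, beta3=0.05, rule=rule))
            np.testing.assert_array_equal(d, 0.0)

    def test_fully_infected_state_decays(self, pl4):
        x = np.ones(pl4.support.size)
        d = hs.rhs_general(x, pl4, params(beta2=0.05, beta3=0.05))
        np.testing.assert_allclose(d, -G)

    def test_rules_coincide_for_pairwise_only(self, pl4):
        rng = np.random.default_rng(0)
        x = rng.random(pl4.support.size)
        d_coll = hs.rhs_general(x, pl4, params(beta2=0.02, rule="collective"))
        d_ind = hs.rhs_general(x, pl4, params(beta2=0.02, rule="individual"))
        np.testing.assert_allclose(d_coll, d_ind, rtol=1e-14)

    def test_all_sizes_model_reduces_to_pairwise_at_m2(self, pl4):
        rng = np.random.default_rng(1)
        x = rng.random(pl4.support.size)
        d_pair = hs.rhs_general(x, pl4, params(beta2=0.02))
        d_allm = hs.rhs_general(
            x, pl4, params(beta_m={2: 0.02}, mean_km={2: pl4.mean}, rule="individual")
        )
        np.testing.assert_allclose(d_pair, d_allm, rtol=1e-12)


class TestIntegration:
    def test_subcritical_epidemic_dies_out(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        traj = hs.integrate_meanfield(pl4, params(beta2=0.5 * b2c), x0=0.05, t_end=200.0)
        assert traj.U[-1] < 1e-6
        assert np.all((traj.x >= 0) & (traj.x <= 1))

    def test_regular_graph_closed_form_prevalence(self, reg100):
        # links-only SIS on a regular network: U_inf = 1 - gamma/(beta2 k)
        traj = hs.integrate_meanfield(reg100, params(beta2=0.03), x0=0.5, t_end=200.0)
        assert traj.U[-1] == pytest.approx(1 - G / (0.03 * 100), abs=1e-6)

    def test_bistability_initial_condition_selects_branch(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        b3 = 2.0 * hs.beta3c_analytic_correlated(pl4, G)
        p = params(beta2=0.95 * b2c, beta3=b3)
        low = hs.integrate_meanfield(pl4, p, x0=0.001, t_end=400.0)
        high = hs.integrate_meanfield(pl4, p, x0=0.5, t_end=400.0)
        assert low.U[-1] < 1e-4
        assert high.U[-1] > 0.3

    def test_invalid_initial_condition_rejected(self, pl4):
        with pytest.raises(ValueError):
            hs.integrate_meanfield(pl4, params(beta2=0.01), x0=1.5, t_end=1.0)


class TestSelfConsistency:
    def test_origin_is_always_a_root(self, pl4):
        for rule in ("collective", "individual"):
            for sign in ("contagion", "healing"):
                p = params(beta2=0.02, beta3=0.03, rule=rule, triangle_sign=sign)
                assert hs.selfconsistency_correlated(0.0, pl4, p) == 0.0
        assert hs.selfconsistency_uncorrelated(0.0, 0.0, pl4, params(beta2=0.02, beta3=0.03)) == (0.0, 0.0)

    def test_regular_nonzero_root_closed_form(self, reg100):
        fps = hs.find_fixed_points(reg100, params(beta2=0.03))
        assert len(fps) == 2
        root = fps.roots[1]
        assert root.V == pytest.approx(1 / 3, abs=1e-10)
        assert root.U == pytest.approx(1 / 3, abs=1e-10)

    def test_individual_linearization_threshold(self, pl4):
        # residual slope at the origin changes sign exactly at
        # beta2 + 2 beta3 = gamma <k>/<k^2>
        b3 = 0.004
        b2_star = G * pl4.moment(1) / pl4.moment(2) - 2 * b3
        eps = 1e-8
        below = hs.selfconsistency_correlated(1e-6, pl4, params(beta2=b2_star * (1 - 1e-3), beta3=b3, rule="individual"))
        above = hs.selfconsistency_correlated(1e-6, pl4, params(beta2=b2_star * (1 + 1e-3), beta3=b3, rule="individual"))
        assert below < 0 < above

    def test_residuals_vanish_at_found_roots(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        b3 = 2.0 * hs.beta3c_analytic_correlated(pl4, G)
        for wiring in ("correlated", "uncorrelated"):
            p = params(beta2=0.97 * b2c, beta3=b3, wiring=wiring)
            for root in hs.find_fixed_points(pl4, p).roots:
                rU, rV = hs.selfconsistency_uncorrelated(root.U, root.V, pl4, p) if wiring == "uncorrelated" else (0.0, hs.selfconsistency_correlated(root.V, pl4, p))
                assert abs(rV) < 1e-10
                assert abs(rU) < 1e-10

    def test_regular_distribution_collapses_wirings(self, reg100):
        # single degree class: U = V and the uncorrelated system reduces to
        # the correlated one, root for root
        p_corr = params(beta2=0.025, beta3=0.03, wiring="correlated")
        p_unc = params(beta2=0.025, beta3=0.03, wiring="uncorrelated")
        r_corr = hs.find_fixed_points(reg100, p_corr)
        r_unc = hs.find_fixed_points(reg100, p_unc)
        assert len(r_corr) == len(r_unc)
        for a, b in zip(r_corr.roots, r_unc.roots):
            assert a.V == pytest.approx(b.V, abs=1e-8)
            assert a.stable == b.stable


class TestFixedPointCounts:
    def test_three_regimes(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        b3c = hs.beta3c_analytic_correlated(pl4, G)
        assert count_fixed_points(pl4, params(beta2=0.5 * b2c, beta3=0.5 * b3c)) == 1
        assert count_fixed_points(pl4, params(beta2=1.2 * b2c, beta3=0.5 * b3c)) == 2
        assert count_fixed_points(pl4, params(beta2=0.97 * b2c, beta3=2.0 * b3c)) == 3

    @pytest.mark.parametrize(
        "b2_rel, b3_rel, expect_labels",
        [
            (0.97, 2.0, [True, False, True]),   # bistable
            (1.20, 0.5, [False, True]),         # supercritical, monostable
        ],
    )
    def test_stability_labels_consistent_with_dynamics(self, pl4, b2_rel, b3_rel, expect_labels):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        p = params(beta2=b2_rel * b2c, beta3=b3_rel * hs.beta3c_analytic_correlated(pl4, G))
        fps = hs.find_fixed_points(pl4, p)
        assert [r.stable for r in fps.roots] == expect_labels
        for root in fps.roots:
            x0 = np.clip(root.x_k + 1e-4, 0.0, 1.0)
            traj = hs.integrate_meanfield(pl4, p, x0=x0, t_end=300.0)
            if root.stable:
                assert abs(traj.U[-1] - root.U) < 1e-3
            else:
                assert abs(traj.U[-1] - root.U) > 1e-2

    def test_collective_healing_never_bistable(self, pl4):
        # coarse grid over non-negative rates: no parameter point with 3 roots
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        b3c = hs.beta3c_analytic_correlated(pl4, G)
        for b2 in np.linspace(0, 2 * b2c, 7):
            for b3 in np.linspace(0, 6 * b3c, 7):
                n = count_fixed_points(pl4, params(beta2=float(b2), beta3=float(b3), triangle_sign="healing"))
                assert n <= 2

    def test_uncorrelated_healing_unsupported(self, pl4):
        with pytest.raises(NotImplementedError):
            hs.find_fixed_points(pl4, params(beta2=0.01, beta3=0.01, wiring="uncorrelated", triangle_sign="healing"))


class TestThresholds:
    def test_beta2c_regular(self, reg100):
        assert hs.epidemic_threshold_beta2c(reg100, G) == pytest.approx(0.02, abs=1e-15)
        assert hs.epidemic_threshold_beta2c(reg100, 0.0) == 0.0

    def test_beta2c_powerlaw_by_direct_summation(self, pl4):
        k = pl4.support.astype(float)
        expect = G * (pl4.probs * k).sum() / (pl4.probs * k * k).sum()
        assert hs.epidemic_threshold_beta2c(pl4, G) == pytest.approx(expect, rel=1e-14)
        assert expect == pytest.approx(0.0159, abs=0.0005)

    def test_beta2c_degenerate_rejected(self):
        with pytest.raises(ValueError):
            hs.epidemic_threshold_beta2c(hs.make_regular(0), G)

    def test_individual_threshold_reduces_at_beta3_zero(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        for wiring in ("correlated", "uncorrelated"):
            assert hs.threshold_individual(pl4, G, 0.0, wiring) == pytest.approx(b2c, rel=1e-15)

    def test_individual_threshold_regular_linear(self, reg100):
        assert hs.threshold_individual(reg100, G, 0.005, "correlated") == pytest.approx(0.01, abs=1e-15)

    @pytest.mark.parametrize("beta3", [0.001, 0.004, 0.008])
    def test_wirings_agree_for_regular(self, reg100, beta3):
        a = hs.threshold_individual(reg100, G, beta3, "correlated")
        b = hs.threshold_individual(reg100, G, beta3, "uncorrelated")
        assert a == pytest.approx(b, rel=1e-12)

    def test_uncorrelated_pole_raises(self, pl4):
        m1, m2 = pl4.moment(1), pl4.moment(2)
        pole = G * m2 / (2 * (m2 - m1**2) * m1)
        # just before the pole the formula is already negative (non-physical)
        assert hs.threshold_individual(pl4, G, pole * 0.999, "uncorrelated") < 0
        with pytest.raises(ZeroDivisionError):
            hs.threshold_individual(pl4, G, pole, "uncorrelated")

    def test_healing_substitutes_negative_beta3(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        assert hs.threshold_individual(pl4, G, 0.01, "correlated", "healing") == pytest.approx(b2c + 0.02)


class TestMultisize:
    def test_m2_reduces_to_pairwise_comparison(self, pl4):
        b2c = hs.epidemic_threshold_beta2c(pl4, G)
        lhs, rhs, prop = hs.threshold_multisize(pl4, G, {2: 1.01 * b2c}, {2: pl4.mean})
        assert prop and lhs == pytest.approx(1.01 * b2c)
        assert rhs == pytest.approx(b2c)

    def test_m3_with_matched_mean_equals_individual_threshold(self, pl4):
        b2, b3 = 0.004, 0.005
        lhs, rhs, _ = hs.threshold_multisize(pl4, G, {2: b2, 3: b3}, {2: pl4.mean, 3: pl4.mean})
        assert lhs == pytest.approx(b2 + 2 * b3, rel=1e-14)

    def test_truncating_sizes_never_raises_the_sum(self, pl4):
        beta_m = {2: 0.003, 3: 0.002, 4: 0.001, 5: 0.001}
        mean_km = {m: pl4.mean / (m - 1) for m in beta_m}
        full, _, _ = hs.threshold_multisize(pl4, G, beta_m, mean_km)
        prev = full
        for cutoff in (4, 3, 2):
            trunc = {m: b for m, b in beta_m.items() if m <= cutoff}
            lhs, _, _ = hs.threshold_multisize(pl4, G, trunc, mean_km)
            assert lhs <= prev + 1e-15
            prev = lhs
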