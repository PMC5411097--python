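"""Closed-form steady-state theory and its numeric cross-checks."""

import numpy as np
import pytest

from crisprdyn import (
    MultiSpacerParams,
    RegimeLabel,
    SingleSpacerParams,
    SingleState,
    SteadyStateError,
    classify_regime,
    coexistence_state_single,
    critical_failure_probability,
    mean_failure_probability,
    multi_rhs,
    solve_coexistence_multi,
    spacer_ratio_single,
    steady_state_numeric,
    unused_capacity_multi,
    unused_capacity_single,
)


def sp(**kw) -> SingleSpacerParams:
    base = dict(f0=1.0, r=1.0, K=1e5, kappa=1e-2, g=1e-5, eta=0.005, alpha=1e-4, mu=1.0, b=100.0)
    base.update(kw)
    return SingleSpacerParams(**base)


class TestUnusedCapacitySingle:
    def test_collapses_to_loss_ratio_without_acquisition_or_failure(self):
        # alpha = eta = 0: the (b(1-alpha)-1)/((b-1)(1-b eta)) factor is 1
        assert unused_capacity_single(sp(alpha=0.0, eta=0.0)) == pytest.approx(1e-2, rel=1e-14)

    def test_no_spacer_loss_means_full_capacity(self):
        assert unused_capacity_single(sp(kappa=0.0)) == 0.0

    def test_hand_value(self):
        # (kappa/f0) * (b(1-alpha)-1) / ((b-1)(1-b eta)) = 0.01*98.99/(99*0.5)
        assert unused_capacity_single(sp()) == pytest.approx(0.0199979797979798, rel=1e-12)

    def test_requires_equal_growth_rates(self):
        with pytest.raises(SteadyStateError, match="steady_state_numeric"):
            unused_capacity_single(sp(r=1.1))

    def test_invalid_beyond_critical_product(self):
        with pytest.raises(SteadyStateError):
            unused_capacity_single(sp(eta=0.02))

    def test_strictly_increasing_in_eta(self):
        etas = np.linspace(0.0, 0.009, 30)
        F = [unused_capacity_single(sp(eta=e)) for e in etas]
        assert np.all(np.diff(F) > 0)

    def test_linearly_decreasing_in_alpha(self):
        alphas = np.linspace(0.0, 0.5, 20)
        F = np.array([unused_capacity_single(sp(alpha=a)) for a in alphas])
        assert np.all(np.diff(F) < 0)
        # linear: second differences vanish
        np.testing.assert_allclose(np.diff(F, 2), 0.0, atol=1e-15)

    def test_diverges_approaching_critical_failure(self):
        # F grows without bound as b*eta -> 1
        vals = [unused_capacity_single(sp(eta=e)) for e in (0.009, 0.0099, 0.00999)]
        assert vals[0] < vals[1] < vals[2]
        assert vals[2] > 100 * vals[0]


class TestCriticalFailureProbability:
    def test_no_loss_gives_inverse_burst(self):
        assert critical_failure_probability(sp(kappa=0.0)) == pytest.approx(0.01, rel=1e-14)

    def test_loss_lowers_the_threshold(self):
        assert critical_failure_probability(sp(kappa=1e-2)) < 0.01

    def test_hand_value(self):
        assert critical_failure_probability(sp(alpha=0.0)) == pytest.approx(0.0099, rel=1e-12)


class TestSpacerRatio:
    def test_perfect_spacer_no_acquisition(self):
        assert spacer_ratio_single(sp(alpha=0.0, eta=0.0)) == pytest.approx(99.0, rel=1e-14)

    def test_hand_value(self):
        assert spacer_ratio_single(sp()) == pytest.approx(197.98, rel=1e-12)

    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_independent_of_growth_rate_ratio(self, r):
        assert spacer_ratio_single(sp(r=r)) == spacer_ratio_single(sp(r=1.0))

    def test_undefined_when_crispr_ineffective(self):
        with pytest.raises(SteadyStateError):
            spacer_ratio_single(sp(eta=0.011))


class TestMeanFailureProbability:
    def test_uniform_abundance_gives_arithmetic_mean(self):
        eta = np.array([0.1, 0.2, 0.6])
        assert mean_failure_probability(np.ones(3), eta) == pytest.approx(0.3)

    def test_point_mass_gives_that_spacer(self):
        assert mean_failure_probability([0.0, 5.0], [0.3, 0.7]) == 0.7

    def test_hand_value(self):
        assert mean_failure_probability([1.0, 3.0], [0.0, 0.01]) == pytest.approx(0.0075)

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(7)
        n = rng.uniform(0, 1, 10)
        eta = rng.uniform(0, 1, 10)
        m = mean_failure_probability(n, eta)
        assert eta.min() <= m <= eta.max()

    def test_all_zero_abundance_rejected(self):
        with pytest.raises(ValueError):
            mean_failure_probability([0.0, 0.0], [0.1, 0.2])


class TestUnusedCapacityMulti:
    def test_matches_single_at_common_eta(self):
        p = MultiSpacerParams(
            alpha_vec=[5e-5, 5e-5], eta_vec=[0.005, 0.005], kappa=1e-2, g=1e-5
        )
        expected = unused_capacity_single(sp(eta=0.005, alpha=1e-4))
        assert unused_capacity_multi(0.005, p) == pytest.approx(expected, rel=1e-14)

    def test_hand_value_at_zero_mean_failure(self):
        p = MultiSpacerParams(
            alpha_vec=np.full(20, 0.0972 / 20), eta_vec=np.zeros(20), kappa=1e-2, g=1e-4
        )
        assert unused_capacity_multi(0.0, p) == pytest.approx(0.00901818181818182, rel=1e-12)

    def test_no_loss_gives_zero(self):
        p = MultiSpacerParams(alpha_vec=[0.01], eta_vec=[0.0], kappa=0.0)
        assert unused_capacity_multi(0.0, p) == 0.0


def fig_style_multi(eta_vec, alpha_vec) -> MultiSpacerParams:
    return MultiSpacerParams(
        alpha_vec=alpha_vec, eta_vec=eta_vec, f=1.0, K=1e5, kappa=1e-2, g=1e-4, mu=1.0, b=100.0
    )


class TestSolveCoexistenceMulti:
    def test_common_eta_reduces_to_single_theory(self):
        """Equal eta_i: eta_bar is that eta and abundances are proportional to alpha_i."""
        alpha = np.array([0.01, 0.02, 0.03])
        p = fig_style_multi(np.full(3, 0.004), alpha)
        sol = solve_coexistence_multi(p)
        assert sol.valid
        assert sol.eta_bar == pytest.approx(0.004, abs=1e-14)
        fr = sol.n_vec_star / sol.n_vec_star.sum()
        np.testing.assert_allclose(fr, alpha / alpha.sum(), rtol=1e-12)

    def test_symmetric_spacers_give_uniform_abundance(self):
        p = fig_style_multi(np.full(5, 0.003), np.full(5, 0.01))
        sol = solve_coexistence_multi(p)
        np.testing.assert_allclose(sol.n_vec_star, sol.n_vec_star[0], rtol=1e-12)

    def test_self_consistency_and_residual(self):
        eta = np.linspace(0.0005, 0.0095, 20)
        p = fig_style_multi(eta, np.full(20, 0.0972 / 20))
        sol = solve_coexistence_multi(p)
        assert sol.valid
        # the solved eta_bar reproduces itself through the abundances
        recomputed = mean_failure_probability(sol.n_vec_star, eta)
        assert abs(recomputed - sol.eta_bar) < 1e-10
        # full-state stationarity
        assert sol.residual_norm < 1e-8 * p.K
        # closed-form total abundance ratio
        assert sol.diagnostics["ratio_sum"] == pytest.approx(
            sol.diagnostics["ratio_sum_closed_form"], rel=1e-10
        )

    def test_total_population_is_capacity_shortfall(self):
        p = fig_style_multi(np.linspace(0.001, 0.009, 10), np.full(10, 0.005))
        sol = solve_coexistence_multi(p)
        assert sol.n_total == pytest.approx(p.K * (1 - sol.F), rel=1e-12)

    def test_matches_numeric_root_find(self):
        eta = np.linspace(0.0005, 0.0095, 20)
        p = fig_style_multi(eta, np.full(20, 0.0972 / 20))
        sol = solve_coexistence_multi(p)
        numeric = steady_state_numeric(p, sol.state())
        np.testing.assert_allclose(
            numeric.to_array(), sol.state().to_array(), rtol=1e-6, atol=1e-9 * p.K
        )

    def test_requires_spacer_loss(self):
        p = MultiSpacerParams(alpha_vec=[0.01], eta_vec=[0.005], kappa=0.0)
        with pytest.raises(SteadyStateError, match="spacer loss"):
            solve_coexistence_multi(p)

    def test_assembled_state_is_stationary(self):
        p = fig_style_multi(np.linspace(0.002, 0.008, 6), np.linspace(1, 6, 6) / 210)
        sol = solve_coexistence_multi(p)
        resid = np.linalg.norm(multi_rhs(sol.state(), p))
        assert resid < 1e-8 * p.K


class TestSingleCoexistenceAssembly:
    def test_numeric_oracle_agrees_with_closed_forms(self):
        p = sp()
        ana = coexistence_state_single(p)
        perturbed = SingleState(
            n0=ana.n0 * 1.3, n1=ana.n1 * 0.7, I0=ana.I0 * 1.1, I1=ana.I1, v=ana.v * 0.9
        )
        num = steady_state_numeric(p, perturbed)
        np.testing.assert_allclose(num.to_array(), ana.to_array(), rtol=1e-6)

    def test_capacity_fixed_point_found_from_phage_free_guess(self):
        p = sp(kappa=0.0, eta=0.0, alpha=0.0)
        st = steady_state_numeric(p, SingleState(n0=p.K))
        assert st.n0 == pytest.approx(p.K, rel=1e-10)
        assert st.v == pytest.approx(0.0, abs=1e-6)

    def test_unequal_growth_rates_fixed_point_is_stationary(self):
        """r != 1 has no closed form; the numeric fixed point must still be a root."""
        p = sp(r=1.05)
        guess = coexistence_state_single(sp())
        st = steady_state_numeric(p, guess)
        from crisprdyn import single_rhs

        resid = np.linalg.norm(single_rhs(st, p))
        assert resid < 1e-6
        assert np.all(st.to_array() > 0)

    def test_nonconvergence_reports_residual(self):
        p = sp(eta=0.02)  # no coexistence fixed point near this guess
        with pytest.raises((SteadyStateError, ValueError)):
            st = steady_state_numeric(p, SingleState(n0=1.0, n1=1.0, I0=1.0, I1=1.0, v=1.0))
            # if a root was found it must not be an interior coexistence point
            assert not np.all(st.to_array() > 1.0)
            raise SteadyStateError("reached a spurious root")


class TestClassifyRegime:
    def test_reference_coexistence_regime(self):
        assert classify_regime(sp(kappa=2e-3)) is RegimeLabel.coexistence

    def test_no_loss_effective_spacer_clears_phage(self):
        assert classify_regime(sp(kappa=0.0, eta=0.0)) is RegimeLabel.phage_extinction

    def test_useless_spacer_dooms_bacteria(self):
        assert classify_regime(sp(eta=1.0)) is RegimeLabel.bacterial_extinction

    def test_no_loss_ineffective_spacer(self):
        assert classify_regime(sp(kappa=0.0, eta=0.05)) is RegimeLabel.bacterial_extinction

    def test_boundary_at_critical_value_is_conservative(self):
        p = sp(alpha=0.0)
        eta_c = critical_failure_probability(p)
        assert classify_regime(sp(alpha=0.0, eta=eta_c)) is RegimeLabel.bacterial_extinction
        assert classify_regime(sp(alpha=0.0, eta=0.999 * eta_c)) is RegimeLabel.coexistence

    def test_unequal_growth_rates_probed_numerically(self):
        assert classify_regime(sp(r=1.05)) is RegimeLabel.coexistence
        assert classify_regime(sp(r=1.05, eta=0.05)) is RegimeLabel.bacterial_extinction
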