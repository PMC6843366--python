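import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclofit import (
    BindingModel,
    TitrationData,
    ValidationError,
    fit_titration,
    gen_titration,
    predict_absorbance,
    residual_trend_test,
    select_model,
    solve_speciation,
)
from cyclofit.equilibria import TitrationModel, speciation_matrix


def complex_1to1_closed_form(k, h_tot, g_tot):
    """Quadratic oracle for [HG]: x^2 - (h+g+1/K)x + hg = 0, smaller root.

    Written in the cancellation-free form 2hg / (b + sqrt(b^2 - 4hg)).
    """
    b = h_tot + g_tot + 1.0 / k
    disc = b * b - 4.0 * h_tot * g_tot
    return 2.0 * h_tot * g_tot / (b + math.sqrt(disc))


class TestSpeciation:
    def test_no_complexes_leaves_totals_free(self):
        m = BindingModel([(1, 1, -math.inf)])
        st_ = solve_speciation(m, 1e-3, 2e-3)
        assert st_.free_h == pytest.approx(1e-3)
        assert st_.free_g == pytest.approx(2e-3)
        assert st_.conc[(1, 1)] == 0.0

    def test_equimolar_1to1_matches_quadratic(self):
        m = BindingModel([(1, 1, math.log10(6025))])
        st_ = solve_speciation(m, 4.43e-5, 4.43e-5)
        assert st_.conc[(1, 1)] == pytest.approx(7.96e-6, rel=1e-3)
        assert st_.conc[(1, 1)] == pytest.approx(
            complex_1to1_closed_form(6025, 4.43e-5, 4.43e-5), rel=1e-9
        )

    def test_zero_host_leaves_guest_free(self):
        m = BindingModel([(1, 1, 4.0)])
        st_ = solve_speciation(m, 0.0, 1e-4)
        assert st_.free_h == 0.0
        assert st_.free_g == pytest.approx(1e-4)
        assert st_.conc[(1, 1)] == 0.0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(
        log_k=st.floats(0.0, 8.0),
        log_h=st.floats(-7.0, -2.0),
        log_g=st.floats(-7.0, -2.0),
    )
    def test_agreement_with_closed_form_across_regimes(self, log_k, log_h, log_g):
        k, h, g = 10.0 ** log_k, 10.0 ** log_h, 10.0 ** log_g
        m = BindingModel([(1, 1, log_k)])
        st_ = solve_speciation(m, h, g)
        oracle = complex_1to1_closed_form(k, h, g)
        assert st_.conc[(1, 1)] == pytest.approx(oracle, rel=1e-9, abs=1e-25)
        # mass balance to 1e-10 relative
        assert st_.total_h() == pytest.approx(h, rel=1e-10)
        assert st_.total_g() == pytest.approx(g, rel=1e-10)

    def test_two_complex_system_mass_balance(self):
        m = BindingModel([(1, 1, 3.8), (2, 1, 6.5)])
        st_ = solve_speciation(m, 5e-4, 1e-4)
        assert st_.total_h() == pytest.approx(5e-4, rel=1e-10)
        assert st_.total_g() == pytest.approx(1e-4, rel=1e-10)

    def test_bound_fraction_monotone_in_host_and_constant(self):
        g = 4.43e-5
        hs = np.logspace(-6, -2, 12)
        for log_k in (2.0, 3.78, 5.0):
            m = BindingModel([(1, 1, log_k)])
            fr = [solve_speciation(m, h, g).bound_guest_fraction() for h in hs]
            assert all(a <= b + 1e-12 for a, b in zip(fr, fr[1:]))
        f_by_k = [
            solve_speciation(BindingModel([(1, 1, lk)]), 1e-4, g).bound_guest_fraction()
            for lk in (2.0, 3.0, 4.0, 5.0)
        ]
        assert all(a < b for a, b in zip(f_by_k, f_by_k[1:]))


class TestPredictAbsorbance:
    def setup_method(self):
        self.model = BindingModel([(1, 1, math.log10(6025))])
        self.wl = np.linspace(200, 400, 21)
        self.data = TitrationData(
            g_tot=4.43e-5,
            h_tot=np.array([0.0, 1e-4, 1e-3]),
            wavelengths=self.wl,
            absorbance=np.zeros((3, 21)),
        )

    def test_zero_epsilon_gives_zero_matrix(self):
        eps = {(0, 1): np.zeros(21), (1, 1): np.zeros(21)}
        assert np.all(predict_absorbance(self.model, eps, self.data) == 0)

    def test_free_guest_only_scales_with_free_concentration(self):
        eps = {(0, 1): np.full(21, 1e4), (1, 1): np.zeros(21)}
        a = predict_absorbance(self.model, eps, self.data)
        frees = [solve_speciation(self.model, h, 4.43e-5).free_g for h in self.data.h_tot]
        np.testing.assert_allclose(a[:, 0], 1e4 * np.array(frees), rtol=1e-9)

    def test_matches_per_cell_summation_oracle(self, rng):
        eps = {(0, 1): rng.uniform(0, 2e4, 21), (1, 1): rng.uniform(0, 2e4, 21)}
        a = predict_absorbance(self.model, eps, self.data)
        c = speciation_matrix(self.model, self.data.h_tot, self.data.g_tot)
        brute = np.array(
            [
                [sum(c[i, s] * eps[k][j] for s, k in enumerate(self.model.absorbing))
                 for j in range(21)]
                for i in range(3)
            ]
        )
        np.testing.assert_allclose(a, brute, rtol=1e-12)

    def test_missing_epsilon_rejected(self):
        with pytest.raises(ValidationError):
            predict_absorbance(self.model, {(0, 1): np.zeros(21)}, self.data)


class TestTitrationFit:
    def test_noiseless_round_trip_recovers_log_beta(self):
        data = gen_titration(noise_sd=0.0)
        res = fit_titration(data, BindingModel([(1, 1, 3.0)]), starts=3, seed=0)
        assert res.log_beta[0] == pytest.approx(math.log10(6025), abs=1e-3)
        assert res.rss <= 1e-12 * np.sum(data.absorbance ** 2)
        assert not res.degenerate
        assert res.kc == pytest.approx(6025, rel=1e-3)

    def test_noiseless_epsilon_recovery(self):
        from cyclofit.synthetic import default_epsilon_specs, _epsilon_matrix

        data = gen_titration(noise_sd=0.0)
        model = BindingModel([(1, 1, 3.0)])
        res = fit_titration(data, model, starts=3, seed=0)
        truth = _epsilon_matrix(res.binding_model, default_epsilon_specs(), data.wavelengths)
        for i, key in enumerate(res.binding_model.absorbing):
            np.testing.assert_allclose(res.epsilon[key], truth[i], atol=truth.max() * 1e-5)

    def test_zero_absorbance_flags_degenerate(self):
        data = gen_titration(noise_sd=0.0)
        zero = TitrationData(data.g_tot, data.h_tot, data.wavelengths,
                             np.zeros_like(data.absorbance))
        res = fit_titration(zero, BindingModel([(1, 1, 3.0)]), starts=2, seed=0)
        assert res.degenerate

    def test_too_few_points_rejected(self):
        data = gen_titration(noise_sd=0.0)
        small = TitrationData(data.g_tot, data.h_tot[:2], data.wavelengths,
                              data.absorbance[:2])
        with pytest.raises(ValidationError):
            TitrationModel(small, BindingModel([(1, 1, 3.0)]))

    def test_noisy_median_recovery_within_five_percent(self):
        kcs = []
        for seed in range(5):
            data = gen_titration(noise_sd=0.002, seed=seed)
            res = fit_titration(data, BindingModel([(1, 1, 3.0)]), starts=5, seed=seed)
            kcs.append(res.kc)
        assert np.median(kcs) == pytest.approx(6025, rel=0.05)


class TestResidualTrend:
    def test_alternating_signs_are_not_systematic(self):
        resid = np.tile([[1.0], [-1.0]], (4, 8))[:7]
        rep = residual_trend_test(resid)
        assert not rep.systematic
        assert np.all(rep.p_values > 0.05)

    def test_two_run_pattern_is_systematic(self):
        col = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0])
        rep = residual_trend_test(np.tile(col[:, None], (1, 10)))
        assert rep.systematic
        assert rep.fraction_rejecting == 1.0

    def test_zero_residual_counts_as_positive(self):
        col = np.array([0.0, 0.0, 0.0, 0.0, -1.0, -1.0, -1.0])
        rep = residual_trend_test(np.tile(col[:, None], (1, 4)))
        assert rep.systematic  # zeros grouped with positives: 2 runs

    def test_wrong_stoichiometry_inflates_residuals_and_loses_ranking(self):
        # data generated 1:1 but fitted with a lone 1:2 complex: the misfit
        # shows up as a large rss excess and a worse AICc than the true model
        data = gen_titration(noise_sd=0.002, seed=11)
        wrong = fit_titration(data, BindingModel([(1, 2, 3.0)]), starts=5, seed=11)
        right = fit_titration(data, BindingModel([(1, 1, 3.0)]), starts=5, seed=11)
        assert wrong.rss > 2.0 * right.rss
        assert wrong.aicc > right.aicc


class TestModelSelection:
    def test_single_candidate_selected_trivially(self):
        data = gen_titration(noise_sd=0.002, seed=3)
        rep = select_model(data, ["1:1"], seed=3, starts=3)
        assert rep.best_name == "1:1"

    def test_true_stoichiometry_preferred_over_richer_models(self):
        data = gen_titration(noise_sd=0.002, seed=5)
        rep = select_model(data, ["1:1", "1:1+1:2", "1:1+2:1"], seed=5, starts=5)
        assert rep.best_name == "1:1"
        assert "1:1" in rep.summary()

    def test_two_complex_data_leaves_1to1_with_trend(self):
        truth = BindingModel([(1, 1, 4.3), (1, 2, 7.8)])
        data = gen_titration(
            model=truth,
            epsilon_specs={
                (0, 1): [(1.5e4, 280.0, 24.0)],
                (1, 1): [(1.9e4, 290.0, 26.0)],
                (1, 2): [(2.4e4, 300.0, 28.0)],
            },
            noise_sd=0.002,
            seed=9,
        )
        res = fit_titration(data, BindingModel([(1, 1, 3.0)]), starts=5, seed=9)
        assert res.trend().systematic
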