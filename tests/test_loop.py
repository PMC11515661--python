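import math

import mpmath as mp
import numpy as np
import pytest

from stochexpr import (
    LoopModel,
    ParameterError,
    build_rate_matrices,
    evaluate_generating_function,
    hyp2f2,
    loop_coefficients,
    loop_derived,
    loop_generating_function,
    loop_noise_metrics,
    noise_reduction_map,
    solve_adaptive,
)
from conftest import draw_loop


class TestDerivedQuantities:
    def test_effective_decay_combines_loop_residence(self, loop_std):
        d = loop_derived(loop_std)
        assert d.gamma_eff == pytest.approx(2.0)  # 1 + 3*1/(1+2)
        assert d.tau == pytest.approx((1.0 + 2.0) / 2.0)

    def test_no_inactivation_reduces_to_plain_decay(self, loop_std):
        loop_std.q12 = 0.0
        assert loop_derived(loop_std).gamma_eff == pytest.approx(loop_std.gamma_1m)

    def test_decoupled_states_factorise_the_quadratic(self):
        m = LoopModel(
            lambda_m=1.0, gamma_1m=2.0, gamma_2m=5.0, q12=0.0, q21=0.0,
            lambda_p=1.0, gamma_p=4.0,
        )
        d = loop_derived(m)
        assert sorted([d.r1, d.r2]) == pytest.approx(sorted([2.0 / 4.0, 5.0 / 4.0]))

    def test_roots_real_and_consistent_with_constant_term(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = draw_loop(rng)
            d = loop_derived(m)
            assert d.r1 >= d.r2 > 0
            const = (
                m.gamma_2m * m.gamma_1m + m.gamma_1m * m.q21 + m.gamma_2m * m.q12
            )
            assert d.r1 * d.r2 * m.gamma_p**2 == pytest.approx(const, rel=1e-10)


class TestCoefficients:
    def test_zeroth_order_is_mean_mrna(self, loop_std):
        b1, b2, a = loop_coefficients(loop_std, 0)
        assert b1 == pytest.approx(2.0 / 2.0)
        assert a == 0.0

    def test_first_cumulant_is_protein_mean(self, loop_std):
        _, _, a1 = loop_coefficients(loop_std, 1)
        d = loop_derived(loop_std)
        assert a1 == pytest.approx(
            loop_std.lambda_p * loop_std.lambda_m / (loop_std.gamma_p * d.gamma_eff)
        )

    def test_closed_form_matches_term_recursion(self):
        # recursion: b_n = lambda_p (g2 + q21 + n gp) / (gp^2 (n+r1)(n+r2)) b_{n-1}
        rng = np.random.default_rng(11)
        for _ in range(25):
            m = draw_loop(rng)
            d = loop_derived(m)
            b = m.lambda_m / d.gamma_eff
            for n in range(1, 4):
                b *= (
                    m.lambda_p
                    * (m.gamma_2m + m.q21 + n * m.gamma_p)
                    / (m.gamma_p**2 * (n + d.r1) * (n + d.r2))
                )
            b3, _, _ = loop_coefficients(m, 3)
            assert b3 == pytest.approx(b, rel=1e-12)


class TestNoiseMetrics:
    def test_fano_for_reference_parameters(self, loop_std):
        met = loop_noise_metrics(loop_std)
        # 1 + 4.8 / (2 + 1 + 3*(2+1)/(2+1+2)) = 2
        assert met.fano == pytest.approx(2.0)

    def test_removing_the_loop_removes_the_reduction(self, loop_std):
        loop_std.q12 = 0.0
        met = loop_noise_metrics(loop_std)
        assert met.fano == pytest.approx(met.fano_baseline)
        assert met.reduction_ratio == pytest.approx(1.0)

    def test_cv2_for_fixed_means_scenario(self):
        # mRNA mean 10 and protein mean 500 pin lambda_m = 20, lambda_p = 100
        m = LoopModel(
            lambda_m=20.0, gamma_1m=1.0, gamma_2m=1.0, q12=3.0, q21=2.0,
            lambda_p=100.0, gamma_p=2.0,
        )
        met = loop_noise_metrics(m)
        assert met.mrna_mean == pytest.approx(10.0)
        assert met.protein_mean == pytest.approx(500.0)
        assert met.cv2 == pytest.approx(0.0436667, rel=1e-5)
        assert met.cv2_baseline == pytest.approx(0.052, rel=1e-10)
        assert met.reduction_ratio == pytest.approx(0.8397, rel=1e-4)

    def test_loop_always_reduces_noise(self):
        # CV^2 < CV0^2 strictly for positive rates
        rng = np.random.default_rng(13)
        for _ in range(1000):
            met = loop_noise_metrics(draw_loop(rng))
            assert met.cv2 < met.cv2_baseline
            assert 0.0 < met.reduction_ratio < 1.0
            assert met.fano >= 1.0

    def test_closed_fano_equals_cumulant_route(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            m = draw_loop(rng)
            _, _, a1 = loop_coefficients(m, 1)
            _, _, a2 = loop_coefficients(m, 2)
            assert loop_noise_metrics(m).fano == pytest.approx(
                1.0 + 2.0 * a2 / a1, rel=1e-10
            )


class TestHyp2F2:
    def test_empty_argument_is_one(self):
        assert hyp2f2(1.0, 2.0, 3.0, 4.0, 0.0) == 1.0

    def test_cancelling_parameters_give_exponential(self):
        for z in (-3.0, 0.5, 2.0):
            assert hyp2f2(1.0, 1.0, 1.0, 1.0, z) == pytest.approx(
                math.exp(z), rel=1e-12
            )

    def test_against_brute_force_extended_precision_sum(self):
        tau, r1, r2, w = 1.5, 2.0, 1.0, -0.5
        with mp.workdps(60):
            s = mp.mpf(0)
            for n in range(200):
                s += (
                    mp.rf(1, n) * mp.rf(1 + tau, n)
                    / (mp.rf(1 + r1, n) * mp.rf(1 + r2, n))
                    * mp.mpf(w) ** n / mp.factorial(n)
                )
            ref = float(s)
        assert hyp2f2(1.0, 1.0 + tau, 1.0 + r1, 1.0 + r2, w) == pytest.approx(
            ref, rel=1e-12
        )

    def test_large_negative_argument_survives_cancellation(self):
        args = (1.0, 2.5, 3.0, 2.0, -45.0)
        ref = float(mp.hyp2f2(*args))
        assert hyp2f2(*args) == pytest.approx(ref, rel=1e-8)

    def test_nonpositive_integer_lower_parameter_rejected(self):
        with pytest.raises(ParameterError):
            hyp2f2(1.0, 1.0, -2.0, 1.0, 0.5)


class TestGeneratingFunction:
    def test_normalisation(self, loop_std):
        assert loop_generating_function(loop_std, 1.0, 1.0, 1.0) == pytest.approx(1.0)

    def test_active_mrna_mean_from_derivative(self, loop_std):
        # dG/dx1 at (1,1,1) = lambda_m / gamma_eff; the 2F2 factor is 1 at 0
        h = 1e-6
        deriv = (
            loop_generating_function(loop_std, 1.0 + h, 1.0, 1.0)
            - loop_generating_function(loop_std, 1.0 - h, 1.0, 1.0)
        ) / (2 * h)
        assert deriv == pytest.approx(
            loop_std.lambda_m / loop_derived(loop_std).gamma_eff, rel=1e-8
        )

    def test_matches_generic_series_solution(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            m = draw_loop(rng)
            table = solve_adaptive(
                build_rate_matrices(m.to_generalized()), y_points=[0.95]
            )
            closed = loop_generating_function(m, 1.1, 0.9, 0.95)
            series = evaluate_generating_function(table, [1.1, 0.9], 0.95)
            assert closed == pytest.approx(series, rel=1e-8)


class TestNoiseReductionMap:
    def test_unstable_scenario_optimum_is_moderate(self):
        nm = noise_reduction_map(scenario="unstable")
        assert 12.0 <= nm.max_reduction_percent <= 18.0
        # optimum at activation and protein decay faster than mRNA decay
        assert nm.argmin_q21 > 1.0 and nm.argmin_gamma_p > 1.0

    def test_stable_scenario_optimum_at_slow_activation(self):
        nm = noise_reduction_map(scenario="stable")
        assert 56.0 <= nm.max_reduction_percent <= 64.0
        assert nm.argmin_q21 == pytest.approx(nm.q21.min(), rel=1e-6)

    def test_no_inactivation_gives_unit_ratio(self):
        nm = noise_reduction_map(scenario="unstable", q12=0.0, n_grid=5, refine=False)
        assert np.allclose(nm.ratio, 1.0)

    def test_stable_ratio_monotone_in_activation_rate(self):
        nm = noise_reduction_map(scenario="stable", n_grid=40, refine=False)
        # for gamma_2m = 0 the ratio is nonincreasing as q21 decreases
        for j in range(nm.gamma_p.size):
            col = nm.ratio[:, j]
            assert np.all(np.diff(col) >= -1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ParameterError):
            noise_reduction_map(q21_grid=np.array([]), gamma_p_grid=np.array([1.0]))
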