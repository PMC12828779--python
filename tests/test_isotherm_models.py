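"""Isotherm forms, slopes, the modification algebra, and the Taylor tools."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings, strategies as st

from isodx.isotherm_models import (
    C_M,
    PHI,
    IsothermDomainError,
    IsothermSpec,
    ModificationRule,
    apply_modification,
    default_rule_library,
    eval_modulated_langmuir,
    eval_polynomial,
    eval_quadratic,
    eval_simple_isotherm,
    isotherm_slope,
    langmuir,
    langmuir_freundlich,
    lss_langmuir,
    polynomial,
    quadratic,
    radius_of_convergence,
    rule_polynomial_growth,
    rule_qsat_lss_phi,
    rule_qsat_lss_phi2,
    rule_sb_linear_phi,
    rule_tanh_damping,
    taylor_coefficients,
    taylor_series,
    validate_parameters,
)

CASE_A_TRUTH = {"K": 118.58, "q_sat": 34.45, "S_a": 9.36, "S_b": 7.50}
CASE_C_TRUTH = {"q_sat": 123.2, "b": 0.04, "b_prime": 0.02}


class TestForms:
    def test_all_forms_vanish_at_zero_concentration(self):
        specs = [
            (langmuir(), {"q_sat": 30.0, "b": 1.2}),
            (langmuir_freundlich(), {"q_sat": 30.0, "b": 1.2}),
            (lss_langmuir("fixed_qsat"), {"K": 100.0, "q_sat": 30.0, "S_a": 9.0}),
            (lss_langmuir("modulated_qsat"), CASE_A_TRUTH),
            (quadratic(), CASE_C_TRUTH),
            (polynomial(4), {"a_1": 5.0, "a_2": 4.0, "a_3": -0.4, "a_4": -0.02}),
            (polynomial(3, damping="tanh_on_cubic"),
             {"a_1": 5.0, "a_2": 4.0, "a_3": -0.1, "a_4": -0.3}),
        ]
        for spec, params in specs:
            assert spec.evaluate(params, 0.0, 0.3) == pytest.approx(0.0, abs=1e-14)

    def test_modulated_langmuir_value_matches_arithmetic(self):
        # direct arithmetic oracle on the capacity-modulated form
        q = eval_modulated_langmuir(CASE_A_TRUTH, 5.0, 0.4,
                                    variant="modulated_qsat")
        assert q == pytest.approx(7.5545, abs=2e-3)

    def test_fixed_qsat_at_phi_zero_reduces_to_langmuir(self):
        params = {"K": 100.0, "q_sat": 30.0, "S_a": 9.0}
        c = np.linspace(0.0, 10.0, 40)
        lhs = eval_modulated_langmuir(params, c, 0.0, variant="fixed_qsat")
        rhs = eval_simple_isotherm(
            {"q_sat": 30.0, "b": 100.0 / 30.0}, c, variant="langmuir")
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_quadratic_value_and_plateau(self):
        assert eval_quadratic(CASE_C_TRUTH, 6.0) == pytest.approx(105.6, rel=1e-6)
        # leading-order ratio gives a 2*q_sat plateau
        assert eval_quadratic(CASE_C_TRUTH, 1e7) == pytest.approx(
            2 * 123.2, rel=1e-4)

    def test_langmuir_half_saturation(self):
        assert eval_simple_isotherm({"q_sat": 30.0, "b": 2.0}, 0.5,
                                    "langmuir") == pytest.approx(15.0)

    def test_langmuir_freundlich_zero_initial_slope(self):
        spec = langmuir_freundlich()
        s0 = spec.slope({"q_sat": 30.0, "b": 2.0}, 0.0)
        assert s0 == pytest.approx(0.0, abs=1e-12)

    def test_polynomial_value_matches_sum(self):
        # printed quartic coefficients summed at C_m = 1
        q = eval_polynomial([4.93, 4.77, -0.38, -0.02], 1.0)
        assert q == pytest.approx(9.30, abs=1e-12)

    def test_tanh_damped_cubic_term_vanishes_at_zero(self):
        q = eval_polynomial([5.0, 4.0, -0.1, -0.3], 0.0,
                            damping="tanh_on_cubic")
        assert q == 0.0

    def test_lss_domain_error_on_negative_concentration(self):
        with pytest.raises(IsothermDomainError):
            eval_modulated_langmuir(CASE_A_TRUTH, -1.0, 0.1,
                                    variant="modulated_qsat")

    def test_quadratic_domain_error_on_nonpositive_denominator(self):
        with pytest.raises(IsothermDomainError):
            eval_quadratic({"q_sat": 10.0, "b": -3.0, "b_prime": 0.0}, 1.0)

    def test_parameter_validation(self):
        validate_parameters(quadratic(), CASE_C_TRUTH)
        with pytest.raises(ValueError):
            validate_parameters(quadratic(), dict(CASE_C_TRUTH, q_sat=-1.0))
        with pytest.raises(ValueError):
            validate_parameters(langmuir(), {"q_sat": 10.0, "b": np.nan})

    def test_spec_rejects_undeclared_symbols(self):
        with pytest.raises(ValueError):
            IsothermSpec("bad", sp.Symbol("zzz", real=True) * C_M, ("a_1",))


class TestSlope:
    @pytest.mark.parametrize("spec,params,phi", [
        (langmuir(), {"q_sat": 30.0, "b": 1.5}, 0.0),
        (lss_langmuir("modulated_qsat"), CASE_A_TRUTH, 0.3),
        (lss_langmuir("quadratic_qsat"),
         {**CASE_A_TRUTH, "S_b": 3.10, "S_c": 4.20}, 0.2),
        (quadratic(), CASE_C_TRUTH, 0.0),
        (polynomial(3, damping="tanh_on_cubic"),
         {"a_1": 5.0, "a_2": 4.0, "a_3": -0.1, "a_4": -0.3}, 0.0),
    ])
    def test_analytic_slope_matches_central_difference(self, spec, params, phi):
        c = np.linspace(0.05, 6.0, 17)
        h = 1e-6
        fd = (spec.evaluate(params, c + h, phi)
              - spec.evaluate(params, c - h, phi)) / (2 * h)
        np.testing.assert_allclose(isotherm_slope(spec, params, c, phi), fd,
                                   rtol=1e-6, atol=1e-9)

    def test_langmuir_henry_limit(self):
        assert isotherm_slope(langmuir(), {"q_sat": 30.0, "b": 1.5}, 0.0) \
            == pytest.approx(45.0)

    def test_quadratic_initial_slope_is_first_taylor_coefficient(self):
        s0 = isotherm_slope(quadratic(), CASE_C_TRUTH, 0.0)
        assert s0 == pytest.approx(4.928, rel=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(c=st.floats(0.0, 8.0), b=st.floats(0.01, 2.0),
           q=st.floats(1.0, 200.0))
    def test_slope_predicts_local_increment(self, c, b, q):
        spec = langmuir()
        params = {"q_sat": q, "b": b}
        dc = 1e-6
        inc = spec.evaluate(params, c + dc) - spec.evaluate(params, c)
        assert spec.slope(params, c) * dc == pytest.approx(inc, rel=1e-4,
                                                           abs=1e-12)


class TestModificationAlgebra:
    def test_capacity_lss_rule_reproduces_modulated_form(self):
        # q_sat -> q_sat*exp(-S_c*phi) on the fixed-capacity form, then
        # reparametrized with S_b = S_a - S_c, equals the modulated form.
        base = lss_langmuir("fixed_qsat")
        mod = apply_modification(base, rule_qsat_lss_phi())
        target = lss_langmuir("modulated_qsat")
        rng = np.random.default_rng(0)
        for _ in range(100):
            c, phi = rng.uniform(0, 8), rng.uniform(0, 1)
            p = {"K": 118.58, "q_sat": 34.45, "S_a": 9.36, "S_c": 1.86}
            pt = {"K": 118.58, "q_sat": 34.45, "S_a": 9.36,
                  "S_b": 9.36 - 1.86}
            assert mod.evaluate(p, c, phi) == pytest.approx(
                target.evaluate(pt, c, phi), rel=1e-12)

    def test_sb_linear_and_qsat_quadratic_rules_differ_only_in_sign(self):
        base = lss_langmuir("modulated_qsat")
        m_sb = apply_modification(base, rule_sb_linear_phi())
        m_qs = apply_modification(base, rule_qsat_lss_phi2())
        p = {"K": 118.58, "q_sat": 34.45, "S_a": 9.36, "S_b": 3.10,
             "S_c": 4.20}
        p_flip = dict(p, S_c=-4.20)
        c = np.linspace(0, 8, 9)
        for phi in (0.0, 0.25, 0.6):
            np.testing.assert_allclose(
                m_sb.evaluate(p_flip, c, phi), m_qs.evaluate(p, c, phi),
                rtol=1e-12)

    def test_polynomial_growth_rule_raises_degree(self):
        grown = apply_modification(polynomial(2), rule_polynomial_growth(2))
        assert sp.simplify(grown.expression
                           - polynomial(3).expression) == 0
        assert grown.parameter_names == ("a_1", "a_2", "a_3")

    def test_tanh_rule_yields_damped_cubic(self):
        damped = apply_modification(polynomial(3), rule_tanh_damping())
        assert sp.simplify(
            damped.expression
            - polynomial(3, damping="tanh_on_cubic").expression) == 0

    def test_neutral_value_recovers_parent(self):
        base = lss_langmuir("modulated_qsat")
        rule = rule_qsat_lss_phi2()
        mod = apply_modification(base, rule)
        p = dict(CASE_A_TRUTH)
        assert mod.evaluate({**p, rule.new_parameter: rule.neutral}, 3.0, 0.4) \
            == pytest.approx(base.evaluate(p, 3.0, 0.4), rel=1e-14)

    def test_history_and_names_extended(self):
        mod = apply_modification(lss_langmuir("modulated_qsat"),
                                 rule_sb_linear_phi())
        assert mod.modification_history == ("sb_linear_phi",)
        assert mod.parameter_names[-1] == "S_c"

    def test_unknown_target_raises(self):
        with pytest.raises(KeyError):
            apply_modification(langmuir(), rule_sb_linear_phi())

    def test_rule_must_introduce_exactly_one_new_parameter(self):
        bad = ModificationRule("bad", "q_sat", "S_c", "q_sat*2")
        with pytest.raises(ValueError):
            apply_modification(lss_langmuir("fixed_qsat"), bad)

    def test_default_library_covers_capacity_and_polynomials(self):
        lib_lss = default_rule_library(lss_langmuir("modulated_qsat"))
        assert [r.name for r in lib_lss["q_sat"]][0] == "qsat_lss_phi"
        assert [r.name for r in lib_lss["S_b"]] == ["sb_linear_phi"]
        lib_poly = default_rule_library(polynomial(3))
        assert [r.name for r in lib_poly["a_3"]] == [
            "poly_growth_a3", "tanh_damping_a3"]

    def test_spec_json_round_trip(self):
        mod = apply_modification(lss_langmuir("modulated_qsat"),
                                 rule_qsat_lss_phi2())
        back = IsothermSpec.from_dict(mod.to_dict())
        assert back.parameter_names == mod.parameter_names
        assert sp.simplify(back.expression - mod.expression) == 0


class TestTaylor:
    def _symbolic_coefficients(self, order):
        b, bp, q = sp.symbols("b bp q")
        expr = q * (b * C_M + 2 * bp * C_M**2) / (1 + b * C_M + bp * C_M**2)
        ser = sp.series(expr, C_M, 0, order + 1).removeO()
        return [sp.expand(ser.coeff(C_M, k)) for k in range(1, order + 1)], \
            (b, bp, q)

    def test_first_three_coefficients_match_closed_forms(self):
        b, bp, q = sp.symbols("b bp q")
        closed = [q * b, q * (-b**2 + 2 * bp), q * (b**3 - 3 * b * bp)]
        sym, syms = self._symbolic_coefficients(3)
        for got, want in zip(sym, closed):
            assert sp.simplify(got - want) == 0

    def test_coefficients_match_symbolic_series_for_random_draws(self):
        sym, (b, bp, q) = self._symbolic_coefficients(4)
        rng = np.random.default_rng(7)
        for _ in range(20):
            bv, bpv, qv = rng.uniform(0.01, 1), rng.uniform(0.001, 0.5), \
                rng.uniform(1, 200)
            want = [float(c.subs({b: bv, bp: bpv, q: qv})) for c in sym]
            got = taylor_coefficients(bv, bpv, qv, 4)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_case_c_leading_coefficient(self):
        c = taylor_coefficients(0.04, 0.02, 123.2, 4)
        assert c[0] == pytest.approx(4.9280, abs=1e-4)
        assert c[1] == pytest.approx(4.73088, rel=1e-10)
        assert c[2] == pytest.approx(-0.2877952, rel=1e-6)
        # exact fourth coefficient, including the -b^4 q_sat term
        assert c[3] == pytest.approx(-0.083105792, rel=1e-6)

    def test_zero_parameters_give_zero_series(self):
        assert np.all(taylor_coefficients(0.0, 0.0, 100.0, 6) == 0.0)

    def test_truncated_series_accurate_inside_radius(self):
        c = np.linspace(0.05, 2.0, 20)
        exact = eval_quadratic(CASE_C_TRUTH, c)
        np.testing.assert_allclose(taylor_series(0.04, 0.02, 123.2, 6, c),
                                   exact, rtol=2e-3)
        np.testing.assert_allclose(taylor_series(0.04, 0.02, 123.2, 8, c),
                                   exact, rtol=1e-3)

    def test_series_diverges_beyond_radius(self):
        r = radius_of_convergence(0.04, 0.02)
        err = {}
        for f in (0.5, 1.5):
            c = f * r
            err[f] = abs(taylor_series(0.04, 0.02, 123.2, 15, c)
                         - eval_quadratic(CASE_C_TRUTH, c))
        assert err[1.5] >= 10 * err[0.5]


class TestRadius:
    def test_complex_pole_pair(self):
        assert radius_of_convergence(0.04, 0.02) == pytest.approx(
            np.sqrt(50.0), rel=1e-12)

    def test_single_real_pole(self):
        assert radius_of_convergence(0.5, 0.0) == pytest.approx(2.0)

    def test_pure_quadratic_pole(self):
        assert radius_of_convergence(0.0, 0.01) == pytest.approx(10.0)

    def test_zero_isotherm_sentinel(self):
        assert radius_of_convergence(0.0, 0.0) == np.inf
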