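"""Pure-compound EoS: alpha-functions, roots, fugacities, saturation."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from cosmopr.constants import R, OMEGA_A, OMEGA_B
from cosmopr.eos import (
    AlphaKind,
    Phase,
    PureComponent,
    alpha_soave,
    alpha_twu,
    attractive_a,
    derive_omega,
    derive_soave_m,
    derive_tc_pc,
    load_component_table,
    pure_fugacity_coeff,
    saturation_pressure,
    save_component_table,
    soave_m_from_omega,
    solve_volumes,
    translation_from_correlation,
)


class TestAlphaFunctions:
    def test_soave_closed_form(self):
        # hand evaluation: (1 + 0.7 (1 - sqrt(0.5)))^2
        expected = (1.0 + 0.7 * (1.0 - math.sqrt(0.5))) ** 2
        assert alpha_soave(0.5, 0.7) == pytest.approx(expected, rel=1e-12)
        assert alpha_soave(0.5, 0.7) == pytest.approx(1.452086, abs=5e-7)

    def test_soave_limits(self):
        assert alpha_soave(1.0, 0.5) == pytest.approx(1.0, abs=1e-14)
        assert alpha_soave(1e-12, 0.5) == pytest.approx(2.25, rel=1e-5)

    def test_twu_closed_form(self):
        # L = 0 collapses the exponential: 0.8^(-0.2)
        assert alpha_twu(0.8, 0.0, 0.9, 2.0) == pytest.approx(
            0.8 ** (-0.2), rel=1e-12
        )
        # full form, hand evaluation
        expected = 0.8 ** (-0.2) * math.exp(0.2 * (1.0 - 0.8 ** 1.8))
        assert alpha_twu(0.8, 0.2, 0.9, 2.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.11716, abs=5e-5)

    @given(
        m=st.floats(0.0, 2.0),
        L=st.floats(0.01, 1.5),
        M=st.floats(0.5, 1.5),
        N=st.floats(0.5, 3.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_alpha_is_one_at_tc(self, m, L, M, N):
        assert abs(alpha_soave(1.0, m) - 1.0) < 1e-14
        assert abs(alpha_twu(1.0, L, M, N) - 1.0) < 1e-14

    def test_rejects_nonpositive_tr(self):
        with pytest.raises(ValueError):
            alpha_soave(0.0, 0.5)
        with pytest.raises(ValueError):
            alpha_twu(-1.0, 0.2, 0.9, 2.0)


class TestAttractiveParameter:
    def test_at_tc_equals_ac(self, hexane):
        assert attractive_a(hexane, hexane.tc) == pytest.approx(
            hexane.a_c, rel=1e-14
        )

    def test_m_zero_is_constant(self):
        comp = PureComponent(
            name="flat", tc=500.0, pc=3e6, omega=0.0, soave_m=0.0
        )
        for t in (100.0, 300.0, 700.0):
            assert attractive_a(comp, t) == pytest.approx(comp.a_c, rel=1e-14)

    def test_scaled_soave_value(self):
        comp = PureComponent(
            name="toy", tc=600.0, pc=3e6, omega=0.0, soave_m=0.7,
            a_c=2.0, b=1e-4, c=0.0, source="gc",
        )
        expected = 2.0 * (1.0 + 0.7 * (1.0 - math.sqrt(0.5))) ** 2
        assert attractive_a(comp, 300.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.904171, abs=1e-5)


def _cardano_roots(t, p, a, b):
    """Independent cubic oracle: expand P(v) = p to a polynomial in v
    and solve with the closed-form trigonometric/Cardano method."""
    # p (v-b)(v^2+2bv-b^2) = RT (v^2+2bv-b^2) - a (v-b)
    # c3 v^3 + c2 v^2 + c1 v + c0 = 0
    c3 = p
    c2 = p * b - R * t
    c1 = -3.0 * p * b * b - 2.0 * R * t * b + a
    c0 = p * b**3 + R * t * b * b - a * b
    # depressed cubic x^3 + px + q with v = x - c2/(3 c3)
    A, B, C = c2 / c3, c1 / c3, c0 / c3
    pp = B - A * A / 3.0
    qq = 2.0 * A**3 / 27.0 - A * B / 3.0 + C
    disc = (qq / 2.0) ** 2 + (pp / 3.0) ** 3
    if disc > 0:
        u = np.cbrt(-qq / 2.0 + math.sqrt(disc))
        v = np.cbrt(-qq / 2.0 - math.sqrt(disc))
        xs = [u + v]
    else:
        r = math.sqrt(-(pp**3) / 27.0)
        phi = math.acos(max(-1.0, min(1.0, -qq / (2.0 * r))))
        m = 2.0 * math.sqrt(-pp / 3.0)
        xs = [m * math.cos((phi + 2.0 * math.pi * k) / 3.0) for k in range(3)]
    return sorted(x - A / 3.0 for x in xs)


class TestVolumeSolver:
    def test_ideal_gas_reduction(self):
        sol = solve_volumes(300.0, 1e5, 0.0, 0.0, 0.0)
        assert sol.volumes == pytest.approx([R * 300.0 / 1e5], rel=1e-14)

    def test_translation_is_constant_shift(self):
        base = solve_volumes(300.0, 1e5, 0.5, 3e-5, 0.0)
        shifted = solve_volumes(300.0, 1e5, 0.5, 3e-5, 5e-6)
        np.testing.assert_allclose(
            shifted.volumes, base.volumes - 5e-6, rtol=1e-12
        )
        assert shifted.phase_labels == base.phase_labels

    def test_roots_match_cardano_oracle(self):
        t, p, a, b = 300.0, 1e5, 0.5, 3e-5
        oracle = [v for v in _cardano_roots(t, p, a, b) if v > b]
        got = solve_volumes(t, p, a, b, 0.0).volumes
        np.testing.assert_allclose(got, oracle, rtol=1e-9)

    def test_residual_satisfied(self, hexane):
        t, p = 350.0, 5e4
        a = attractive_a(hexane, t)
        sol = solve_volumes(t, p, a, hexane.b, hexane.c)
        for v in sol.volumes:
            w = v + hexane.c
            p_back = R * t / (w - hexane.b) - a / (
                w * (w + hexane.b) + hexane.b * (w - hexane.b)
            )
            assert p_back == pytest.approx(p, rel=1e-8)

    def test_liquid_below_vapor(self, hexane):
        t = 350.0
        p = saturation_pressure(hexane, t)
        sol = solve_volumes(t, p, attractive_a(hexane, t), hexane.b, hexane.c)
        assert sol.volume(Phase.LIQUID) < sol.volume(Phase.VAPOR)

    def test_error_when_no_physical_root(self):
        with pytest.raises((RuntimeError, ValueError)):
            solve_volumes(-1.0, 1e5, 0.5, 3e-5, 0.0)


class TestFugacity:
    def test_ideal_gas_ln_phi_zero(self):
        comp = PureComponent.ideal_gas()
        assert pure_fugacity_coeff(comp, 300.0, 1e5, Phase.VAPOR) == 0.0

    def test_equilibrium_identity(self, hexane):
        t = 360.0
        psat = saturation_pressure(hexane, t)
        lv = pure_fugacity_coeff(hexane, t, psat, Phase.LIQUID)
        gv = pure_fugacity_coeff(hexane, t, psat, Phase.VAPOR)
        assert abs(lv - gv) < 1e-8

    def test_translation_preserves_phase_ratio(self, hexane):
        """Translation shifts both phases' ln phi by the same -cP/RT."""
        t = 360.0
        psat = saturation_pressure(hexane, t)
        tr = PureComponent.from_critical(
            "hexane_t", hexane.tc, hexane.pc, hexane.omega, c=5e-6
        )
        for_both = [
            pure_fugacity_coeff(hexane, t, psat, ph)
            - pure_fugacity_coeff(tr, t, psat, ph)
            for ph in (Phase.LIQUID, Phase.VAPOR)
        ]
        assert for_both[0] == pytest.approx(for_both[1], abs=1e-12)
        assert for_both[0] == pytest.approx(
            (5e-6 - hexane.c) * psat / (R * t), rel=1e-10
        )

    def test_matches_quadrature_oracle(self, hexane):
        """ln phi = int_0^P (Z-1) dP/P along the vapour isotherm."""
        t, p = 300.0, 1e4
        a = attractive_a(hexane, t)

        def zm1_over_p(pp):
            sol = solve_volumes(t, pp, a, hexane.b, 0.0)
            w = sol.volumes[-1]
            return (pp * w / (R * t) - 1.0) / pp

        val, _ = quad(zm1_over_p, 1e-8, p, limit=200)
        untr = PureComponent.from_critical(
            "hexane0", hexane.tc, hexane.pc, hexane.omega, c=0.0
        )
        assert pure_fugacity_coeff(untr, t, p, Phase.VAPOR) == pytest.approx(
            val, abs=1e-6
        )


class TestSaturationPressure:
    def test_defining_residual(self, hexane):
        for t in (300.0, 400.0, 480.0):
            psat = saturation_pressure(hexane, t)
            lv = pure_fugacity_coeff(hexane, t, psat, Phase.LIQUID)
            gv = pure_fugacity_coeff(hexane, t, psat, Phase.VAPOR)
            assert abs(lv - gv) < 1e-9

    def test_critical_limit(self, hexane):
        psat = saturation_pressure(hexane, 0.999 * hexane.tc)
        assert psat == pytest.approx(hexane.pc, rel=0.02)

    def test_above_tc_rejected(self, hexane):
        with pytest.raises(ValueError):
            saturation_pressure(hexane, hexane.tc + 1.0)

    def test_agrees_with_bisection_oracle(self, toy_pairs):
        """Plain bisection on the fugacity-difference sign change."""
        for comp, _ in toy_pairs:
            t = 0.7 * comp.tc
            psat = saturation_pressure(comp, t)
            a = attractive_a(comp, t)

            def resid(p):
                sol = solve_volumes(t, p, a, comp.b, 0.0)
                if not (sol.has_liquid and sol.has_vapor):
                    return math.nan
                from cosmopr.eos import _ln_phi_untranslated

                return _ln_phi_untranslated(
                    sol.volume(Phase.LIQUID), t, p, a, comp.b
                ) - _ln_phi_untranslated(
                    sol.volume(Phase.VAPOR), t, p, a, comp.b
                )

            lo, hi = 0.5 * psat, min(1.5 * psat, 0.999 * comp.pc)
            f_lo = resid(lo)
            assert f_lo == f_lo, "oracle bracket must contain both phases"
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                f_mid = resid(mid)
                if f_mid != f_mid:
                    break
                if f_lo * f_mid <= 0:
                    hi = mid
                else:
                    lo, f_lo = mid, f_mid
            assert psat == pytest.approx(0.5 * (lo + hi), rel=1e-8)


class TestDerivedParameters:
    def test_soave_m_closed_form(self):
        assert derive_soave_m(2.0, 2.0) == 0.0
        assert derive_soave_m(1.0, 4.0) == pytest.approx(1.0, rel=1e-14)
        assert derive_soave_m(2.0, 4.5) == pytest.approx(0.5, rel=1e-14)

    def test_soave_m_rejects_a0_below_ac(self):
        with pytest.raises(ValueError):
            derive_soave_m(2.0, 1.9)

    def test_tc_pc_round_trip(self):
        tc0, pc0 = 600.0, 3.0e6
        a_c = OMEGA_A * R**2 * tc0**2 / pc0
        b = OMEGA_B * R * tc0 / pc0
        tc, pc = derive_tc_pc(a_c, b)
        assert tc == pytest.approx(tc0, rel=1e-12)
        assert pc == pytest.approx(pc0, rel=1e-12)

    def test_tc_proportional_to_ac(self):
        tc1, _ = derive_tc_pc(2.0, 1e-4)
        tc2, _ = derive_tc_pc(4.0, 1e-4)
        assert tc2 == pytest.approx(2.0 * tc1, rel=1e-14)

    def test_tc_pc_spot_value(self):
        tc, pc = derive_tc_pc(2.0, 1.0e-4)
        assert tc == pytest.approx(
            (OMEGA_B / OMEGA_A) * 2.0 / (R * 1.0e-4), rel=1e-12
        )
        assert tc == pytest.approx(409.3, abs=0.5)
        assert pc == pytest.approx(2.648e6, rel=2e-3)

    def test_omega_inversion(self):
        assert derive_omega(0.37464) == pytest.approx(0.0, abs=1e-12)
        m_at_1 = soave_m_from_omega(1.0)
        assert m_at_1 == pytest.approx(1.64698, abs=1e-5)
        assert derive_omega(m_at_1) == pytest.approx(1.0, rel=1e-12)

    @given(omega=st.floats(-0.3, 1.2))
    @settings(max_examples=60, derandomize=True)
    def test_omega_round_trip(self, omega):
        assert derive_omega(soave_m_from_omega(omega)) == pytest.approx(
            omega, abs=1e-12
        )

    def test_component_round_trip_from_gc(self):
        comp = PureComponent.from_gc("toy", a_c=2.0, b=1.0e-4, a_0=4.5)
        assert comp.alpha(comp.tc) == pytest.approx(1.0, abs=1e-14)
        assert comp.a_c == pytest.approx(
            OMEGA_A * R**2 * comp.tc**2 / comp.pc, rel=1e-12
        )
        assert comp.source == "gc" and comp.c == 0.0


class TestTranslationCorrelation:
    def test_scales_with_rtc_over_pc(self):
        c1 = translation_from_correlation(500.0, 3e6, 0.3)
        c2 = translation_from_correlation(1000.0, 3e6, 0.3)
        assert c2 == pytest.approx(2.0 * c1, rel=1e-12)
        assert translation_from_correlation(500.0, 3e6, 0.3) == c1

    def test_spot_value_hand_evaluation(self):
        z_ra = 0.29056 - 0.08775 * 0.3
        expected = 0.50033 * (R * 500.0 / 3e6) * (0.25969 - z_ra)
        assert translation_from_correlation(500.0, 3e6, 0.3) == pytest.approx(
            expected, rel=1e-12
        )

    def test_magnitude_is_a_few_cm3(self, hexane):
        assert abs(hexane.c) < 2e-5    # |c| below 20 cm3/mol


class TestComponentTable:
    def test_csv_round_trip(self, hexane, water, tmp_path):
        twu = PureComponent.from_critical(
            "twu_comp", 500.0, 3e6, 0.25, alpha_kind=AlphaKind.TWU91,
            generalized_twu=True,
        )
        path = tmp_path / "components.csv"
        save_component_table([hexane, water, twu], path)
        back = load_component_table(path)
        assert [c.name for c in back] == ["hexane", "water", "twu_comp"]
        assert back[0].soave_m == pytest.approx(hexane.soave_m, rel=1e-12)
        assert back[2].twu_M == pytest.approx(twu.twu_M, rel=1e-12)

    def test_inconsistent_ac_b_rejected(self):
        with pytest.raises(ValueError):
            PureComponent(
                name="bad", tc=500.0, pc=3e6, omega=0.2, soave_m=0.7,
                a_c=1.0, b=1e-4, source="experimental",
            )
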