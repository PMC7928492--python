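"""Unit and property tests for the flux laws and the algebraic closures."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from redcell.model_core import (
    RT_F,
    CellState,
    MediumState,
    MembranePotentialError,
    ModelError,
    SystemState,
    TransportParams,
    decompose_water_flux,
    free_calcium,
    gardos_flux,
    ghk_flux,
    js_flux,
    nak_pump_flux,
    osmotic_coefficient,
    pmca_flux,
    solve_membrane_potential,
    system_derivatives,
    compute_fluxes,
    water_flux,
)

POS_CONC = st.floats(min_value=1e-4, max_value=500.0)


class TestGhkFlux:
    @pytest.mark.parametrize("z", [-1, 1, 2])
    def test_zero_at_nernst_potential(self, z):
        ci, co = 0.140, 0.005
        em = RT_F / z * math.log(co / ci)
        assert ghk_flux(1.0, z, em, ci, co) == pytest.approx(0.0, abs=1e-15)

    @given(ci=POS_CONC, co=POS_CONC, z=st.sampled_from([-2, -1, 1, 2]))
    @settings(max_examples=50, deadline=None)
    def test_nernst_zero_property(self, ci, co, z):
        em = RT_F / z * math.log(co / ci)
        scale = max(ci, co)
        assert abs(ghk_flux(1.0, z, em, ci, co)) < 1e-12 * scale

    def test_zero_potential_is_ficks_law(self):
        for z in (-1, 1, 2):
            assert ghk_flux(2.0, z, 0.0, 0.1, 0.25) == pytest.approx(0.3)

    def test_continuous_at_small_potential(self):
        lim = ghk_flux(1.0, 1, 0.0, 0.140, 0.005)
        near = ghk_flux(1.0, 1, 1e-7, 0.140, 0.005)
        assert near == pytest.approx(lim, rel=1e-6)

    def test_matches_high_precision_evaluation(self):
        """Independent 50-digit evaluation of the constant-field formula."""
        import sympy

        em, ci, co = -10.0, 0.140, 0.005
        u = sympy.Rational(-10) / (sympy.Rational(R := 831446261815324,
                                                  10**14)
                                   * sympy.Rational(31015, 100)
                                   / sympy.Rational(9648533212, 10**5)
                                   * 1000)
        expected = sympy.N(u * (co - ci * sympy.exp(u)) / (sympy.exp(u) - 1),
                           50)
        got = ghk_flux(1.0, 1, em, ci, co)
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_input_validation(self):
        with pytest.raises(ModelError):
            ghk_flux(1.0, 1, 0.0, -1.0, 1.0)
        with pytest.raises(ModelError):
            ghk_flux(1.0, 1, 401.0, 1.0, 1.0)
        with pytest.raises(ModelError):
            ghk_flux(-1.0, 1, 0.0, 1.0, 1.0)

    @given(em=st.floats(min_value=-120, max_value=120))
    @settings(max_examples=40, deadline=None)
    def test_influx_increases_with_outside_concentration(self, em):
        lo = ghk_flux(1.0, 1, em, 0.1, 0.05)
        hi = ghk_flux(1.0, 1, em, 0.1, 0.10)
        assert hi > lo


class TestGardosFlux:
    def test_silent_channel_gives_zero(self):
        p = TransportParams(FKmax=0.0)
        assert gardos_flux(5e-6, p, -9.0, 140.0, 5.0) == 0.0

    def test_zero_calcium_gives_zero(self):
        p = TransportParams()
        assert gardos_flux(0.0, p, -9.0, 140.0, 5.0) == 0.0

    def test_hill_midpoint_half_activation(self):
        p = TransportParams(nHill=1.0)
        full = ghk_flux(p.FKmax, 1, -9.0, 140.0, 5.0)
        half = gardos_flux(p.KCaGardos, p, -9.0, 140.0, 5.0)
        assert half == pytest.approx(0.5 * full, rel=1e-12)


class TestPmcaFlux:
    def test_zero_and_saturation_and_midpoint(self):
        p = TransportParams(FCamax=12.0, KmCa=3e-7)
        assert pmca_flux(0.0, p) == (0.0, 0.0)
        ca_out, h_in = pmca_flux(1e-2, p)  # CaI >> Km
        assert ca_out == pytest.approx(12.0, rel=1e-4)
        assert h_in == pytest.approx(2.0 * ca_out)
        mid, _ = pmca_flux(p.KmCa, p)
        assert mid == pytest.approx(6.0)

    @given(ca=st.floats(min_value=0, max_value=1e-4))
    @settings(max_examples=30, deadline=None)
    def test_monotone_and_bounded(self, ca):
        p = TransportParams()
        lo, _ = pmca_flux(ca, p)
        hi, _ = pmca_flux(ca * 2 + 1e-9, p)
        assert 0.0 <= lo <= hi <= p.FCamax


class TestJsFlux:
    def test_zero_at_donnan_equilibrium(self):
        # ClI*HI == ClO*HO
        assert js_flux(90.0, 127.0, 127e-8, 90e-8, 1000.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("scale", [0.4, 5.0])
    def test_rate_coefficient_scales_flux(self, scale):
        base = js_flux(95.0, 127.0, 6e-8, 4e-8, 1000.0)
        scaled = js_flux(95.0, 127.0, 6e-8, 4e-8, 1000.0 * scale)
        assert scaled == pytest.approx(scale * base, rel=1e-12)

    def test_sign_follows_product_gradient(self):
        assert js_flux(50.0, 127.0, 4e-8, 4e-8, 1000.0) > 0  # outside larger
        assert js_flux(200.0, 127.0, 4e-8, 4e-8, 1000.0) < 0


class TestNaKPump:
    def test_zero_sodium_stalls_pump(self):
        assert nak_pump_flux(0.0, 5.0, TransportParams()) == (0.0, 0.0)

    @given(na=st.floats(min_value=0.1, max_value=50),
           ko=st.floats(min_value=0.1, max_value=20))
    @settings(max_examples=30, deadline=None)
    def test_three_to_two_stoichiometry(self, na, ko):
        na_out, k_in = nak_pump_flux(na, ko, TransportParams())
        assert na_out == pytest.approx(1.5 * k_in, rel=1e-12)

    def test_reference_pump_balances_sodium_leak(self, ref):
        system, params = ref
        fl = compute_fluxes(system, params)
        assert abs(fl.na_leak - fl.pump_na) < 1e-9


class TestOsmoticCoefficient:
    def test_ideal_limit_and_monotonicity(self):
        p = TransportParams()
        assert osmotic_coefficient(0.0, p) == 1.0
        grid = np.linspace(0.0, 15.0, 50)
        vals = [osmotic_coefficient(c, p) for c in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert osmotic_coefficient(15.0, p) > osmotic_coefficient(7.5, p)

    def test_reference_cell_is_isotonic(self, ref):
        system, params = ref
        fl = compute_fluxes(system, params)
        assert fl.COs == pytest.approx(fl.MOs, rel=1e-12)


class TestWaterFlux:
    def test_sign_and_zero(self):
        assert water_flux(290.0, 290.0, 5.8) == 0.0
        assert water_flux(290.1, 290.0, 5.8) > 0
        assert water_flux(289.9, 290.0, 5.8) < 0


class TestMembranePotential:
    def test_pure_potassium_conductance_rests_at_nernst(self, ref):
        system, params = ref
        p = replace(params, PNa=0.0, PA=0.0, PCa=0.0, FKmax=0.0,
                    FNaKmax=0.0, PK=0.05)
        em = solve_membrane_potential(system, p)
        ek = RT_F * math.log(system.medium.KO / system.cell.CK)
        assert em == pytest.approx(ek, abs=1e-9)

    def test_reference_resting_potential_physiological(self, ref):
        system, params = ref
        em = solve_membrane_potential(system, params)
        assert -15.0 < em < -5.0

    def test_residual_current_negligible(self, ref):
        system, params = ref
        fl = compute_fluxes(system, params)
        biggest = max(abs(fl.na_leak), abs(fl.k_leak), abs(fl.a_leak),
                      2 * abs(fl.ca_leak), abs(fl.pump_na))
        assert abs(fl.current) < 1e-10 * biggest

    def test_no_solution_raises(self, ref):
        system, params = ref
        p = replace(params, PNa=0.0, PK=0.0, PA=0.0, PCa=0.0, FKmax=0.0,
                    PzCa=0.0, PzA=0.0)
        with pytest.raises(MembranePotentialError):
            solve_membrane_potential(system, p)


class TestSystemDerivatives:
    def test_reference_state_is_stationary(self, ref):
        system, params = ref
        dy, _ = system_derivatives(system, params)
        assert np.abs(dy[:6]).max() < 1e-9

    def test_totals_conserved_for_every_species(self, ref):
        system, params = ref
        dy, _ = system_derivatives(system, params, piezo_open=True)
        # cell + medium amount derivatives cancel exactly
        for cell_i, med_i in ((0, 6), (1, 7), (2, 8), (3, 9)):
            assert dy[cell_i] + dy[med_i] == 0.0
        assert dy[5] + dy[11] == 0.0  # water

    def test_electroneutral_transfer(self, ref):
        """Net charge crossing the membrane is zero at the solved Em."""
        system, params = ref
        rng = np.random.default_rng(7)
        for _ in range(10):
            s = system.copy()
            s.cell.QNa *= 1 + 0.05 * rng.standard_normal()
            s.cell.QK *= 1 + 0.05 * rng.standard_normal()
            s.cell.QA *= 1 + 0.05 * rng.standard_normal()
            s.cell.QCa *= 1 + 10 ** rng.uniform(-1, 2)
            fl = compute_fluxes(s, params, piezo_open=bool(rng.integers(2)))
            biggest = max(abs(fl.na_leak), abs(fl.k_leak), abs(fl.a_leak),
                          abs(fl.k_gardos), 2 * abs(fl.ca_leak),
                          2 * abs(fl.ca_piezo), abs(fl.a_piezo),
                          abs(fl.pump_na), 1e-12)
            assert abs(fl.current) < 1e-10 * biggest


class TestWaterDecomposition:
    def test_identity_against_direct_water_flux(self, ref):
        """W1 - (W2+W3+W4) reproduces Lp*(COs-MOs) at random states."""
        system, params = ref
        rng = np.random.default_rng(11)
        for _ in range(20):
            s = system.copy()
            s.cell.QNa *= 1 + 0.02 * rng.standard_normal()
            s.cell.QK *= 1 + 0.02 * rng.standard_normal()
            s.cell.QA *= 1 + 0.02 * rng.standard_normal()
            s.cell.Vw *= 1 + 0.01 * rng.standard_normal()
            s.cell.QCa *= 10 ** rng.uniform(0, 2)
            piezo = bool(rng.integers(2))
            dec = decompose_water_flux(s, params, piezo)
            fl = compute_fluxes(s, params, piezo)
            direct = water_flux(fl.COs, fl.MOs, params.Lp)
            lhs = dec.W1 - (dec.W2 + dec.W3 + dec.W4)
            assert lhs == pytest.approx(direct, rel=1e-9, abs=1e-12)
            assert dec.Fw == pytest.approx(direct, rel=1e-12, abs=1e-15)

    def test_components_vanish_at_baseline(self, ref):
        system, params = ref
        dec = decompose_water_flux(system, params, piezo_open=False)
        assert abs(dec.W1) < 1e-4
        assert abs(dec.W2) < 1e-4
        assert abs(dec.W3) < 1e-9
        assert abs(dec.W4) < 1e-9


def test_free_calcium_buffering_ratio():
    p = TransportParams(alpha_ca=0.3)
    assert free_calcium(7e-5, 0.7, p) == pytest.approx(0.3 * 1e-4 * 1e-3)
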