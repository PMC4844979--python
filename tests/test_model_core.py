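"""Model symbols, vaccine input, therapy modifiers and the system RHS."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from micromet.model import (
    ModelParameters,
    Regimen,
    SystemState,
    VaccineSchedule,
    effective_parameters,
    model_rhs,
    vaccine_input,
)


class TestModelParameters:
    def test_nominal_links_k_ink_to_k_iap(self):
        assert ModelParameters().k_ink == pytest.approx(0.02 * 1.0)
        assert ModelParameters(k_iap=5.0).k_ink == pytest.approx(0.1)
        assert ModelParameters(k_iap=5.0, k_ink=0.3).k_ink == 0.3

    def test_nominal_normalizations(self, nominal):
        assert nominal.k_atg == 1.0
        assert nominal.M_T == 1.0

    @pytest.mark.parametrize("bad", [
        dict(k_pmc=-1.0), dict(M_T=0.0), dict(g_1=0.5), dict(t_dtc=0.0),
        dict(k_iap=float("nan")),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParameters(**bad)

    def test_array_round_trip(self, nominal):
        assert ModelParameters.from_array(nominal.to_array()) == nominal


class TestVaccineInput:
    @pytest.mark.parametrize("t, expected", [
        (2.0, 1.0),        # inside the first 5-day pulse
        (100.0, 0.0),      # between pulses
        (182.0, 1.0),      # day 2 of cycle 2
        (1200.0, 0.0),     # beyond the sixth cycle
        (0.0, 0.0),        # pulse interval is open at both ends
        (5.0, 0.0),
        (1080.0, 0.0),
    ])
    def test_step_function(self, t, expected):
        assert vaccine_input(t) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            vaccine_input(-0.1)

    def test_schedule_invariants(self):
        with pytest.raises(ValueError):
            VaccineSchedule(pulse_length=200.0)
        with pytest.raises(ValueError):
            VaccineSchedule(n_cycles=-1)

    @settings(derandomize=True, max_examples=200)
    @given(t=st.floats(min_value=0.0, max_value=2000.0,
                       allow_nan=False, allow_infinity=False))
    def test_output_is_binary_and_within_schedule(self, t):
        schedule = VaccineSchedule(amplitude=2.5)
        value = vaccine_input(t, schedule)
        assert value in (0.0, 2.5)
        if value > 0:
            assert t < schedule.end_time
            assert 0 < t % schedule.cycle_length < schedule.pulse_length


class TestEffectiveParameters:
    def test_il2_scales_cytotoxicity_and_expansion(self, nominal):
        eff = effective_parameters(nominal, Regimen(il2=True), t=10.0)
        assert eff.k_iap == pytest.approx(10 * nominal.k_iap)
        assert eff.k_atc == pytest.approx(10 * nominal.k_atc)
        assert eff.k_atg == nominal.k_atg

    def test_ifna_scales_antigen_presentation(self, nominal):
        eff = effective_parameters(nominal, Regimen(ifna=True), t=10.0)
        assert eff.k_atg == pytest.approx(15 * nominal.k_atg)
        assert eff.k_iap == nominal.k_iap

    def test_outside_window_identity(self, nominal):
        regimen = Regimen(il2=True, ifna=True, therapy_window=30.0)
        assert effective_parameters(nominal, regimen, t=50.0) == nominal

    def test_no_adjuvants_identity(self, nominal):
        assert effective_parameters(nominal, Regimen.vaccine_only(), t=10.0) is nominal

    def test_input_never_mutated(self, nominal):
        before = nominal.to_dict()
        effective_parameters(nominal, Regimen(il2=True, ifna=True), t=1.0)
        assert nominal.to_dict() == before

    def test_adjuvants_commute(self, nominal):
        both = effective_parameters(nominal, Regimen(il2=True, ifna=True), t=5.0)
        via_il2_first = effective_parameters(
            effective_parameters(nominal, Regimen(il2=True), t=5.0),
            Regimen(ifna=True), t=5.0)
        via_ifna_first = effective_parameters(
            effective_parameters(nominal, Regimen(ifna=True), t=5.0),
            Regimen(il2=True), t=5.0)
        assert both == via_il2_first == via_ifna_first

    def test_factor_validation(self):
        with pytest.raises(ValueError):
            Regimen(il2_factor=0.5)


class TestModelRhs:
    def test_extinction_fixed_point(self, nominal):
        assert model_rhs(0.0, SystemState(0.0, 0.0), 0.0, nominal) == (0.0, 0.0)

    def test_logistic_equilibrium_without_immunity(self, nominal):
        p = nominal.replace(k_ink=0.0)
        _, dM = model_rhs(0.0, SystemState(0.0, p.M_T), 0.0, p)
        assert dM == pytest.approx(0.0, abs=1e-14)

    def test_activation_half_saturation(self, nominal):
        M = nominal.k_tapc / nominal.k_atg
        dT, _ = model_rhs(0.0, SystemState(0.0, M), 0.0, nominal)
        assert dT == pytest.approx(0.5 * nominal.k_apc)

    def test_against_independent_formula(self, nominal):
        """Cross-check the RHS against a independently written evaluation
        of the same biological terms."""
        p, T, M = nominal, 1.0, 0.5
        am = p.k_atg * M
        act = p.k_apc * am ** p.g_1 / (p.k_tapc ** p.g_1 + am ** p.g_1)
        expand = p.k_atc * T * am ** p.g_2 / (p.k_tatc ** p.g_2 + am ** p.g_2)
        dep = p.k_dtc * (T ** 3 + p.rho_mem * T)
        growth = p.k_pmc * M * (1 - M / p.M_T)
        tkill = p.k_iap * p.k_atg / (1 + p.k_iev) * T * M
        nk = p.k_ink * M / (1 + (p.k_atg / p.k_nkc) ** p.g_nk)
        dT, dM = model_rhs(0.0, SystemState(T, M), T, nominal)
        assert dT == pytest.approx(act + expand - dep, rel=1e-12)
        assert dM == pytest.approx(growth - tkill - nk, rel=1e-12)

    def test_activation_monotone_in_M_and_katg(self, nominal):
        p = nominal.replace(rho_mem=0.0)
        grids = np.linspace(1e-3, 2.0, 25)
        acts = [model_rhs(0.0, SystemState(0.0, m), 0.0, p)[0] for m in grids]
        assert np.all(np.diff(acts) >= 0)
        acts_k = [model_rhs(0.0, SystemState(0.0, 0.3), 0.0, p.replace(k_atg=k))[0]
                  for k in grids]
        assert np.all(np.diff(acts_k) >= 0)

    def test_nk_killing_decreases_with_antigen_presentation(self, nominal):
        p = nominal.replace(k_pmc=0.0, k_iap=0.0, k_ink=0.5)
        kill = [-model_rhs(0.0, SystemState(0.0, 1.0), 0.0, p.replace(k_atg=k))[1]
                for k in np.linspace(0.02, 50, 30)]
        assert np.all(np.diff(kill) <= 0)

    def test_no_delay_dependence_when_rho_zero(self, nominal):
        p = nominal.replace(rho_mem=0.0)
        outs = {model_rhs(0.0, SystemState(1.0, 0.5), d, p) for d in (0.0, 1.0, 7.0)}
        assert len(outs) == 1

    @pytest.mark.parametrize("state, delayed", [
        (SystemState(-0.1, 0.5), 0.0),
        (SystemState(1.0, float("nan")), 0.0),
        (SystemState(1.0, 0.5), -1.0),
    ])
    def test_invalid_inputs_rejected(self, nominal, state, delayed):
        with pytest.raises(ValueError):
            model_rhs(0.0, state, delayed, nominal)
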