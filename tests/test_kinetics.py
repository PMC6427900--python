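"""Rate laws, interaction factors, and the pointwise reaction terms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from angiopd.kinetics import (FIELDS, IDX, N_FIELDS, StateFields,
                              cancer_growth_rate,
                              checkpoint_inhibition_factor,
                              endothelial_growth_rate, pd1_transport_rhs,
                              pd_l1_concentration, perfusion_factor,
                              reaction_split, reaction_terms,
                              vegf_production_rate)
from angiopd.params import default_baselines, mouse_parameters
from angiopd.solver import INITIAL_VALUES


def _uniform_state(values: dict, n=4) -> StateFields:
    vals = np.zeros((N_FIELDS, n))
    for name, v in values.items():
        vals[IDX[name]] = v
    return StateFields(vals)


def baseline_state(baselines, n=4) -> StateFields:
    vals = {f: getattr(baselines, f) for f in
            ("D", "T1", "T8", "Tr", "E", "C", "I12", "I2", "Tb", "W", "G")}
    p = mouse_parameters()
    vals["P1"] = p.rho_P * (baselines.T1 + p.eps_T * baselines.Tr)
    vals["P8"] = p.rho_P * baselines.T8 * (1.0 + p.eps_G * baselines.G)
    return _uniform_state(vals, n)


class TestCancerGrowthRate:
    def test_zero_oxygen(self, mouse_params):
        assert cancer_growth_rate(0.0, mouse_params) == 0.0

    def test_normal_oxygen_gives_full_rate(self, mouse_params):
        assert cancer_growth_rate(mouse_params.W_0, mouse_params) == \
            pytest.approx(mouse_params.lam_CW)

    def test_linear_below_threshold(self, mouse_params):
        assert cancer_growth_rate(mouse_params.W_0 / 2, mouse_params) == \
            pytest.approx(mouse_params.lam_CW / 2)

    def test_capped_above_threshold(self, mouse_params):
        assert cancer_growth_rate(5 * mouse_params.W_0, mouse_params) == \
            pytest.approx(mouse_params.lam_CW)

    @given(st.floats(0, 1e-2), st.floats(0, 1e-2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nondecreasing(self, w1, w2):
        p = mouse_parameters()
        lo, hi = sorted((w1, w2))
        assert cancer_growth_rate(lo, p) <= cancer_growth_rate(hi, p) + 1e-15


class TestVegfProductionRate:
    def test_peak_at_hypoxia_threshold(self, mouse_params):
        assert vegf_production_rate(mouse_params.W_star, mouse_params) == \
            pytest.approx(mouse_params.lam_GW)

    def test_plateau_above_normal(self, mouse_params):
        for w in (mouse_params.W_0 * 1.001, 10 * mouse_params.W_0):
            assert vegf_production_rate(w, mouse_params) == \
                pytest.approx(0.3 * mouse_params.lam_GW)

    def test_zero_at_zero(self, mouse_params):
        assert vegf_production_rate(0.0, mouse_params) == 0.0

    @pytest.mark.parametrize("breakpoint", ["W_star", "W_0"])
    def test_continuity_at_breakpoints(self, mouse_params, breakpoint):
        w = getattr(mouse_params, breakpoint)
        left = vegf_production_rate(w * (1 - 1e-9), mouse_params)
        right = vegf_production_rate(w * (1 + 1e-9), mouse_params)
        assert left == pytest.approx(right, rel=1e-6)


class TestEndothelialGrowthRate:
    def test_threshold(self, mouse_params):
        assert endothelial_growth_rate(mouse_params.G_0, mouse_params) == 0.0
        assert endothelial_growth_rate(mouse_params.G_0 / 2, mouse_params) == 0.0

    def test_linear_above_threshold(self, mouse_params):
        g = mouse_params.G_0 + 1e-8
        assert endothelial_growth_rate(g, mouse_params) == \
            pytest.approx(mouse_params.lam_E * 1e-8, rel=1e-9)

    def test_value_at_half_saturation(self, mouse_params):
        expected = mouse_params.lam_E * (mouse_params.K_G - mouse_params.G_0)
        assert endothelial_growth_rate(mouse_params.K_G, mouse_params) == \
            pytest.approx(expected)


class TestCheckpointInhibition:
    def test_half_at_composite_constant(self, mouse_params):
        P = 1e-9
        L = mouse_params.Kp_TQ / P
        assert checkpoint_inhibition_factor(P, L, mouse_params) == pytest.approx(0.5)

    def test_steady_state_is_one_third(self, mouse_params):
        # P and L at their closure values give Q/K_TQ = 2
        assert checkpoint_inhibition_factor(8.715e-10, 3.86e-9, mouse_params) \
            == pytest.approx(1.0 / 3.0, rel=5e-3)

    def test_no_pd1_no_inhibition(self, mouse_params):
        assert checkpoint_inhibition_factor(0.0, 5e-9, mouse_params) == 1.0

    @given(st.floats(0, 1e-8), st.floats(0, 1e-8), st.floats(0, 1e-8))
    @settings(max_examples=50, deadline=None)
    def test_monotone_decreasing_in_P(self, p1, p2, ell):
        params = mouse_parameters()
        lo, hi = sorted((p1, p2))
        assert checkpoint_inhibition_factor(hi, ell, params) <= \
            checkpoint_inhibition_factor(lo, ell, params) + 1e-15


class TestPerfusionFactor:
    def test_no_drug_is_neutral(self, mouse_params):
        assert perfusion_factor(0.0, mouse_params, "blocking") == 1.0
        assert perfusion_factor(0.0, mouse_params, "enhancing") == 1.0

    def test_blocking_half(self, mouse_params):
        assert perfusion_factor(mouse_params.K_PB, mouse_params, "blocking") \
            == pytest.approx(0.5)

    def test_enhancing_saturates_at_two(self, mouse_params):
        assert perfusion_factor(1e3 * mouse_params.K_B, mouse_params,
                                "enhancing") == pytest.approx(2.0, abs=1e-2)

    def test_unknown_mode(self, mouse_params):
        with pytest.raises(ValueError):
            perfusion_factor(0.0, mouse_params, "osmotic")

    @given(st.floats(0, 1e-6), st.floats(0, 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_blocking_monotone_nonincreasing(self, b1, b2):
        p = mouse_parameters()
        lo, hi = sorted((b1, b2))
        assert perfusion_factor(hi, p, "blocking") <= \
            perfusion_factor(lo, p, "blocking") + 1e-15


class TestReactionTerms:
    def test_zero_state_all_zero(self, mouse_params):
        state = _uniform_state({})
        rhs = reaction_terms(state, mouse_params, I_A=0.0, I_B=0.0)
        assert np.all(rhs == 0.0)

    def test_negative_state_rejected(self, mouse_params):
        state = _uniform_state({"C": -0.1})
        with pytest.raises(ValueError):
            reaction_terms(state, mouse_params)

    def test_dosing_sources(self, mouse_params):
        from dataclasses import replace
        p = replace(mouse_params, gamma_A=3e-8, gamma_B=2e-8)
        state = _uniform_state({})
        rhs = reaction_terms(state, p, I_A=1.0, I_B=1.0)
        assert np.all(rhs[IDX["A"]] == 3e-8)
        assert np.all(rhs[IDX["B"]] == 2e-8)

    def test_baseline_residuals_of_enforced_closures(self, mouse_params,
                                                     baselines):
        """The appendix constructs lam_I2T1/lam_TbC/d_W/lam_GW so that the
        cytokine balances vanish at the baseline state; running the reactions
        there must return residuals below 1% of the largest constituent."""
        state = baseline_state(baselines)
        split = reaction_split(state, mouse_params)
        rhs = split.rhs(state)
        for name in ("I2", "Tb", "W", "G"):
            largest = split.source[IDX[name]].max()
            assert abs(rhs[IDX[name]]).max() < 0.01 * largest

    def test_dc_activation_half_saturation(self, mouse_params, baselines):
        """C = K_C with no VEGF leaves the DC activation at lam_DC*D_0/2."""
        state = baseline_state(baselines)
        state["G"] = 0.0
        split = reaction_split(state, mouse_params)
        expected = mouse_params.lam_DC * mouse_params.D_0 / 2.0
        assert split.source[IDX["D"]] == pytest.approx(expected)

    def test_pd_l1_exact_combination(self, mouse_params, baselines):
        L = pd_l1_concentration(baselines.T1, baselines.T8, baselines.Tr,
                                baselines.C, mouse_params)
        expected = mouse_params.rho_L * (
            baselines.T1 + baselines.T8
            + mouse_params.eps_T * baselines.Tr
            + mouse_params.eps_C * baselines.C)
        assert L == pytest.approx(expected, rel=1e-14)


class TestPd1TransportRhs:
    def _pieces(self, state, params):
        split = reaction_split(state, params)
        rhs = split.rhs(state)
        return (rhs[IDX["T1"]], rhs[IDX["T8"]], rhs[IDX["Tr"]], rhs[IDX["G"]])

    def test_reduction_without_cross_terms(self, baselines):
        from dataclasses import replace
        p = replace(mouse_parameters(), eps_G=1e-30, eps_T=1e-30)
        state = baseline_state(baselines)
        n = state.n_nodes
        z = np.zeros(n)
        rhs3, rhs4, rhs5, rhs12 = self._pieces(state, p)
        src1, src8 = pd1_transport_rhs(state, p, rhs3, rhs4, rhs5, rhs12,
                                       grad_T8=z, grad_G=z, lap_G=z, u=z)
        assert src1 == pytest.approx(p.rho_P * rhs3, rel=1e-9)
        assert src8 == pytest.approx(p.rho_P * rhs4, rel=1e-9)

    def test_uniform_fields_kill_cross_terms(self, mouse_params, baselines):
        state = baseline_state(baselines)
        n = state.n_nodes
        z = np.zeros(n)
        rhs3, rhs4, rhs5, rhs12 = self._pieces(state, mouse_params)
        src1, src8 = pd1_transport_rhs(state, mouse_params, rhs3, rhs4, rhs5,
                                       rhs12, grad_T8=z, grad_G=z, lap_G=z,
                                       u=z)
        p = mouse_params
        expected8 = p.rho_P * ((1 + p.eps_G * state["G"]) * rhs4
                               + p.eps_G * state["T8"] * rhs12)
        assert src8 == pytest.approx(expected8, rel=1e-9)

    def test_missing_gradients_rejected(self, mouse_params, baselines):
        state = baseline_state(baselines)
        rhs3, rhs4, rhs5, rhs12 = self._pieces(state, mouse_params)
        with pytest.raises(ValueError):
            pd1_transport_rhs(state, mouse_params, rhs3, rhs4, rhs5, rhs12,
                              grad_T8=None, grad_G=None, lap_G=None, u=None)


def test_state_fields_shape_guard():
    with pytest.raises(ValueError):
        StateFields(np.zeros((3, 5)))


def test_state_cell_total(baselines):
    state = baseline_state(baselines)
    assert state.cell_total() == pytest.approx(0.4064, abs=1e-12)
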