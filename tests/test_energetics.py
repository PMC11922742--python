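"""Pump-leak model: closed forms against an independent numerical
flux-balance solver, plus the discrete per-event cost arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from necell.constants import PA_TO_A
from necell.energetics import (
    DiscreteCostAssumptions,
    InvalidRegimeError,
    IonEnvironment,
    ProductionAssumptions,
    RestingMeasurement,
    ap_charge_cost,
    cells_per_ug_protein,
    energy_budget_cohort,
    nernst,
    partition_conductance,
    production_rate_per_cell,
    resting_atp_rate,
    round_to_sig_figs,
    vesicle_count_from_capacitance,
    vesicle_release_cost,
)


def solve_flux_balance(V, g_in, env):
    """Independent oracle: find the pump cycle rate a (mol/s) such that the
    two ion balances and the conductance sum are simultaneously satisfied:

        g_Na (E_Na - V) = 3 F a        (Na influx = 3 x pump rate)
        g_K  (V - E_K)  = 2 F a        (K efflux  = 2 x pump rate)
        g_Na + g_K = g_in

    solved numerically with a bracketing root finder on the conductance-sum
    residual.  Currents in amperes, conductances in siemens.
    """
    g_in_S = g_in * 1e-9
    dna = (env.E_Na - V) * 1e-3  # volts
    dk = (V - env.E_K) * 1e-3

    def residual(a):
        g_na = 3 * env.F * a / dna
        g_k = 2 * env.F * a / dk
        return g_na + g_k - g_in_S

    # a is bounded by the rate a single fraction carrying all of g_in implies
    a_hi = g_in_S * dna / (3 * env.F)
    a = brentq(residual, 0.0, a_hi, xtol=1e-30, rtol=1e-15)
    g_na = 3 * env.F * a / dna
    return g_na * 1e9, (g_in_S - g_na) * 1e9, a  # nS, nS, mol/s


class TestNernst:
    def test_equal_concentrations_give_zero(self):
        assert nernst(1, 140.0, 140.0) == pytest.approx(0.0, abs=1e-12)

    def test_tenfold_gradient_at_25C(self):
        env = IonEnvironment(T=298.15)
        # RT/F ln 10 = 59.16 mV, frozen from the CODATA constants
        assert nernst(1, 100.0, 10.0, env) == pytest.approx(59.159, abs=0.01)

    def test_valence_negation_flips_sign(self):
        env = IonEnvironment(T=298.15)
        assert nernst(-1, 100.0, 10.0, env) == pytest.approx(
            -nernst(1, 100.0, 10.0, env), rel=1e-12)

    @pytest.mark.parametrize("c_out,c_in", [(0.0, 10.0), (10.0, 0.0),
                                            (-1.0, 5.0)])
    def test_nonpositive_concentration_rejected(self, c_out, c_in):
        with pytest.raises(ValueError):
            nernst(1, c_out, c_in)

    def test_zero_valence_rejected(self):
        with pytest.raises(ValueError):
            nernst(0, 10.0, 1.0)


class TestPartition:
    def test_derived_example_against_flux_balance(self, env):
        m = RestingMeasurement(V=-70.0, g_in=1.0)
        sol = partition_conductance(m, env)
        g_na, g_k, _ = solve_flux_balance(-70.0, 1.0, env)
        assert sol.g_Na == pytest.approx(g_na, rel=1e-9)
        assert sol.g_K == pytest.approx(g_k, rel=1e-9)
        # frozen values from the oracle
        assert sol.g_Na == pytest.approx(0.317530, rel=1e-5)
        assert sol.g_K == pytest.approx(0.682470, rel=1e-5)

    def test_limits_at_reversal_potentials(self, env):
        near_k = partition_conductance(
            RestingMeasurement(V=env.E_K + 1e-9, g_in=1.0), env)
        assert near_k.g_Na == pytest.approx(0.0, abs=1e-10)
        assert near_k.g_K == pytest.approx(1.0, abs=1e-10)
        near_na = partition_conductance(
            RestingMeasurement(V=env.E_Na - 1e-9, g_in=1.0), env)
        assert near_na.g_Na == pytest.approx(1.0, abs=1e-10)
        assert near_na.g_K == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("V", [-108.4, -120.0, 53.8, 60.0])
    def test_out_of_regime_raises_named_bound(self, V, env):
        with pytest.raises(InvalidRegimeError, match="E_K|E_Na"):
            partition_conductance(RestingMeasurement(V=V, g_in=1.0), env)

    def test_pump_current_is_third_of_sodium_current(self, env):
        sol = partition_conductance(RestingMeasurement(V=-55.0, g_in=0.7), env)
        assert sol.I_pump == pytest.approx(sol.I_Na / 3, rel=1e-15)


class TestRestingRate:
    def test_derived_example(self, env):
        sol = resting_atp_rate(RestingMeasurement(V=-70.0, g_in=1.0), env)
        _, _, a = solve_flux_balance(-70.0, 1.0, env)
        assert sol.atp_rate_mol == pytest.approx(a, rel=1e-9)
        assert sol.atp_rate_molecules == pytest.approx(8.18e7, rel=0.01)

    def test_rate_equals_sodium_current_over_three_faraday(self, env):
        sol = resting_atp_rate(RestingMeasurement(V=-62.0, g_in=1.3), env)
        assert sol.atp_rate_mol == pytest.approx(
            sol.I_Na * PA_TO_A / (3 * env.F), rel=1e-12)

    def test_closed_form_matches_solver_on_random_inputs(self, env, rng):
        V = rng.uniform(env.E_K + 1.0, env.E_Na - 1.0, 1000)
        g = rng.uniform(0.05, 5.0, 1000)
        for v_i, g_i in zip(V, g):
            sol = resting_atp_rate(RestingMeasurement(V=v_i, g_in=g_i), env)
            g_na, g_k, a = solve_flux_balance(v_i, g_i, env)
            assert abs(sol.g_Na - g_na) <= 1e-9 * abs(g_na)
            assert abs(sol.g_K - g_k) <= 1e-9 * abs(g_k)
            assert abs(sol.atp_rate_mol - a) <= 1e-9 * abs(a)

    @settings(derandomize=True, max_examples=200)
    @given(V=st.floats(-107.4, 52.8), g=st.floats(0.01, 10.0))
    def test_stoichiometry_and_linearity(self, V, g):
        env = IonEnvironment()
        sol = resting_atp_rate(RestingMeasurement(V=V, g_in=g), env)
        # Na influx : K efflux = 3 : 2 for every valid solution
        na_flux = sol.g_Na * (env.E_Na - V)
        k_flux = sol.g_K * (V - env.E_K)
        assert na_flux == pytest.approx(1.5 * k_flux, rel=1e-12)
        assert sol.g_Na + sol.g_K == pytest.approx(g, rel=1e-12)
        # rate is homogeneous of degree 1 in g_in
        sol2 = resting_atp_rate(RestingMeasurement(V=V, g_in=2 * g), env)
        assert sol2.atp_rate_mol == pytest.approx(2 * sol.atp_rate_mol,
                                                  rel=1e-12)
        # unit round trip
        assert sol.atp_rate_molecules == pytest.approx(
            sol.atp_rate_mol * env.N_A, rel=1e-15)
        assert sol.atp_rate_mol > 0

    def test_rate_vanishes_toward_both_reversal_potentials(self, env):
        for V in (env.E_K + 1e-9, env.E_Na - 1e-9):
            sol = resting_atp_rate(RestingMeasurement(V=V, g_in=1.0), env)
            assert sol.atp_rate_molecules < 0.01  # vs ~8e7 in the interior


class TestDiscreteCosts:
    def test_ap_charge_cost_printed_value(self):
        assert ap_charge_cost() == pytest.approx(2.5e6, rel=0.02)

    def test_ap_charge_cost_hand_arithmetic(self):
        a = DiscreteCostAssumptions(C_m=10.0, dV_ap=30.0)
        # 10 pF * 30 mV / (3 * 1.602176634e-19 C) = 6.242e5
        assert ap_charge_cost(a) == pytest.approx(6.242e5, rel=1e-3)

    def test_vesicle_count_about_400(self):
        raw = vesicle_count_from_capacitance()
        assert raw == pytest.approx(397.9, abs=0.1)
        assert round_to_sig_figs(raw, 1) == 400

    def test_vesicle_count_zero_and_scaled(self):
        assert vesicle_count_from_capacitance(
            DiscreteCostAssumptions(dC_vesicles=0.0)) == 0.0
        assert vesicle_count_from_capacitance(
            DiscreteCostAssumptions(dC_vesicles=50.0)) == pytest.approx(
                994.7, abs=0.1)

    @pytest.mark.parametrize("n,expected", [(0, 0.0), (1, 23_400.0),
                                            (398, 9_313_200.0)])
    def test_vesicle_release_cost_is_plain_product(self, n, expected):
        assert vesicle_release_cost(n) == pytest.approx(expected, rel=1e-12)

    def test_cells_per_ug_protein(self):
        assert cells_per_ug_protein() == pytest.approx(4000.0, rel=1e-9)
        assert cells_per_ug_protein(ProductionAssumptions(
            dry_fraction=1.0)) == pytest.approx(1000.0, rel=1e-9)
        assert cells_per_ug_protein(ProductionAssumptions(
            cell_volume=2.0)) == pytest.approx(2000.0, rel=1e-9)

    def test_production_rate_per_cell(self):
        rate = production_rate_per_cell()
        assert round_to_sig_figs(rate, 1) == 5e7
        assert production_rate_per_cell(
            ProductionAssumptions(bulk_rate=0.0)) == 0.0
        assert production_rate_per_cell(
            ProductionAssumptions(bulk_rate=40.0)) == pytest.approx(
                2 * rate, rel=1e-12)


class TestCohort:
    def test_single_cell_row_and_flagged_sem(self, env):
        df = energy_budget_cohort(
            [RestingMeasurement(V=-70.0, g_in=1.0, cell_id="c1",
                                condition="ctrl")], env)
        cells = df[df.row_type == "cell"]
        agg = df[df.row_type == "aggregate"]
        expected = resting_atp_rate(
            RestingMeasurement(V=-70.0, g_in=1.0), env).atp_rate_molecules
        assert len(cells) == 1
        assert cells.iloc[0].atp_rate_molecules_s == pytest.approx(expected)
        assert math.isnan(agg.iloc[0].sem_molecules_s)

    def test_two_identical_cells_zero_sem(self, env):
        ms = [RestingMeasurement(V=-70.0, g_in=1.0, cell_id=f"c{i}",
                                 condition="ctrl") for i in range(2)]
        agg = energy_budget_cohort(ms, env).query("row_type == 'aggregate'")
        assert agg.iloc[0].sem_molecules_s == 0.0
        assert agg.iloc[0].n_cells == 2

    def test_group_means_ordered_as_generating_distributions(self, env):
        from necell.simulate import simulate_resting_cohort
        cohort, _ = simulate_resting_cohort(seed=11)
        df = energy_budget_cohort(cohort, env)
        agg = df[df.row_type == "aggregate"].set_index("condition")
        # direct per-cell evaluation as the oracle
        for m in cohort:
            row = df[(df.row_type == "cell") & (df.cell_id == m.cell_id)]
            assert row.iloc[0].atp_rate_molecules_s == pytest.approx(
                resting_atp_rate(m, env).atp_rate_molecules, rel=1e-12)
        # starved cells (depolarized, low g) demand less than lactate-fed
        assert (agg.loc["starvation_16h"].atp_rate_molecules_s
                < agg.loc["glucose_5mM_16h"].atp_rate_molecules_s
                < agg.loc["lactate_10mM_16h"].atp_rate_molecules_s)

    def test_invalid_cells_excluded_with_reason(self, env):
        ms = [RestingMeasurement(V=-70.0, g_in=1.0, cell_id="ok"),
              RestingMeasurement(V=-120.0, g_in=1.0, cell_id="bad")]
        df = energy_budget_cohort(ms, env)
        bad = df[df.row_type == "excluded"]
        assert list(bad.cell_id) == ["bad"]
        assert "E_K" in bad.iloc[0].reason

    def test_empty_cohort_returns_empty_frame(self, env):
        df = energy_budget_cohort([], env)
        assert df.empty
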