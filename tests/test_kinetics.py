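"""Reaction-network construction, initial states, and trajectory propagation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm, null_space

import pgbkinetics as pk
from pgbkinetics.kinetics import (
    R_CO,
    R_DOCK1,
    R_FREE,
    SPECIES,
    T_CO,
    T_DOCK1,
    T_FREE,
)

from conftest import random_rate_set

rate_values = st.floats(min_value=0.0, max_value=1e9, allow_nan=False)


class TestRateMatrix:
    def test_all_rates_zero_gives_zero_matrix(self):
        a = pk.build_rate_matrix(pk.RateConstants(), co_molar=1e-3)
        assert np.all(a == 0.0)

    @settings(max_examples=50, derandomize=True)
    @given(
        k1=rate_values, kg_r=rate_values, kout=rate_values,
        kin_r=rate_values, kc=rate_values, kdiss_t=rate_values,
    )
    def test_columns_sum_to_zero(self, k1, kg_r, kout, kin_r, kc, kdiss_t):
        rates = pk.RateConstants(k1=k1, kg_r=kg_r, kout=kout, kin_r=kin_r,
                                 kc=kc, kdiss_t=kdiss_t)
        a = pk.build_rate_matrix(rates, co_molar=1e-3)
        # column sums vanish to machine precision relative to the largest entry
        assert np.allclose(a.sum(axis=0), 0.0, atol=1e-13 * max(1.0, np.abs(a).max()))
        off_diag = a - np.diag(np.diag(a))
        assert np.all(off_diag >= 0.0)

    def test_unliganded_interconversion_equilibrium(self):
        """With only k3/k_3 active, the stationary r/t split of the free states
        equals the rate ratio K3 = 3."""
        rates = pk.RateConstants(k3=6e4, k_3=2e4)
        a = pk.build_rate_matrix(rates, co_molar=0.0)
        block = a[np.ix_([R_FREE, T_FREE], [R_FREE, T_FREE])]
        stationary = null_space(block)[:, 0]
        stationary /= stationary.sum()
        assert stationary[1] / stationary[0] == pytest.approx(3.0, rel=1e-9)

    @pytest.mark.parametrize(
        "fwd_name,bwd_name,src,dst",
        [("k1", "k_1", R_CO, T_CO), ("k2", "k_2", R_DOCK1, T_DOCK1),
         ("k3", "k_3", R_FREE, T_FREE), ("kc", "k_c", R_DOCK1, 4),
         ("kd2", "k_d2", T_DOCK1, 5)],
    )
    def test_detailed_balance_isolated_pairs(self, fwd_name, bwd_name, src, dst):
        rates = pk.RateConstants(**{fwd_name: 7.3e5, bwd_name: 1.9e5})
        a = pk.build_rate_matrix(rates, co_molar=0.0)
        block = a[np.ix_([src, dst], [src, dst])]
        stationary = null_space(block)[:, 0]
        assert stationary[1] / stationary[0] == pytest.approx(7.3e5 / 1.9e5, rel=1e-9)

    def test_entry_fluxes_and_pseudo_first_order_scaling(self, wt):
        a1 = pk.build_rate_matrix(wt, co_molar=1e-3)
        a10 = pk.build_rate_matrix(wt, co_molar=1e-2)
        assert a1[R_DOCK1, R_FREE] == wt.kin_r * 1e-3
        assert a1[T_DOCK1, T_FREE] == wt.kin_t * 1e-3
        assert a10[R_DOCK1, R_FREE] == 10.0 * a1[R_DOCK1, R_FREE]
        assert a10[T_DOCK1, T_FREE] == 10.0 * a1[T_DOCK1, T_FREE]

    def test_scavenger_mode_disables_entry(self, wt):
        a = pk.build_rate_matrix(wt, co_molar=1e-3, scavenger_mode=True)
        assert a[R_DOCK1, R_FREE] == 0.0
        assert a[T_DOCK1, T_FREE] == 0.0

    def test_invalid_inputs_rejected(self, wt):
        with pytest.raises(pk.InvalidParameterError):
            pk.build_rate_matrix(wt, co_molar=-1e-3)
        with pytest.raises(pk.InvalidParameterError):
            pk.RateConstants(k1=-1.0)
        with pytest.raises(pk.InvalidParameterError):
            pk.RateConstants(kout=float("nan"))


class TestInitialStates:
    def test_photolysis_split_follows_bound_equilibrium(self, wt):
        rates = wt.replace(k1=0.3e5, k_1=1.0e5)  # K1 = 0.3
        state = pk.photolysis_initial_state(rates, pk.ExperimentConditions())
        assert state["R_dock1"] == pytest.approx(1.0 / 1.3, rel=1e-12)
        assert state["T_dock1"] == pytest.approx(0.3 / 1.3, rel=1e-12)
        assert state["R_CO"] == 0.0 and state["T_CO"] == 0.0

    def test_single_conformation_limit(self, wt):
        state = pk.photolysis_initial_state(wt.replace(k1=0.0), pk.ExperimentConditions())
        assert state["R_dock1"] == 1.0
        assert sum(state.as_dict().values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_yield_keeps_everything_bound(self, wt):
        state = pk.photolysis_initial_state(
            wt, pk.ExperimentConditions(photolysis_yield=0.0)
        )
        assert state.bound_fraction == pytest.approx(1.0, abs=1e-12)
        assert state["R_dock1"] == 0.0 and state["T_dock1"] == 0.0

    def test_degenerate_equilibrium_raises(self, wt):
        with pytest.raises(pk.DegenerateEquilibriumError):
            pk.photolysis_initial_state(wt.replace(k_1=0.0), pk.ExperimentConditions())

    def test_state_vector_invariants_enforced(self):
        with pytest.raises(pk.InvalidParameterError):
            pk.StateVector(np.full(8, 0.25))  # sums to 2
        with pytest.raises(pk.InvalidParameterError):
            pk.StateVector(np.array([1.5, -0.5, 0, 0, 0, 0, 0, 0]))


class TestSimulateTrace:
    def test_frozen_system_stays_fully_photolysed(self, cond_1atm, coarse_times):
        trace = pk.simulate_trace(pk.RateConstants(), cond_1atm, coarse_times)
        assert np.allclose(trace.signal, 1.0, atol=1e-12)

    def test_geminate_branching_ratio(self, coarse_times):
        """With only geminate rebinding vs escape (no re-entry), the long-time
        rebound fraction is kg_r / (kg_r + kout) = 0.25."""
        rates = pk.RateConstants(kg_r=5e7, kout=1.5e8)
        trace = pk.simulate_trace(rates, pk.ExperimentConditions(co_pressure=0.0),
                                  coarse_times)
        assert 1.0 - trace.signal[-1] == pytest.approx(0.25, rel=1e-6)

    @pytest.mark.parametrize("method", ["stiff", "eig"])
    def test_matches_matrix_exponential_oracle(self, method, cond_1atm):
        rng = np.random.default_rng(7)
        times = pk.log_times(1e-8, 1e-1, per_decade=8)
        for _ in range(5):
            rates = pk.RateConstants(**random_rate_set(rng))
            trace = pk.simulate_trace(rates, cond_1atm, times, method=method)
            a = pk.build_rate_matrix(rates, cond_1atm.co_molar)
            y0 = pk.photolysis_initial_state(rates, cond_1atm).populations
            oracle = np.column_stack([expm(a * t) @ y0 for t in times])
            assert np.max(np.abs(trace.species - oracle)) < 1e-6

    def test_mass_conserved_along_trajectory(self, wt, cond_1atm, coarse_times):
        trace = pk.simulate_trace(wt, cond_1atm, coarse_times)
        sums = trace.species.sum(axis=0)
        assert np.max(np.abs(sums - 1.0)) < 1e-9
        assert np.all(trace.species >= 0.0)

    def test_unliganded_fraction_monotone_without_thermal_dissociation(
        self, wt, cond_1atm, coarse_times
    ):
        rates = wt.replace(kdiss_r=0.0, kdiss_t=0.0)
        trace = pk.simulate_trace(rates, cond_1atm, coarse_times)
        assert np.all(np.diff(trace.signal) <= 1e-9)

    def test_initial_signal_equals_photolysis_yield(self, wt):
        times = np.concatenate([[1e-14], pk.log_times(1e-8, 1e-3, 10)])
        cond = pk.ExperimentConditions(photolysis_yield=0.6)
        trace = pk.simulate_trace(wt, cond, times)
        assert trace.signal[0] == pytest.approx(0.6, abs=1e-6)

    def test_trace_validation(self):
        with pytest.raises(pk.InvalidParameterError):
            pk.KineticTrace(times=np.array([1.0, 1.0, 2.0]), signal=np.zeros(3))
        with pytest.raises(pk.InvalidParameterError):
            pk.KineticTrace(times=np.array([1.0, 2.0]), signal=np.array([0.0, 2.0]))


class TestNoDisplacement:
    def test_requires_scavenger_mode(self, wt, cond_1atm, coarse_times):
        with pytest.raises(pk.InvalidParameterError):
            pk.simulate_no_displacement(wt, cond_1atm, coarse_times)

    def test_no_geminate_recapture_gives_kdiss_exactly(self, scavenger_conditions):
        """r-only pathway with kg_r = 0: the bound decay rate is kdiss_r."""
        rates = pk.RateConstants(kdiss_r=0.05, kout=1.5e8, kg_r=0.0)
        times = pk.log_times(1e-2, 200.0, per_decade=20)
        trace = pk.simulate_no_displacement(rates, scavenger_conditions, times)
        fit = pk.fit_multiexponential(trace, 1)
        assert 1.0 / fit.lifetimes[0] == pytest.approx(0.05, rel=1e-6)

    def test_branching_relation_helper(self):
        assert pk.apparent_off_rate(1.0, 3.0, 1.0) == pytest.approx(0.75, rel=1e-12)
        assert pk.apparent_off_rate(0.05, 1.5e8, 0.0) == pytest.approx(0.05)

    def test_frozen_interconversion_gives_biexponential_branching_rates(
        self, wt, scavenger_conditions
    ):
        times = pk.log_times(1e-3, 200.0, per_decade=25)
        trace = pk.simulate_no_displacement(
            wt, scavenger_conditions, times, freeze_interconversion=True
        )
        fit = pk.fit_multiexponential(trace, 2)
        expected_r = pk.apparent_off_rate(wt.kdiss_r, wt.kout, wt.kg_r)
        expected_t = pk.apparent_off_rate(wt.kdiss_t, wt.kout, wt.kg_t)
        rates_fit = np.sort(1.0 / fit.lifetimes)
        assert rates_fit[0] == pytest.approx(expected_r, rel=1e-3)
        assert rates_fit[1] == pytest.approx(expected_t, rel=1e-3)
        # WT-scale check of the branching algebra: kout/(kout+kg_r) = 0.75
        assert expected_r == pytest.approx(0.75 * wt.kdiss_r, rel=1e-12)

    def test_premix_state_uses_unfrozen_equilibrium(self, wt, scavenger_conditions):
        times = pk.log_times(1e-6, 1e-4, per_decade=10)
        trace = pk.simulate_no_displacement(
            wt, scavenger_conditions, times, freeze_interconversion=True
        )
        k1_ratio = wt.k1 / wt.k_1
        assert trace.species[T_CO, 0] == pytest.approx(
            k1_ratio / (1 + k1_ratio), rel=1e-4
        )
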