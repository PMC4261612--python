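"""Compartmental system: rate matrix, solvers, conservation, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clozapk import (
    DoseEvent,
    FixedEffects,
    ModelStructureConfig,
    brain_plasma_ratio,
    build_rate_matrix,
    compartment_labels,
    mass_balance_error,
    net_efflux,
    simulate_constant_infusion,
    simulate_profile,
)
from clozapk.parameters import CHANNELS

RAT_TIMES = [-30.0, 0.0, 15.0, 30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0,
             240.0, 270.0, 300.0, 330.0, 360.0, 420.0, 480.0]
DOSE = [DoseEvent(0.0, 3.5, "sc_parent")]  # 10 mg/kg x 0.35 kg


def _random_params(rng) -> FixedEffects:
    ref = {
        "cl_clo": 0.5, "v_clo_p": 19.4, "ka_clo": 0.00801, "q_clo": 2.01,
        "v_clo_b": 0.214, "ktr1": 0.0125, "f_clo": 1.0, "cl_clo_met": 0.055,
        "cl_met": 0.419, "v_met_p": 2.95, "ka_met": 0.00277, "q_met": 0.388,
        "v_met_b": 0.25, "ktr2": 0.00517, "f_met": 1.0,
    }
    return FixedEffects(**{k: v * np.exp(rng.uniform(-1.5, 1.5)) for k, v in ref.items()})


class TestRateMatrix:
    def test_micro_rate_constants(self, reference_params, default_structure):
        A = build_rate_matrix(reference_params, default_structure)
        labels = compartment_labels(default_structure)
        pp = labels.index("plasma_parent")
        bp = labels.index("brain_parent")
        elim = labels.index("eliminated")
        # plasma elimination micro-rate CL/V and brain->plasma micro-rate Q/Vb
        assert A[elim, pp] >= 0.5 / 19.4 - 1e-12  # elimination row also holds CL_met part
        assert A[elim, pp] == pytest.approx(0.5 / 19.4, rel=1e-9)
        assert A[pp, bp] == pytest.approx(2.01 / 0.214, rel=1e-9)
        assert A[pp, bp] == pytest.approx(9.393, rel=1e-3)

    def test_columns_sum_to_zero_for_random_parameters(self, default_structure):
        rng = np.random.default_rng(0)
        for _ in range(20):
            A = build_rate_matrix(_random_params(rng), default_structure)
            assert np.abs(A.sum(axis=0)).max() < 1e-12

    def test_transit_count_changes_dimension(self, reference_params):
        for ntp, ntm in [(0, 0), (2, 1), (4, 3)]:
            s = ModelStructureConfig(n_transit_parent=ntp, n_transit_metabolite=ntm)
            assert build_rate_matrix(reference_params, s).shape[0] == 7 + ntp + ntm


class TestSimulation:
    def test_zero_dose_gives_zero_everywhere(self, reference_params, default_structure):
        sim = simulate_profile(
            reference_params, default_structure,
            [DoseEvent(0.0, 0.0, "sc_parent")], RAT_TIMES,
        )
        for c in CHANNELS:
            assert np.all(sim.concentrations[c] == 0.0)

    def test_predose_samples_are_exactly_zero(self, reference_params, default_structure):
        sim = simulate_profile(reference_params, default_structure, DOSE, RAT_TIMES)
        for c in CHANNELS:
            assert sim.concentrations[c][0] == 0.0  # -30 min
            assert sim.concentrations[c][1] == 0.0  # 0 min (pre-dose convention)

    def test_mass_balance_at_reference(self, reference_params, default_structure):
        sim = simulate_profile(reference_params, default_structure, DOSE, RAT_TIMES)
        assert mass_balance_error(sim, reference_params, default_structure, DOSE) < 1e-9
        post = np.array(RAT_TIMES) > 0
        np.testing.assert_allclose(sim.total_amount()[post], 3.5, rtol=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_mass_balance_for_random_parameter_draws(self, seed):
        """Conservation: system amount + eliminated equals bioavailable dose."""
        rng = np.random.default_rng(seed)
        params = _random_params(rng)
        structure = ModelStructureConfig()
        doses = [DoseEvent(0.0, 3.5, "sc_parent"), DoseEvent(120.0, 1.7, "sc_metabolite")]
        sim = simulate_profile(params, structure, doses, RAT_TIMES)
        assert mass_balance_error(sim, params, structure, doses) < 1e-9

    def test_solver_equivalence(self, reference_params, default_structure):
        """Matrix-exponential and LSODA profiles agree to < 1e-6 relative."""
        a = simulate_profile(reference_params, default_structure, DOSE, RAT_TIMES)
        b = simulate_profile(
            reference_params, default_structure, DOSE, RAT_TIMES, solver="numeric_ode"
        )
        for c in CHANNELS:
            x, y = a.concentrations[c], b.concentrations[c]
            mask = x > 0
            if mask.any():
                assert np.max(np.abs(x - y)[mask] / x[mask]) < 1e-6

    def test_superposition_doubling(self, reference_params, default_structure):
        one = simulate_profile(reference_params, default_structure, DOSE, RAT_TIMES)
        two = simulate_profile(
            reference_params, default_structure,
            [DoseEvent(0.0, 7.0, "sc_parent")], RAT_TIMES,
        )
        for c in CHANNELS:
            np.testing.assert_allclose(
                two.concentrations[c], 2.0 * one.concentrations[c], rtol=1e-12
            )

    def test_bioavailability_scales_dose(self, reference_params, default_structure):
        half_f = reference_params.replace(f_clo=0.5)
        full = simulate_profile(reference_params, default_structure, DOSE, RAT_TIMES)
        half = simulate_profile(half_f, default_structure, DOSE, RAT_TIMES)
        np.testing.assert_allclose(
            half.concentrations["parent_plasma"],
            0.5 * full.concentrations["parent_plasma"],
            rtol=1e-12,
        )

    def test_transit_chain_delays_brain_peak(self, reference_params):
        """Removing the transit compartments makes the brain peak earlier."""
        times = np.arange(0.0, 481.0, 1.0)
        with_transits = simulate_profile(
            reference_params, ModelStructureConfig(), DOSE, times
        )
        direct = simulate_profile(
            reference_params, ModelStructureConfig(n_transit_parent=0), DOSE, times
        )
        t_direct = times[np.argmax(direct.concentrations["parent_brain"])]
        t_chain = times[np.argmax(with_transits.concentrations["parent_brain"])]
        assert t_direct < t_chain

    def test_lag_time_shifts_profile(self, reference_params):
        lagged = simulate_profile(
            reference_params, ModelStructureConfig(lag_time_parent=30.0), DOSE,
            [0.0, 15.0, 29.0, 45.0],
        )
        assert np.all(lagged.concentrations["parent_plasma"][:3] == 0.0)
        assert lagged.concentrations["parent_plasma"][3] > 0.0


class TestBrainPlasmaRatio:
    def test_closed_form_values(self, reference_params):
        assert brain_plasma_ratio(reference_params, "clozapine") == pytest.approx(
            0.0125 * 19.4 / 2.01, rel=1e-12
        )
        assert brain_plasma_ratio(reference_params, "norclozapine") == pytest.approx(
            0.00517 * 2.95 / 0.388, rel=1e-12
        )
        assert brain_plasma_ratio(reference_params, "clozapine") == pytest.approx(
            0.1206, abs=1e-4
        )
        assert brain_plasma_ratio(reference_params, "norclozapine") == pytest.approx(
            0.0393, abs=1e-4
        )

    def test_net_efflux_flag(self, reference_params):
        """Both ratios below 1: net efflux across the blood-brain barrier."""
        assert net_efflux(reference_params, "clozapine")
        assert net_efflux(reference_params, "norclozapine")

    def test_constant_infusion_oracle(self, reference_params, default_structure):
        """Steady-state concentration ratio matches Ktr * V_plasma / Q."""
        sim = simulate_constant_infusion(
            reference_params, default_structure,
            {"plasma_parent": 0.01, "plasma_metabolite": 0.01}, [6000.0],
        )
        parent = (
            sim.concentrations["parent_brain"][0] / sim.concentrations["parent_plasma"][0]
        )
        met = (
            sim.concentrations["metabolite_brain"][0]
            / sim.concentrations["metabolite_plasma"][0]
        )
        assert parent == pytest.approx(brain_plasma_ratio(reference_params, "clozapine"), rel=1e-4)
        assert met == pytest.approx(brain_plasma_ratio(reference_params, "norclozapine"), rel=1e-4)


def test_unknown_route_and_unsorted_times_rejected(reference_params, default_structure):
    with pytest.raises(ValueError):
        DoseEvent(0.0, 1.0, "iv_bolus")
    with pytest.raises(ValueError, match="sorted"):
        simulate_profile(reference_params, default_structure, DOSE, [10.0, 5.0])
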