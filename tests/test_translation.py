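"""Allometric scaling, human model construction and steady-state simulation."""

import numpy as np
import pytest

from clozapk import (
    AllometricRules,
    HumanPKConfig,
    brain_plasma_ratio,
    build_human_model,
    plasma_overlay_table,
    scale_brain_parameters,
    simulate_constant_infusion,
    simulate_human_steady_state,
    unbound_fraction_convert,
)
from clozapk.parameters import CHANNELS, REFERENCE_RAT_ESTIMATES

import pandas as pd


@pytest.fixture(scope="module")
def human_model(human_config_dict):
    return build_human_model(
        REFERENCE_RAT_ESTIMATES, HumanPKConfig.from_dict(human_config_dict)
    )


class TestScaling:
    def test_scaled_values_from_reference_estimates(self):
        scaled = scale_brain_parameters(REFERENCE_RAT_ESTIMATES, AllometricRules())
        # weight ratio 70 / 0.35 = 200
        assert scaled["q_clo"] == pytest.approx(2.01 * 200**0.75, rel=1e-12)
        assert scaled["q_clo"] == pytest.approx(106.9, abs=0.1)
        assert scaled["ktr1"] == pytest.approx(0.0125 * 200**-0.25, rel=1e-12)
        assert scaled["ktr1"] == pytest.approx(0.003324, abs=1e-6)
        assert scaled["v_clo_b"] == pytest.approx(0.214 * 200.0, rel=1e-12)

    def test_equal_weights_leave_parameters_unchanged(self):
        rules = AllometricRules(rat_weight_kg=0.35, human_weight_kg=0.35)
        scaled = scale_brain_parameters(REFERENCE_RAT_ESTIMATES, rules)
        for name, value in scaled.items():
            assert value == pytest.approx(getattr(REFERENCE_RAT_ESTIMATES, name), rel=1e-12)

    def test_rate_constant_consistency_with_cl_over_v(self):
        """CL/V of the scaled brain parameters falls as W^-0.25, matching the
        directly scaled rate constants."""
        rules = AllometricRules()
        scaled = scale_brain_parameters(REFERENCE_RAT_ESTIMATES, rules)
        ratio = rules.weight_ratio
        assert scaled["q_clo"] / scaled["v_clo_b"] == pytest.approx(
            (REFERENCE_RAT_ESTIMATES.q_clo / REFERENCE_RAT_ESTIMATES.v_clo_b)
            * ratio**-0.25,
            rel=1e-12,
        )

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            AllometricRules(human_weight_kg=0.0)
        with pytest.raises(ValueError):
            AllometricRules(rat_weight_kg=-1.0)


class TestHumanModel:
    def test_fm_half_splits_clearance_equally(self, human_model):
        assert human_model.params.cl_clo == pytest.approx(0.35)
        assert human_model.params.cl_clo_met == pytest.approx(0.35)

    def test_missing_plasma_constants_error_names_fields(self, human_config_dict):
        broken = dict(human_config_dict)
        broken["cl_clo_plasma"] = float("nan")
        with pytest.raises(ValueError, match="cl_clo_plasma"):
            HumanPKConfig.from_dict(broken)
        with pytest.raises(TypeError):
            HumanPKConfig.from_dict({"fm": 0.5})

    def test_fm_zero_gives_no_metabolite(self, human_config_dict):
        cfg = HumanPKConfig.from_dict({**human_config_dict, "fm": 0.0})
        model = build_human_model(REFERENCE_RAT_ESTIMATES, cfg)
        sim = simulate_human_steady_state(model, 200.0, n_subjects=1, seed=0)
        assert np.max(sim.profiles["metabolite_plasma"]) < 1e-9
        assert np.max(sim.profiles["metabolite_brain"]) < 1e-9

    def test_fm_one_maximises_metabolite_exposure(self, human_config_dict):
        half = build_human_model(
            REFERENCE_RAT_ESTIMATES, HumanPKConfig.from_dict(human_config_dict)
        )
        full = build_human_model(
            REFERENCE_RAT_ESTIMATES,
            HumanPKConfig.from_dict({**human_config_dict, "fm": 1.0}),
        )
        sim_half = simulate_human_steady_state(half, 200.0, n_subjects=1, seed=0)
        sim_full = simulate_human_steady_state(full, 200.0, n_subjects=1, seed=0)
        assert np.all(
            sim_full.profiles["metabolite_plasma"]
            >= sim_half.profiles["metabolite_plasma"]
        )
        assert sim_full.profiles["metabolite_plasma"].max() > 1.5 * (
            sim_half.profiles["metabolite_plasma"].max()
        )

    def test_human_brain_plasma_ratio_matches_closed_form(self, human_model):
        sim = simulate_constant_infusion(
            human_model.params, human_model.structure,
            {"plasma_parent": 1.0}, [2_000_000.0],
        )
        ratio = (
            sim.concentrations["parent_brain"][0] / sim.concentrations["parent_plasma"][0]
        )
        assert ratio == pytest.approx(
            brain_plasma_ratio(human_model.params, "clozapine"), rel=1e-4
        )


class TestUnboundConversion:
    def test_three_percent_unbound(self):
        assert unbound_fraction_convert(100.0, 0.03) == pytest.approx(3.0)

    def test_fu_one_is_identity_and_round_trip_exact(self):
        assert unbound_fraction_convert(7.3, 1.0) == 7.3
        total = 12.5
        free = unbound_fraction_convert(total, 0.03)
        assert unbound_fraction_convert(free, 0.03, "free_to_total") == pytest.approx(
            total, rel=1e-15
        )

    def test_fu_outside_unit_interval_rejected(self):
        for fu in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                unbound_fraction_convert(1.0, fu)


class TestSteadyState:
    def test_dose_linearity(self, human_model):
        a = simulate_human_steady_state(human_model, 200.0, n_subjects=20, seed=4)
        b = simulate_human_steady_state(human_model, 400.0, n_subjects=20, seed=4)
        for c in CHANNELS:
            np.testing.assert_allclose(b.profiles[c], 2.0 * a.profiles[c], rtol=1e-12)

    def test_superposition_matches_repeated_dosing(self, human_model):
        sup = simulate_human_steady_state(human_model, 300.0, n_subjects=3, seed=8)
        rep = simulate_human_steady_state(
            human_model, 300.0, n_subjects=3, seed=8, method="repeated"
        )
        assert rep.converged
        for c in CHANNELS:
            scale = max(sup.profiles[c].max(), 1e-300)
            assert np.abs(sup.profiles[c] - rep.profiles[c]).max() / scale < 1e-4

    def test_median_monotone_in_dose(self, human_model):
        sims = {
            d: simulate_human_steady_state(human_model, d, n_subjects=30, seed=2)
            for d in (200.0, 300.0, 400.0)
        }
        med = {
            d: np.median(s.profiles["parent_brain"], axis=0) for d, s in sims.items()
        }
        assert np.all(med[200.0] <= med[300.0] + 1e-15)
        assert np.all(med[300.0] <= med[400.0] + 1e-15)

    def test_grid_spans_one_interval_in_hours(self, human_model):
        sim = simulate_human_steady_state(human_model, 200.0, n_subjects=2, seed=1)
        assert sim.times_h[0] == 0.0
        assert sim.times_h[-1] == pytest.approx(24.0)

    def test_summary_percentile_ordering(self, human_model):
        sim = simulate_human_steady_state(human_model, 200.0, n_subjects=40, seed=3)
        s = sim.summary()
        assert (s.p5 <= s["median"]).all() and (s["median"] <= s.p95).all()


class TestOverlay:
    def test_overlay_window_and_flags(self, human_model):
        sim = simulate_human_steady_state(human_model, 300.0, n_subjects=40, seed=12)
        j12 = int(np.argmin(np.abs(sim.times_h - 12.0)))
        median_total = unbound_fraction_convert(
            float(np.median(sim.profiles["parent_plasma"][:, j12])),
            0.03, "free_to_total",
        )
        published = pd.DataFrame(
            {
                "time_h": [6.0, 12.0, 18.0],
                "conc_total_mg_per_l": [1.0, median_total, 1e6],
            }
        )
        table = plasma_overlay_table(sim, published, fu=0.03)
        # 6 h is outside the default 12-24 h window
        assert set(table.time_h) == {12.0, 18.0}
        assert bool(table.loc[table.time_h == 12.0, "inside"].iloc[0])
        assert not bool(table.loc[table.time_h == 18.0, "inside"].iloc[0])

    def test_overlay_requires_columns(self, human_model):
        sim = simulate_human_steady_state(human_model, 200.0, n_subjects=2, seed=0)
        with pytest.raises(ValueError, match="columns"):
            plasma_overlay_table(sim, pd.DataFrame({"t": [1]}), fu=0.03)
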