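"""Likelihood, population fitting, empirical Bayes and the likelihood-ratio test."""

import math

import numpy as np
import pandas as pd
import pytest

from clozapk import (
    FixedEffects,
    GeneratorConfig,
    ModelStructureConfig,
    RandomEffectSpec,
    ResidualSpec,
    StudyDataset,
    default_rat_design,
    empirical_bayes,
    fit_population,
    generate_study,
    likelihood_ratio_test,
    negative_two_loglik,
    scale_design,
)
from clozapk.estimation import FitResult
from clozapk.parameters import (
    CHANNELS,
    DEFAULT_FIXED_PARAMETERS,
    REFERENCE_RANDOM_EFFECTS,
    REFERENCE_RAT_ESTIMATES,
    REFERENCE_RESIDUALS,
)

TRUTH = REFERENCE_RAT_ESTIMATES


def _perturbed(factor_map) -> FixedEffects:
    return TRUTH.replace(
        **{n: getattr(TRUTH, n) * f for n, f in factor_map.items()}
    )


PERTURBED_START = _perturbed(
    dict(cl_clo=1.3, v_clo_p=0.8, ka_clo=1.25, q_clo=0.75, ktr1=1.3, cl_clo_met=0.7,
         cl_met=1.3, v_met_p=0.8, ka_met=1.25, q_met=0.75, ktr2=1.3)
)


class TestObjective:
    def test_pooled_ofv_closed_form_at_perfect_fit(self, clean_dataset):
        """With obs == pred, the OFV reduces to sum log(2 pi (sigma*pred)^2)."""
        ofv = negative_two_loglik(
            clean_dataset, TRUTH, REFERENCE_RESIDUALS, method="pooled"
        )
        obs = clean_dataset.observations()
        sig = obs["CHANNEL"].map(REFERENCE_RESIDUALS.sigmas).to_numpy(dtype=float)
        expected = np.sum(np.log(2.0 * np.pi * (sig * obs["DV"].to_numpy()) ** 2))
        assert ofv == pytest.approx(expected, abs=1e-8)

    def test_laplace_equals_pooled_without_random_effects(self, noisy_dataset):
        pooled = negative_two_loglik(
            noisy_dataset, TRUTH, REFERENCE_RESIDUALS, method="pooled"
        )
        laplace = negative_two_loglik(
            noisy_dataset, TRUTH, REFERENCE_RESIDUALS,
            RandomEffectSpec({}), method="laplace",
        )
        assert abs(laplace - pooled) < 1e-8

    def test_laplace_with_zero_omegas_equals_pooled(self, noisy_dataset):
        zero = RandomEffectSpec({k: 0.0 for k in REFERENCE_RANDOM_EFFECTS.omegas})
        pooled = negative_two_loglik(
            noisy_dataset, TRUTH, REFERENCE_RESIDUALS, method="pooled"
        )
        laplace = negative_two_loglik(
            noisy_dataset, TRUTH, REFERENCE_RESIDUALS, zero, method="laplace"
        )
        assert abs(laplace - pooled) < 1e-8

    def test_doubling_sigma_shifts_ofv_by_2n_log2(self, clean_dataset):
        """At zero residuals, OFV(2 sigma) - OFV(sigma) = 2 N log 2 exactly."""
        doubled = ResidualSpec({k: 2 * v for k, v in REFERENCE_RESIDUALS.sigmas.items()})
        a = negative_two_loglik(clean_dataset, TRUTH, REFERENCE_RESIDUALS, method="pooled")
        b = negative_two_loglik(clean_dataset, TRUTH, doubled, method="pooled")
        n_obs = clean_dataset.n_observations()
        assert b - a == pytest.approx(2.0 * n_obs * math.log(2.0), rel=1e-12)

    def test_zero_prediction_with_nonzero_observation_gives_infinite_ofv(self):
        df = pd.DataFrame(
            [
                dict(ID=1, ARM="clozapine", WT=0.35, TIME=60.0, EVID=1, AMT=3.5,
                     DV=np.nan, CHANNEL="", BQL=0),
                dict(ID=1, ARM="clozapine", WT=0.35, TIME=15.0, EVID=0, AMT=0.0,
                     DV=0.01, CHANNEL="parent_plasma", BQL=0),
            ]
        )
        ofv = negative_two_loglik(StudyDataset(df), TRUTH, REFERENCE_RESIDUALS,
                                  method="pooled")
        assert math.isinf(ofv)

    def test_ofv_invariant_to_row_order_and_relabeling(self, noisy_dataset):
        base = negative_two_loglik(
            noisy_dataset, TRUTH, REFERENCE_RESIDUALS, REFERENCE_RANDOM_EFFECTS
        )
        df = noisy_dataset.df.sample(frac=1.0, random_state=4).reset_index(drop=True)
        df["ID"] = df["ID"].map(lambda i: f"rat_{i * 7 % 13}")
        shuffled = negative_two_loglik(
            StudyDataset(df), TRUTH, REFERENCE_RESIDUALS, REFERENCE_RANDOM_EFFECTS
        )
        assert shuffled == pytest.approx(base, abs=1e-6)


class TestFit:
    def test_noise_free_recovery_within_one_percent(self, clean_dataset):
        """Self-consistency: zero-noise, zero-BAV data inverts the generator."""
        small_sigma = ResidualSpec({c: 0.01 for c in CHANNELS})
        fit = fit_population(
            clean_dataset, PERTURBED_START, RandomEffectSpec({}), small_sigma,
            method="pooled", estimate_sigmas=False, maxiter=500,
        )
        for name in FixedEffects.parameter_names():
            est, true = getattr(fit.fixed_effects, name), getattr(TRUTH, name)
            assert abs(est - true) / true < 0.01, name

    def test_ofv_trace_non_increasing(self, clean_dataset):
        small_sigma = ResidualSpec({c: 0.01 for c in CHANNELS})
        fit = fit_population(
            clean_dataset, PERTURBED_START, RandomEffectSpec({}), small_sigma,
            method="pooled", estimate_sigmas=False, maxiter=200,
        )
        trace = fit.ofv_trace
        assert len(trace) > 2
        assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))

    def test_non_convergence_is_flagged_with_best_so_far(self, noisy_dataset):
        fit = fit_population(
            noisy_dataset, PERTURBED_START, RandomEffectSpec({}), REFERENCE_RESIDUALS,
            method="pooled", maxiter=2,
        )
        assert not fit.converged
        assert math.isfinite(fit.ofv)

    def test_fixed_parameters_stay_fixed(self, noisy_dataset):
        fit = fit_population(
            noisy_dataset, TRUTH, RandomEffectSpec({}), REFERENCE_RESIDUALS,
            method="pooled", maxiter=30,
        )
        assert fit.fixed_effects.v_clo_b == TRUTH.v_clo_b
        assert fit.fixed_effects.v_met_b == TRUTH.v_met_b
        assert fit.fixed_effects.f_clo == 1.0

    def test_relative_standard_errors_non_negative(self, clean_dataset):
        small_sigma = ResidualSpec({c: 0.01 for c in CHANNELS})
        fit = fit_population(
            clean_dataset, TRUTH, RandomEffectSpec({}), small_sigma,
            method="pooled", estimate_sigmas=False, maxiter=50, compute_se=True,
        )
        assert fit.rse
        assert all(v >= 0 for v in fit.rse.values())

    def test_replicate_recovery_median_bias_under_15_percent(self):
        """Median relative bias of each fixed effect over 10 replicate
        24-rat/arm studies stays below 15% (variability fixed at truth)."""
        estimates = []
        for rep in range(10):
            ds = generate_study(
                scale_design(default_rat_design(), 24), GeneratorConfig(seed=1000 + rep)
            )
            fit = fit_population(
                ds, TRUTH, REFERENCE_RANDOM_EFFECTS, REFERENCE_RESIDUALS,
                method="laplace", estimate_omegas=False, estimate_sigmas=False,
                maxiter=20,
            )
            estimates.append(fit.fixed_effects.to_dict())
        for name in FixedEffects.parameter_names():
            if name in DEFAULT_FIXED_PARAMETERS:
                continue
            rel = [(e[name] - getattr(TRUTH, name)) / getattr(TRUTH, name)
                   for e in estimates]
            assert abs(np.median(rel)) < 0.15, name


class TestEmpiricalBayes:
    def test_zero_omega_gives_zero_etas(self, noisy_dataset, default_structure):
        fit = FitResult(
            TRUTH, RandomEffectSpec({k: 0.0 for k in REFERENCE_RANDOM_EFFECTS.omegas}),
            REFERENCE_RESIDUALS, ofv=0.0, method="laplace", structure=default_structure,
        )
        ebes = empirical_bayes(noisy_dataset, fit)
        for etas in ebes.values():
            assert all(v == 0.0 for v in etas.values())

    def test_noise_free_zero_bav_subject_has_near_zero_etas(
        self, clean_dataset, reference_fit
    ):
        ebes = empirical_bayes(clean_dataset, reference_fit)
        worst = max(abs(v) for etas in ebes.values() for v in etas.values())
        # the proportional-error log-variance term shifts the conditional
        # mode by O(sigma^2) even at zero residuals; the etas are near zero
        # relative to the omegas (0.05-0.37), not exactly zero
        assert worst < 0.02

    def test_subject_without_observations_warned_and_zeroed(self, reference_fit):
        df = pd.DataFrame(
            [dict(ID=1, ARM="clozapine", WT=0.35, TIME=0.0, EVID=1, AMT=3.5,
                  DV=np.nan, CHANNEL="", BQL=0)]
        )
        with pytest.warns(UserWarning, match="no observations"):
            ebes = empirical_bayes(StudyDataset(df), reference_fit)
        assert all(v == 0.0 for v in ebes[1].values())

    def test_ebe_spread_recovers_omega_at_rich_sampling(self, reference_fit):
        """Sample SD of the EBEs approaches omega (mild shrinkage) when each
        animal contributes dense plasma + brain sampling."""
        from clozapk.synth import ArmDesign, StudyDesign

        design = StudyDesign(
            arms=(ArmDesign(compound="clozapine", n_animals=80, body_weight_kg=0.35),)
        )
        ds = generate_study(design, GeneratorConfig(seed=21))
        ebes = empirical_bayes(ds, reference_fit)
        for p in ("q_clo", "ktr1", "f_clo"):
            sd = np.std([e[p] for e in ebes.values()])
            omega = REFERENCE_RANDOM_EFFECTS.omega(p)
            assert 0.7 * omega < sd < 1.15 * omega, p


class TestLikelihoodRatio:
    def test_delta_663_is_significant_at_001(self):
        res = likelihood_ratio_test(ofv_full=100.0, ofv_reduced=106.63, df=1)
        assert res.p_value == pytest.approx(0.01, abs=5e-4)
        assert res.significant

    def test_zero_delta_not_significant(self):
        res = likelihood_ratio_test(100.0, 100.0, df=1)
        assert res.p_value == 1.0
        assert not res.significant

    def test_delta_384_not_significant_at_001(self):
        res = likelihood_ratio_test(100.0, 103.84, df=1)
        assert res.p_value == pytest.approx(0.05, abs=5e-4)
        assert not res.significant

    def test_negative_delta_warns_and_returns_p_one(self):
        with pytest.warns(UserWarning, match="negative OFV"):
            res = likelihood_ratio_test(100.0, 99.0, df=1)
        assert res.p_value == 1.0
        assert not res.significant

    def test_df_must_be_positive(self):
        with pytest.raises(ValueError):
            likelihood_ratio_test(1.0, 2.0, df=0)
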