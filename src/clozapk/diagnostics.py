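"""Model evaluation: weighted residuals, visual predictive check, bootstrap.

The visual predictive check (VPC) simulates many replicate studies under the
fitted model and compares the observed per-timepoint medians with the 90%
prediction interval of the replicate-wise medians.  Parameter uncertainty is
quantified by a nonparametric bootstrap resampling animals with replacement,
stratified by study arm so every replicate keeps the original arm sizes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .dataset import StudyDataset
from .estimation import (
    FitResult,
    _attach_plans,
    _prepare_subjects,
    _predict_obs,
    _subject_inner,
    _subject_varying,
    fit_population,
)
from .parameters import (
    CHANNELS,
    FixedEffects,
    RandomEffectSpec,
    ResidualSpec,
    _individual_unchecked,
)
from .synth import GeneratorConfig, StudyDesign, design_from_dataset, generate_study

__all__ = ["VPCResult", "BootstrapResult", "weighted_residuals", "vpc", "bootstrap"]


# --------------------------------------------------------------------------- #
# goodness of fit

def weighted_residuals(dataset: StudyDataset, fit: FitResult) -> pd.DataFrame:
    """Per-observation residual table at the individual and population level.

    Individual-level residuals (IWRES) are ``(obs - ipred) / (sigma * ipred)``
    with predictions at the subject's empirical Bayes etas.  Population-level
    conditional weighted residuals (CWRES) come from a first-order
    linearization of the model around the etas: the observation vector is
    decorrelated with the linearized covariance ``J Omega J' + diag((sigma *
    ipred)^2)``.  If that covariance is not positive definite, an
    eigenvalue-clipped factorization is used instead.

    Residuals against a zero prediction are flagged non-finite and the count
    is reported in the ``DataFrame.attrs['n_nonfinite']`` entry.
    """
    subjects = _prepare_subjects(dataset)
    _attach_plans(subjects, fit.structure)
    sigma_by_channel = np.array([fit.residual.sigmas.get(c, np.nan) for c in CHANNELS])
    rows = []
    n_nonfinite = 0
    for s in subjects:
        if s.y.size == 0:
            continue
        names = _subject_varying(s, fit.random_effects.varying)
        omegas = np.array([fit.random_effects.omega(p) for p in names])
        active = omegas > 1e-10
        names = [n for n, a in zip(names, active) if a]
        omegas = omegas[active]
        sig = sigma_by_channel[s.obs_channel]
        if names:
            _, eta, _ = _subject_inner(
                s, fit.fixed_effects, fit.structure, sig, names, omegas, None
            )
        else:
            eta = np.zeros(0)
        ipred = _predict_obs(
            s, _individual_unchecked(fit.fixed_effects, names, eta), fit.structure
        )
        pred = _predict_obs(s, fit.fixed_effects, fit.structure)

        with np.errstate(divide="ignore", invalid="ignore"):
            iwres = (s.y - ipred) / (sig * ipred)
        iwres[~np.isfinite(iwres)] = np.nan

        # first-order conditional linearization around the etas
        if names:
            J = np.empty((s.y.size, len(names)))
            h = 1e-4
            for k in range(len(names)):
                ep = eta.copy()
                ep[k] += h
                fp = _predict_obs(
                    s, _individual_unchecked(fit.fixed_effects, names, ep), fit.structure
                )
                J[:, k] = (fp - ipred) / h
            mean = ipred - J @ eta
            cov = J @ np.diag(omegas**2) @ J.T + np.diag((sig * ipred) ** 2)
            try:
                L = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                vals, vecs = np.linalg.eigh(cov)
                vals = np.clip(vals, 1e-12, None)
                L = vecs @ np.diag(np.sqrt(vals))
            cwres = np.linalg.solve(L, s.y - mean)
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                cwres = (s.y - pred) / (sig * pred)
        cwres = np.asarray(cwres, dtype=float)
        bad = ~np.isfinite(cwres)
        n_nonfinite += int(bad.sum()) + int(np.isnan(iwres).sum())
        cwres[bad] = np.nan

        for j in range(s.y.size):
            rows.append(
                dict(
                    ID=s.sid,
                    ARM=s.arm,
                    TIME=float(s.times[s.obs_tpos[j]]),
                    CHANNEL=CHANNELS[s.obs_channel[j]],
                    DV=s.y[j],
                    PRED=pred[j],
                    IPRED=ipred[j],
                    IWRES=iwres[j],
                    CWRES=cwres[j],
                )
            )
    out = pd.DataFrame(rows)
    out.attrs["n_nonfinite"] = n_nonfinite
    return out


# --------------------------------------------------------------------------- #
# visual predictive check

@dataclass(frozen=True)
class VPCResult:
    """Observed medians and simulated 90% prediction intervals of the median."""

    table: pd.DataFrame  # CHANNEL, TIME, observed_median, sim_p5, sim_p50, sim_p95
    n_replicates: int

    def coverage(self) -> float:
        """Fraction of timepoints at which the observed median lies inside
        the 90% interval of simulated medians."""
        t = self.table.dropna(subset=["observed_median"])
        inside = (t["observed_median"] >= t["sim_p5"]) & (
            t["observed_median"] <= t["sim_p95"]
        )
        return float(inside.mean())


def vpc(
    dataset: StudyDataset,
    fit: FitResult,
    design: StudyDesign | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
) -> VPCResult:
    """Visual predictive check of the fitted model against the dataset.

    Simulates ``n_replicates`` full studies (between-animal variability plus
    residual noise) under the fit's estimates on the dataset's own design and
    summarises the replicate-wise median per channel and timepoint.
    """
    if n_replicates < 100:
        warnings.warn("fewer than 100 VPC replicates gives unstable percentiles")
    if design is None:
        design = design_from_dataset(dataset)
    obs = dataset.observations()
    observed_median = (
        obs.groupby(["CHANNEL", "TIME"])["DV"].median().rename("observed_median")
    )

    sim_medians: dict[tuple, list[float]] = {}
    rng = np.random.default_rng(seed)
    for r in range(n_replicates):
        rep = generate_study(
            design,
            GeneratorConfig(
                fixed=fit.fixed_effects,
                random_effects=fit.random_effects,
                residual=fit.residual,
                structure=fit.structure,
                seed=int(rng.integers(0, 2**31 - 1)),
            ),
        )
        med = rep.observations().groupby(["CHANNEL", "TIME"])["DV"].median()
        for key, value in med.items():
            sim_medians.setdefault(key, []).append(value)

    rows = []
    for key, values in sorted(sim_medians.items()):
        p5, p50, p95 = np.percentile(values, [5, 50, 95])
        rows.append(
            dict(
                CHANNEL=key[0],
                TIME=key[1],
                observed_median=observed_median.get(key, np.nan),
                sim_p5=p5,
                sim_p50=p50,
                sim_p95=p95,
            )
        )
    return VPCResult(table=pd.DataFrame(rows), n_replicates=n_replicates)


# --------------------------------------------------------------------------- #
# bootstrap

@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap parameter distribution: point estimate, median, 5-95th pctiles."""

    table: pd.DataFrame  # parameter, estimate, median, p5, p95
    n_replicates: int
    n_failed: int
    flagged: bool  # more than 20% of replicates failed

    def summary(self, parameter: str) -> dict:
        row = self.table[self.table["parameter"] == parameter].iloc[0]
        return {k: float(row[k]) for k in ("estimate", "median", "p5", "p95")}


def resample_subjects(
    dataset: StudyDataset, rng: np.random.Generator
) -> StudyDataset:
    """One bootstrap replicate: subjects resampled with replacement within arm.

    Stratification by arm preserves the original number of animals per arm.
    """
    df = dataset.df
    pieces = []
    new_id = 0
    for arm in ("clozapine", "norclozapine"):
        ids = df.loc[df["ARM"] == arm, "ID"].unique()
        if len(ids) == 0:
            continue
        chosen = rng.choice(ids, size=len(ids), replace=True)
        for sid in chosen:
            new_id += 1
            block = df[df["ID"] == sid].copy()
            block["ID"] = new_id
            pieces.append(block)
    return StudyDataset(pd.concat(pieces, ignore_index=True))


def bootstrap(
    dataset: StudyDataset,
    fit: FitResult,
    n_replicates: int = 1000,
    seed: int = 0,
    method: str | None = None,
    maxiter: int = 200,
) -> BootstrapResult:
    """Nonparametric bootstrap of the population fit.

    Each replicate resamples animals with replacement (stratified by arm),
    refits the model starting from the original point estimates, and the
    per-parameter medians and 5th-95th percentiles are reported.  Replicates
    whose refit does not converge are excluded and counted; the result is
    flagged when more than 20% fail.
    """
    for arm in ("clozapine", "norclozapine"):
        ids = dataset.df.loc[dataset.df["ARM"] == arm, "ID"].nunique()
        if 0 < ids < 2:
            raise ValueError(f"bootstrap requires >= 2 subjects in arm {arm!r}")
    method = method or fit.method
    rng = np.random.default_rng(seed)
    estimates: list[dict[str, float]] = []
    n_failed = 0
    for r in range(n_replicates):
        rep = resample_subjects(dataset, rng)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                refit = fit_population(
                    rep,
                    fit.fixed_effects,
                    fit.random_effects,
                    fit.residual,
                    structure=fit.structure,
                    method=method,
                    maxiter=maxiter,
                    prefit_pooled=False,
                )
        except Exception:
            n_failed += 1
            continue
        if not math.isfinite(refit.ofv):
            n_failed += 1
            continue
        rec = refit.fixed_effects.to_dict()
        rec.update({f"omega_{k}": v for k, v in refit.random_effects.omegas.items()})
        rec.update({f"sigma_{k}": v for k, v in refit.residual.sigmas.items()})
        estimates.append(rec)

    point = fit.fixed_effects.to_dict()
    point.update({f"omega_{k}": v for k, v in fit.random_effects.omegas.items()})
    point.update({f"sigma_{k}": v for k, v in fit.residual.sigmas.items()})
    rows = []
    for name, value in point.items():
        values = np.array([e[name] for e in estimates]) if estimates else np.array([np.nan])
        p5, p50, p95 = np.percentile(values, [5, 50, 95])
        rows.append(dict(parameter=name, estimate=value, median=p50, p5=p5, p95=p95))
    return BootstrapResult(
        table=pd.DataFrame(rows),
        n_replicates=n_replicates,
        n_failed=n_failed,
        flagged=n_failed > 0.2 * n_replicates,
    )
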