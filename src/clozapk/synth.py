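"""Synthetic rat-study generator replicating the microdialysis study design.

Two arms: clozapine 10 mg/kg SC in 4 rats (0.35 kg mean weight) and
norclozapine 10 mg/kg SC in 5 rats (0.34 kg).  Plasma is sampled at 9
timepoints (0-480 min) and brain ECF at 18 timepoints (-30 to 480 min, every
30 min).  Between-animal variability is log-normal (exponential model) and
residual error is proportional per observation channel.  Norclozapine in
brain ECF is not measurable after clozapine dosing, so that channel is
emitted below-quantification-flagged in the clozapine arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .dataset import ARM_CHANNELS, QUANTIFIABLE_CHANNELS, StudyDataset
from .model import DoseEvent, predict_concentrations
from .parameters import (
    CHANNELS,
    REFERENCE_RANDOM_EFFECTS,
    REFERENCE_RAT_ESTIMATES,
    REFERENCE_RESIDUALS,
    FixedEffects,
    ModelStructureConfig,
    RandomEffectSpec,
    ResidualSpec,
    individual_parameters,
)

__all__ = [
    "ArmDesign",
    "StudyDesign",
    "GeneratorConfig",
    "default_rat_design",
    "scale_design",
    "generate_study",
    "draw_etas",
    "design_from_dataset",
]

PLASMA_TIMES = (0.0, 15.0, 30.0, 60.0, 90.0, 120.0, 240.0, 360.0, 480.0)
BRAIN_TIMES = tuple(float(t) for t in range(-30, 481, 30))

#: Sampling schedule per channel: plasma channels follow the plasma schedule,
#: brain channels the brain schedule.
_CHANNEL_SCHEDULE = {
    "parent_plasma": PLASMA_TIMES,
    "metabolite_plasma": PLASMA_TIMES,
    "parent_brain": BRAIN_TIMES,
    "metabolite_brain": BRAIN_TIMES,
}


@dataclass(frozen=True)
class ArmDesign:
    compound: str  # "clozapine" or "norclozapine"
    n_animals: int
    body_weight_kg: float
    dose_mg_per_kg: float = 10.0
    plasma_times: tuple[float, ...] = PLASMA_TIMES
    brain_times: tuple[float, ...] = BRAIN_TIMES
    weight_spread: float = 0.0  # half-width of uniform relative spread

    def __post_init__(self) -> None:
        if self.compound not in ("clozapine", "norclozapine"):
            raise ValueError(f"unknown compound {self.compound!r}")
        if self.n_animals < 1:
            raise ValueError("n_animals must be >= 1")
        if self.body_weight_kg <= 0 or self.dose_mg_per_kg < 0:
            raise ValueError("weights must be positive and dose non-negative")
        for times in (self.plasma_times, self.brain_times):
            if list(times) != sorted(times):
                raise ValueError("sampling times must be sorted")

    @property
    def channels(self) -> tuple[str, ...]:
        return ARM_CHANNELS[self.compound]


@dataclass(frozen=True)
class StudyDesign:
    arms: tuple[ArmDesign, ...]


def default_rat_design() -> StudyDesign:
    """The two-arm rat study design: 4 clozapine + 5 norclozapine animals."""
    return StudyDesign(
        arms=(
            ArmDesign(compound="clozapine", n_animals=4, body_weight_kg=0.35),
            ArmDesign(compound="norclozapine", n_animals=5, body_weight_kg=0.34),
        )
    )


def scale_design(design: StudyDesign, n_per_arm: int) -> StudyDesign:
    """Replace animal counts, preserving schedules and doses (recovery studies)."""
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    return StudyDesign(arms=tuple(replace(a, n_animals=n_per_arm) for a in design.arms))


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating truth and stochastic settings for synthetic studies."""

    fixed: FixedEffects = REFERENCE_RAT_ESTIMATES
    random_effects: RandomEffectSpec = REFERENCE_RANDOM_EFFECTS
    residual: ResidualSpec = REFERENCE_RESIDUALS
    structure: ModelStructureConfig = field(default_factory=ModelStructureConfig)
    seed: int = 0
    include_bav: bool = True
    include_residual: bool = True


def draw_etas(config: GeneratorConfig, n: int, rng: np.random.Generator) -> list[dict[str, float]]:
    """Draw per-animal random effects (one dict per animal, in varying-parameter order)."""
    varying = config.random_effects.varying
    out = []
    for _ in range(n):
        if config.include_bav:
            out.append(
                {p: rng.normal(0.0, config.random_effects.omega(p)) for p in varying}
            )
        else:
            out.append({p: 0.0 for p in varying})
    return out


def _proportional_noise(rng: np.random.Generator, sigma: float) -> float:
    """Draw 1 + sigma*eps, redrawing the rare (>9 sigma at study noise levels)
    realizations that would yield a non-positive concentration."""
    for _ in range(1000):
        factor = 1.0 + sigma * rng.normal()
        if factor > 0:
            return factor
    warnings.warn("proportional-noise redraw limit reached; clamping to zero")
    return 0.0


def generate_study(design: StudyDesign, config: GeneratorConfig) -> StudyDataset:
    """Simulate a full study dataset under the design and generating truth."""
    rng = np.random.default_rng(config.seed)
    rows = []
    sid = 0
    for arm in design.arms:
        etas = draw_etas(config, arm.n_animals, rng)
        route = "sc_parent" if arm.compound == "clozapine" else "sc_metabolite"
        for k in range(arm.n_animals):
            sid += 1
            weight = arm.body_weight_kg
            if arm.weight_spread > 0:
                weight *= 1.0 + arm.weight_spread * rng.uniform(-1.0, 1.0)
            amount = arm.dose_mg_per_kg * weight
            params_i = individual_parameters(config.fixed, etas[k])
            dose = DoseEvent(time=0.0, amount=amount, route=route, subject=sid)
            rows.append(
                dict(ID=sid, ARM=arm.compound, WT=weight, TIME=0.0, EVID=1,
                     AMT=amount, DV=np.nan, CHANNEL="", BQL=0)
            )
            schedule: list[tuple[str, float]] = []
            for ch in arm.channels:
                times = arm.plasma_times if ch.endswith("plasma") else arm.brain_times
                schedule += [(ch, t) for t in times]
            post_times = np.array(sorted({t for _, t in schedule if t > 0}))
            pred = predict_concentrations(params_i, config.structure, [dose], post_times)
            tpos = {t: j for j, t in enumerate(post_times)}
            for ch, t in schedule:
                bql = 1 if ch not in QUANTIFIABLE_CHANNELS[arm.compound] else 0
                if t <= 0:
                    dv = 0.0
                elif bql:
                    dv = np.nan
                else:
                    f = pred[CHANNELS.index(ch), tpos[t]]
                    if config.include_residual:
                        f *= _proportional_noise(rng, config.residual.sigma(ch))
                    dv = f
                rows.append(
                    dict(ID=sid, ARM=arm.compound, WT=weight, TIME=float(t), EVID=0,
                         AMT=0.0, DV=dv, CHANNEL=ch, BQL=bql)
                )
    return StudyDataset(pd.DataFrame(rows))


def design_from_dataset(dataset: StudyDataset) -> StudyDesign:
    """Recover the sampling design (arms, counts, weights, schedules) from a dataset."""
    arms = []
    df = dataset.df
    for compound in ("clozapine", "norclozapine"):
        sub = df[df["ARM"] == compound]
        if sub.empty:
            continue
        n = sub["ID"].nunique()
        weight = float(sub["WT"].mean())
        doses = sub[sub["EVID"] == 1]
        dose_per_kg = float((doses["AMT"] / doses["WT"]).mean())
        obs = sub[sub["EVID"] == 0]
        plasma_ch = "parent_plasma" if compound == "clozapine" else "metabolite_plasma"
        brain_ch = "parent_brain" if compound == "clozapine" else "metabolite_brain"
        plasma_times = tuple(sorted(obs.loc[obs["CHANNEL"] == plasma_ch, "TIME"].unique()))
        brain_times = tuple(sorted(obs.loc[obs["CHANNEL"] == brain_ch, "TIME"].unique()))
        arms.append(
            ArmDesign(
                compound=compound,
                n_animals=n,
                body_weight_kg=weight,
                dose_mg_per_kg=dose_per_kg,
                plasma_times=plasma_times or PLASMA_TIMES,
                brain_times=brain_times or BRAIN_TIMES,
            )
        )
    if not arms:
        raise ValueError("dataset contains no recognised arm")
    return StudyDesign(arms=tuple(arms))
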