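"""Structural parameters and variability specifications.

The model describes clozapine (parent) and norclozapine (its N-desmethyl
metabolite) in plasma and brain extracellular fluid (ECF).  Each compound has
a first-order absorption depot, a plasma compartment, a chain of transit
compartments carrying drug from plasma into brain ECF (the blood-brain-barrier
delay), and a brain ECF compartment returning drug to plasma through an
intercompartmental clearance.  Clozapine is eliminated both directly and by
conversion to norclozapine.

Units are fixed throughout the package: amounts in mg, volumes in L, time in
minutes, concentrations in mg/L.  Clearances and volumes are *apparent*
(confounded with bioavailability F under extravascular dosing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Mapping

__all__ = [
    "CHANNELS",
    "FixedEffects",
    "ModelStructureConfig",
    "RandomEffectSpec",
    "ResidualSpec",
    "individual_parameters",
    "REFERENCE_RAT_ESTIMATES",
    "REFERENCE_RANDOM_EFFECTS",
    "REFERENCE_RESIDUALS",
    "DEFAULT_FIXED_PARAMETERS",
]

#: Observation channels, in canonical order.
CHANNELS = ("parent_plasma", "parent_brain", "metabolite_plasma", "metabolite_brain")

#: Fixed-effect names whose value only influences the metabolite sub-system.
METABOLITE_PARAMETERS = frozenset(
    {"cl_met", "v_met_p", "ka_met", "q_met", "v_met_b", "ktr2", "f_met"}
)


@dataclass(frozen=True)
class FixedEffects:
    """Population typical values of the structural model.

    Parameters
    ----------
    cl_clo : float
        Clozapine non-metabolic apparent clearance CL_clo/F (L/min).
    v_clo_p : float
        Clozapine apparent plasma volume V_clo-p/F (L).
    ka_clo : float
        Clozapine first-order absorption rate constant (1/min).
    q_clo : float
        Clozapine brain-to-plasma intercompartmental clearance Q_clo/F (L/min).
    v_clo_b : float
        Clozapine apparent brain-ECF volume V_clo-b/F (L).
    ktr1 : float
        Clozapine plasma-to-brain transit rate constant (1/min).
    f_clo : float
        Clozapine bioavailability fraction (dimensionless, typical value 1).
    cl_clo_met : float
        Clearance of clozapine by conversion to norclozapine CL_clo-met/F (L/min).
    cl_met : float
        Norclozapine apparent clearance CL_met/F (L/min).
    v_met_p : float
        Norclozapine apparent plasma volume V_met-p/F (L).
    ka_met : float
        Norclozapine absorption rate constant (1/min).
    q_met : float
        Norclozapine brain-to-plasma intercompartmental clearance Q_met/F (L/min).
    v_met_b : float
        Norclozapine apparent brain-ECF volume V_met-b/F (L).
    ktr2 : float
        Norclozapine transit rate constant (1/min).
    f_met : float
        Norclozapine bioavailability fraction (dimensionless, typical value 1).
    """

    cl_clo: float
    v_clo_p: float
    ka_clo: float
    q_clo: float
    v_clo_b: float
    ktr1: float
    f_clo: float
    cl_clo_met: float
    cl_met: float
    v_met_p: float
    ka_met: float
    q_met: float
    v_met_b: float
    ktr2: float
    f_met: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ValueError(f"parameter {f.name!r} must be finite, got {value!r}")
            if value <= 0:
                raise ValueError(f"parameter {f.name!r} must be strictly positive, got {value!r}")

    @classmethod
    def parameter_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))

    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, values: Mapping[str, float]) -> "FixedEffects":
        return cls(**{k: float(v) for k, v in values.items()})

    def replace(self, **changes: float) -> "FixedEffects":
        return replace(self, **changes)


def individual_parameters(fixed: FixedEffects, etas: Mapping[str, float]) -> FixedEffects:
    """Apply log-normal between-animal random effects: P_i = P_TV * exp(eta).

    ``etas`` maps parameter names to individual deviations; parameters not
    listed pass through unchanged.  Non-finite etas are rejected with a
    diagnostic naming the parameter.
    """
    if not etas:
        return fixed
    names = set(FixedEffects.parameter_names())
    changes: dict[str, float] = {}
    for name, eta in etas.items():
        if name not in names:
            raise ValueError(f"unknown parameter {name!r} in eta map")
        if not math.isfinite(eta):
            raise ValueError(f"non-finite eta for parameter {name!r}: {eta!r}")
        if eta != 0.0:
            changes[name] = getattr(fixed, name) * math.exp(eta)
    return replace(fixed, **changes) if changes else fixed


def _individual_unchecked(
    fixed: FixedEffects, names: Iterable[str], etas: Iterable[float]
) -> FixedEffects:
    """Validation-free variant of :func:`individual_parameters` (hot path).

    Callers guarantee finite etas and known names.
    """
    values = dict(fixed.__dict__)
    for name, eta in zip(names, etas):
        values[name] = values[name] * math.exp(eta)
    obj = object.__new__(FixedEffects)
    obj.__dict__.update(values)
    return obj


@dataclass(frozen=True)
class ModelStructureConfig:
    """Number of plasma-to-brain transit compartments and optional lag times.

    Defaults reproduce the final rat model: two transit compartments for
    clozapine, one for norclozapine, no lag times.
    """

    n_transit_parent: int = 2
    n_transit_metabolite: int = 1
    lag_time_parent: float = 0.0
    lag_time_metabolite: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_transit_parent", "n_transit_metabolite"):
            n = getattr(self, name)
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {n!r}")
        for name in ("lag_time_parent", "lag_time_metabolite"):
            lag = getattr(self, name)
            if not (math.isfinite(lag) and lag >= 0):
                raise ValueError(f"{name} must be a finite non-negative time, got {lag!r}")


@dataclass(frozen=True)
class RandomEffectSpec:
    """Diagonal between-animal variability: omega is the SD of eta per parameter."""

    omegas: Mapping[str, float]

    def __post_init__(self) -> None:
        names = set(FixedEffects.parameter_names())
        clean = {}
        for name, omega in dict(self.omegas).items():
            if name not in names:
                raise ValueError(f"unknown parameter {name!r} in RandomEffectSpec")
            if not (math.isfinite(omega) and omega >= 0):
                raise ValueError(f"omega for {name!r} must be finite and >= 0, got {omega!r}")
            clean[name] = float(omega)
        object.__setattr__(self, "omegas", clean)

    @property
    def varying(self) -> tuple[str, ...]:
        """Parameters with strictly positive variability, in FixedEffects order."""
        return tuple(n for n in FixedEffects.parameter_names() if self.omegas.get(n, 0.0) > 0.0)

    def omega(self, name: str) -> float:
        return self.omegas.get(name, 0.0)


@dataclass(frozen=True)
class ResidualSpec:
    """Channel-specific proportional residual error: DV = pred * (1 + sigma * eps)."""

    sigmas: Mapping[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for channel, sigma in dict(self.sigmas).items():
            if channel not in CHANNELS:
                raise ValueError(f"unknown channel {channel!r} in ResidualSpec")
            if not (math.isfinite(sigma) and sigma > 0):
                raise ValueError(f"sigma for {channel!r} must be finite and > 0, got {sigma!r}")
            clean[channel] = float(sigma)
        object.__setattr__(self, "sigmas", clean)

    def sigma(self, channel: str) -> float:
        try:
            return self.sigmas[channel]
        except KeyError:
            raise KeyError(f"no residual sigma defined for channel {channel!r}") from None


# Final population estimates from the rat clozapine/norclozapine microdialysis
# study; the package's default generating truth for synthetic studies.
REFERENCE_RAT_ESTIMATES = FixedEffects(
    cl_clo=0.5,
    v_clo_p=19.4,
    ka_clo=0.00801,
    q_clo=2.01,
    v_clo_b=0.214,
    ktr1=0.0125,
    f_clo=1.0,
    cl_clo_met=0.055,
    cl_met=0.419,
    v_met_p=2.95,
    ka_met=0.00277,
    q_met=0.388,
    v_met_b=0.25,
    ktr2=0.00517,
    f_met=1.0,
)

# Between-animal variability (SD of eta) of the final rat model.
REFERENCE_RANDOM_EFFECTS = RandomEffectSpec(
    omegas={
        "q_clo": 0.193,
        "ktr1": 0.05,
        "f_clo": 0.259,
        "cl_met": 0.111,
        "v_met_p": 0.168,
        "ka_met": 0.371,
    }
)

# Proportional residual error SD per observation channel of the final rat model.
REFERENCE_RESIDUALS = ResidualSpec(
    sigmas={
        "parent_plasma": 0.109,
        "parent_brain": 0.0367,
        "metabolite_plasma": 0.0762,
        "metabolite_brain": 0.014,
    }
)

#: Fixed effects held fixed (not estimated) in the final rat model: the brain
#: ECF volumes (literature values) and both bioavailability fractions.
DEFAULT_FIXED_PARAMETERS = frozenset({"v_clo_b", "v_met_b", "f_clo", "f_met"})
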