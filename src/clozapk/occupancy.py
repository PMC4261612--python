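"""Receptor-occupancy prediction from simulated brain-ECF concentrations.

Occupancy follows the single-site law of mass action,
``occupancy% = 100 * C / (C + Kd)``, applied to unbound brain-ECF
concentrations converted to nM.  Clozapine occupancy is predicted at D2,
5-HT2A, M1, alpha-1, alpha-2 and H1; norclozapine at D2 only.  Dissociation
constants are literature values and must be supplied as configuration with a
provenance tag; no numeric defaults ship with the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .translation import HumanSimulation

__all__ = [
    "Receptor",
    "ReceptorPanel",
    "OccupancyProfile",
    "mass_to_molar",
    "molar_to_mass",
    "occupancy_fraction",
    "occupancy_time_course",
    "RECEPTOR_NAMES",
    "DEFAULT_MOLECULAR_WEIGHTS",
]

RECEPTOR_NAMES = ("D2", "5HT2A", "M1", "alpha1", "alpha2", "H1")
COMPOUNDS = ("clozapine", "norclozapine")

#: Molecular weights (g/mol) used to convert mg/L to nM.
DEFAULT_MOLECULAR_WEIGHTS = {"clozapine": 326.8, "norclozapine": 312.8}

_COMPOUND_CHANNEL = {"clozapine": "parent_brain", "norclozapine": "metabolite_brain"}


@dataclass(frozen=True)
class Receptor:
    """One receptor/compound pair with its dissociation constant.

    ``kd_nm`` is the equilibrium dissociation constant in nM, the unbound
    concentration giving 50% occupancy.  ``reference`` records where the
    value came from and is required (these are literature constants).
    """

    name: str
    compound: str
    kd_nm: float
    reference: str

    def __post_init__(self) -> None:
        if self.name not in RECEPTOR_NAMES:
            raise ValueError(f"unknown receptor {self.name!r}; expected {RECEPTOR_NAMES}")
        if self.compound not in COMPOUNDS:
            raise ValueError(f"unknown compound {self.compound!r}")
        if not (math.isfinite(self.kd_nm) and self.kd_nm > 0):
            raise ValueError(f"Kd must be finite and > 0, got {self.kd_nm!r}")
        if not self.reference:
            raise ValueError("a provenance reference tag is required for each Kd")


@dataclass(frozen=True)
class ReceptorPanel:
    """Receptor panel with compound molecular weights.

    By default the norclozapine panel is restricted to D2 (the only receptor
    with a published norclozapine dissociation constant in this workflow);
    pass ``allow_extended=True`` to lift the restriction.
    """

    receptors: tuple[Receptor, ...]
    molecular_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MOLECULAR_WEIGHTS)
    )
    allow_extended: bool = False

    def __post_init__(self) -> None:
        for compound, mw in self.molecular_weights.items():
            if compound not in COMPOUNDS:
                raise ValueError(f"unknown compound {compound!r}")
            if not (math.isfinite(mw) and mw > 0):
                raise ValueError(f"molecular weight for {compound!r} must be > 0")
        if not self.allow_extended:
            for r in self.receptors:
                if r.compound == "norclozapine" and r.name != "D2":
                    raise ValueError(
                        "norclozapine panel is restricted to D2 by default; "
                        "set allow_extended=True to override"
                    )

    def kd(self, name: str, compound: str) -> float:
        for r in self.receptors:
            if r.name == name and r.compound == compound:
                return r.kd_nm
        raise KeyError(f"no Kd in panel for receptor {name!r} / {compound!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReceptorPanel":
        receptors = tuple(Receptor(**r) for r in d["receptors"])
        mw = dict(DEFAULT_MOLECULAR_WEIGHTS)
        mw.update(d.get("molecular_weights", {}))
        return cls(
            receptors=receptors,
            molecular_weights=mw,
            allow_extended=bool(d.get("allow_extended", False)),
        )


def mass_to_molar(concentration_mg_per_l, molecular_weight: float):
    """mg/L to nM: c * 1e6 / MW."""
    if not molecular_weight > 0:
        raise ValueError("molecular weight must be strictly positive")
    return concentration_mg_per_l * 1e6 / molecular_weight


def molar_to_mass(concentration_nm, molecular_weight: float):
    """nM to mg/L: c * MW / 1e6."""
    if not molecular_weight > 0:
        raise ValueError("molecular weight must be strictly positive")
    return concentration_nm * molecular_weight / 1e6


def occupancy_fraction(unbound_nm, kd_nm: float):
    """Percent receptor occupancy under the law of mass action."""
    if kd_nm <= 0:
        raise ValueError("Kd must be strictly positive")
    c = np.asarray(unbound_nm, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = 100.0 * c / (c + kd_nm)
    return float(out) if np.isscalar(unbound_nm) or out.ndim == 0 else out


@dataclass(frozen=True)
class OccupancyProfile:
    """Median percent occupancy across the virtual population, with bands."""

    table: pd.DataFrame  # receptor, compound, dose_mg, time_h, median, p5, p95

    def median_series(self, receptor: str, compound: str, dose_mg: float) -> pd.DataFrame:
        t = self.table
        return t[
            (t["receptor"] == receptor)
            & (t["compound"] == compound)
            & (t["dose_mg"] == dose_mg)
        ].sort_values("time_h")


def occupancy_time_course(
    simulations: Mapping[float, HumanSimulation] | Sequence[HumanSimulation],
    panel: ReceptorPanel,
    receptors: Sequence[tuple[str, str]] | None = None,
    window_h: tuple[float, float] = (6.0, 24.0),
) -> OccupancyProfile:
    """Predicted occupancy time courses over the post-dose window.

    Occupancy is computed per virtual subject from its brain-ECF unbound
    concentration at each timepoint, then summarised by the median (and
    5th/95th percentiles) across subjects, separately per receptor and dose.
    """
    if not isinstance(simulations, Mapping):
        simulations = {sim.dose_mg: sim for sim in simulations}
    if receptors is None:
        receptors = [(r.name, r.compound) for r in panel.receptors]
    rows = []
    for name, compound in receptors:
        kd = panel.kd(name, compound)  # raises KeyError when absent
        mw = panel.molecular_weights[compound]
        channel = _COMPOUND_CHANNEL[compound]
        for dose, sim in sorted(simulations.items()):
            mask = (sim.times_h >= window_h[0]) & (sim.times_h <= window_h[1])
            times = sim.times_h[mask]
            conc_nm = mass_to_molar(sim.profiles[channel][:, mask], mw)
            occ = occupancy_fraction(conc_nm, kd)
            p5, p50, p95 = np.percentile(occ, [5, 50, 95], axis=0)
            for j, t in enumerate(times):
                rows.append(
                    dict(
                        receptor=name,
                        compound=compound,
                        dose_mg=float(dose),
                        time_h=float(t),
                        median=p50[j],
                        p5=p5[j],
                        p95=p95[j],
                    )
                )
    return OccupancyProfile(table=pd.DataFrame(rows))
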