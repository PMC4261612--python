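"""Long-format study dataset container and NONMEM-style CSV I/O.

Records carry one row per dosing event or observation:

====== =====================================================================
column meaning
====== =====================================================================
ID     subject (animal) identifier
ARM    study arm, ``clozapine`` or ``norclozapine`` (compound dosed)
WT     body weight, kg
TIME   minutes relative to dosing
EVID   1 for dose rows, 0 for observation rows
AMT    dose amount in mg (dose rows; 0 otherwise)
DV     observed unbound concentration, mg/L (observation rows)
CHANNEL observation channel (parent_plasma, parent_brain,
        metabolite_plasma, metabolite_brain); empty on dose rows
BQL    1 if the observation is below the quantification limit
====== =====================================================================
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import pandas as pd

from .parameters import CHANNELS

__all__ = ["StudyDataset", "read_dataset", "write_dataset", "COLUMNS", "ARMS"]

COLUMNS = ("ID", "ARM", "WT", "TIME", "EVID", "AMT", "DV", "CHANNEL", "BQL")
ARMS = ("clozapine", "norclozapine")

#: Channels that can carry quantifiable observations in each arm.  In the
#: clozapine arm, norclozapine in brain ECF was not measurable, so
#: metabolite_brain rows must be flagged below quantification there.
QUANTIFIABLE_CHANNELS = {
    "clozapine": ("parent_plasma", "parent_brain", "metabolite_plasma"),
    "norclozapine": ("metabolite_plasma", "metabolite_brain"),
}
ARM_CHANNELS = {
    "clozapine": ("parent_plasma", "parent_brain", "metabolite_plasma", "metabolite_brain"),
    "norclozapine": ("metabolite_plasma", "metabolite_brain"),
}


class DatasetValidationError(ValueError):
    """Raised when a study dataset violates the schema."""


@dataclass(frozen=True)
class StudyDataset:
    """Validated long-format two-arm rat study dataset."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        object.__setattr__(self, "df", _validate(self.df))

    @property
    def subjects(self) -> tuple:
        return tuple(self.df["ID"].unique())

    def subject_rows(self, sid) -> pd.DataFrame:
        return self.df[self.df["ID"] == sid]

    def arm_of(self, sid) -> str:
        return str(self.df.loc[self.df["ID"] == sid, "ARM"].iloc[0])

    def observations(self, include_bql: bool = False, include_predose: bool = False) -> pd.DataFrame:
        """Observation rows used for fitting (by default: post-dose, above BQL)."""
        obs = self.df[self.df["EVID"] == 0]
        if not include_bql:
            obs = obs[obs["BQL"] == 0]
        if not include_predose:
            obs = obs[obs["TIME"] > 0]
        return obs

    def doses(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 1]

    def n_observations(self, **kwargs) -> int:
        return len(self.observations(**kwargs))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing required column(s): {', '.join(missing)}")
    df = df.loc[:, list(COLUMNS)].reset_index(drop=True)

    for col in ("WT", "TIME", "AMT"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            raise DatasetValidationError(
                f"non-numeric {col} at row {int(bad.idxmax())}: {df[col][bad.idxmax()]!r}"
            )
        df[col] = vals
    dv = pd.to_numeric(df["DV"], errors="coerce")
    bad = dv.isna() & df["DV"].notna() & (df["DV"].astype(str).str.strip() != "")
    if bad.any():
        raise DatasetValidationError(
            f"non-numeric DV at row {int(bad.idxmax())}: {df['DV'][bad.idxmax()]!r}"
        )
    df["DV"] = dv
    df["EVID"] = pd.to_numeric(df["EVID"], errors="coerce").fillna(0).astype(int)
    df["BQL"] = pd.to_numeric(df["BQL"], errors="coerce").fillna(0).astype(int)
    df["CHANNEL"] = df["CHANNEL"].fillna("").astype(str)

    for i, row in df.iterrows():
        arm = row["ARM"]
        if arm not in ARMS:
            raise DatasetValidationError(f"unknown arm {arm!r} at row {i}")
        if row["EVID"] == 0:
            ch = row["CHANNEL"]
            if ch not in CHANNELS:
                raise DatasetValidationError(f"unknown channel {ch!r} at row {i}")
            if ch not in ARM_CHANNELS[arm]:
                raise DatasetValidationError(
                    f"channel {ch!r} inconsistent with arm {arm!r} at row {i}"
                )
            if ch not in QUANTIFIABLE_CHANNELS[arm] and row["BQL"] != 1:
                raise DatasetValidationError(
                    f"channel {ch!r} must be flagged below quantification in "
                    f"arm {arm!r} (row {i})"
                )

    for sid, grp in df.groupby("ID", sort=False):
        if (grp["EVID"] == 1).sum() < 1:
            raise DatasetValidationError(f"subject {sid!r} has no dose row")
    return df


def read_dataset(path: str | Path) -> StudyDataset:
    """Read and validate a NONMEM-style long-format CSV dataset."""
    df = pd.read_csv(path)
    return StudyDataset(df)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    dataset.df.to_csv(path, index=False)
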