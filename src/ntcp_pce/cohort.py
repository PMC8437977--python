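"""Patient records and cohorts: the unit of model fitting.

A :class:`PatientRecord` couples the mean heart dose (MHD), optional full
heart DVH, clinical covariates, and the two pericardial-effusion endpoints:
any-grade (A-PCE) and symptomatic, CTCAE grade >= 3 (S-PCE).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dvh import DoseVolumeHistogram, mean_dose
from .errors import ContractError, DegenerateDataError, MalformedInputError

#: Maximum tolerated disagreement between a record's mhd and its DVH mean, Gy.
MHD_DVH_TOL = 0.05

OUTCOMES = ("any", "symptomatic")


def _outcome_attr(outcome: str) -> str:
    if outcome not in OUTCOMES:
        raise ContractError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    return "outcome_any_grade" if outcome == "any" else "outcome_symptomatic"


@dataclass
class PatientRecord:
    patient_id: str
    mhd: float
    outcome_any_grade: int
    outcome_symptomatic: int
    covariates: dict[str, float] = field(default_factory=dict)
    dvh: DoseVolumeHistogram | None = None

    def __post_init__(self) -> None:
        if self.mhd < 0:
            raise MalformedInputError(f"{self.patient_id}: mhd must be >= 0")
        if "hypertension" not in self.covariates:
            raise MalformedInputError(
                f"{self.patient_id}: covariates must include 'hypertension'"
            )
        for o in (self.outcome_any_grade, self.outcome_symptomatic):
            if o not in (0, 1):
                raise MalformedInputError(f"{self.patient_id}: outcomes must be 0/1")
        if self.dvh is not None and abs(self.mhd - mean_dose(self.dvh)) > MHD_DVH_TOL:
            raise MalformedInputError(
                f"{self.patient_id}: mhd {self.mhd:.3f} Gy disagrees with "
                f"DVH mean {mean_dose(self.dvh):.3f} Gy by more than {MHD_DVH_TOL} Gy"
            )

    def outcome(self, outcome: str) -> int:
        return int(getattr(self, _outcome_attr(outcome)))


@dataclass
class Cohort:
    """Ordered collection of patients plus provenance metadata."""

    patients: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise MalformedInputError("patient_ids must be unique")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    @property
    def has_dvhs(self) -> bool:
        return all(p.dvh is not None for p in self.patients)

    def mhd_array(self) -> np.ndarray:
        return np.array([p.mhd for p in self.patients], dtype=float)

    def outcome_array(self, outcome: str) -> np.ndarray:
        attr = _outcome_attr(outcome)
        return np.array([getattr(p, attr) for p in self.patients], dtype=int)

    def feature_frame(self, features: Sequence[str]) -> pd.DataFrame:
        """Design matrix for the requested features; ``mhd`` resolves to the
        dose summary, anything else to a covariate."""
        cols = {}
        for f in features:
            if f == "mhd":
                cols[f] = self.mhd_array()
            else:
                try:
                    cols[f] = np.array(
                        [p.covariates[f] for p in self.patients], dtype=float
                    )
                except KeyError as exc:
                    raise ContractError(f"unknown feature {f!r}") from exc
        return pd.DataFrame(cols, index=[p.patient_id for p in self.patients])

    def require_fittable(self, outcome: str) -> None:
        y = self.outcome_array(outcome)
        if y.sum() == 0 or y.sum() == len(y):
            raise DegenerateDataError(
                f"cohort needs at least one event and one non-event for {outcome!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        covs = sorted({k for p in self.patients for k in p.covariates})
        rows = []
        for p in self.patients:
            row = {"patient_id": p.patient_id, "mhd": p.mhd}
            row.update({c: p.covariates.get(c, np.nan) for c in covs})
            row["outcome_any_grade"] = p.outcome_any_grade
            row["outcome_symptomatic"] = p.outcome_symptomatic
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n", float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path, metadata: dict | None = None) -> "Cohort":
        df = pd.read_csv(path)
        needed = {"patient_id", "mhd", "outcome_any_grade", "outcome_symptomatic"}
        if not needed.issubset(df.columns):
            raise MalformedInputError(f"cohort table must have columns {sorted(needed)}")
        cov_cols = [c for c in df.columns if c not in needed]
        patients = [
            PatientRecord(
                patient_id=str(row["patient_id"]),
                mhd=float(row["mhd"]),
                outcome_any_grade=int(row["outcome_any_grade"]),
                outcome_symptomatic=int(row["outcome_symptomatic"]),
                covariates={c: float(row[c]) for c in cov_cols},
            )
            for _, row in df.iterrows()
        ]
        return cls(patients, metadata=dict(metadata or {}))
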