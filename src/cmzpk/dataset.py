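"""Longitudinal PK dataset container and NONMEM-style CSV I/O.

The on-disk format is a rectangular CSV with the columns

    ID, TIME, AMT, RATE, DV, MDV, EVID, AGE, SEX, BW, SCR, CCR, STAGE, PROC, ALB

where dose rows have ``EVID = 1`` with ``AMT`` (mg) and ``RATE`` (mg/h, 0
for bolus) filled and ``DV`` empty, and observation rows have ``EVID = 0``
with ``DV`` (mg/L) filled and ``AMT`` empty.  ``SEX`` is 1 for male, 0 for
female; ``PROC`` is 1 for open surgery, 0 for laparoscopic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .pk_core import DoseEvent, Subject

__all__ = ["SubjectRecord", "PKDataset", "read_dataset", "write_dataset", "COLUMNS"]

COLUMNS = [
    "ID", "TIME", "AMT", "RATE", "DV", "MDV", "EVID",
    "AGE", "SEX", "BW", "SCR", "CCR", "STAGE", "PROC", "ALB",
]


@dataclass
class SubjectRecord:
    """One subject's covariates, dosing history and observations.

    ``individual_pk`` carries the true simulated (CL, Vd) when the record
    comes from the synthetic generator; it is None for real data and is
    never used by estimation.
    """

    subject: Subject
    doses: list[DoseEvent]
    times: np.ndarray
    conc: np.ndarray
    individual_pk: object = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.conc = np.asarray(self.conc, float)
        if self.times.shape != self.conc.shape:
            raise DataError("observation times and concentrations must align")
        self.doses = sorted(self.doses, key=lambda d: d.time)

    @property
    def n_obs(self) -> int:
        return int(self.times.size)


@dataclass
class PackedData:
    """Padded per-subject arrays for vectorized likelihood evaluation."""

    ids: list
    obs_t: np.ndarray      # (n, max_obs)
    obs_y: np.ndarray      # (n, max_obs)
    obs_mask: np.ndarray   # (n, max_obs) bool
    dose_t: np.ndarray     # (n, max_dose)
    dose_amt: np.ndarray   # (n, max_dose)
    dose_dur: np.ndarray   # (n, max_dose)
    dose_mask: np.ndarray  # (n, max_dose) bool
    covariates: dict = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.obs_mask.sum())


class PKDataset:
    """An ordered collection of :class:`SubjectRecord`."""

    def __init__(self, records: Iterable[SubjectRecord]):
        self.records = list(records)
        if not self.records:
            raise DataError("dataset must contain at least one subject")
        ids = [r.subject.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DataError("subject IDs must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n_observations(self) -> int:
        return sum(r.n_obs for r in self.records)

    @property
    def subjects(self) -> list[Subject]:
        return [r.subject for r in self.records]

    def resample(self, indices: Sequence[int]) -> "PKDataset":
        """New dataset from subject indices (with repeats re-identified)."""
        recs = []
        for new_id, i in enumerate(indices, start=1):
            r = self.records[i]
            subj = Subject(
                id=new_id,
                age=r.subject.age,
                sex=r.subject.sex,
                body_weight=r.subject.body_weight,
                serum_creatinine=r.subject.serum_creatinine,
                creatinine_clearance=r.subject.creatinine_clearance,
                stage=r.subject.stage,
                procedure=r.subject.procedure,
                albumin=r.subject.albumin,
            )
            recs.append(SubjectRecord(subj, list(r.doses), r.times.copy(),
                                      r.conc.copy(), r.individual_pk))
        return PKDataset(recs)

    # -- packed representation -------------------------------------------
    def packed(self) -> PackedData:
        n = len(self.records)
        max_o = max(r.n_obs for r in self.records)
        max_d = max(len(r.doses) for r in self.records)
        obs_t = np.zeros((n, max_o))
        obs_y = np.ones((n, max_o))
        obs_mask = np.zeros((n, max_o), bool)
        dose_t = np.zeros((n, max_d))
        dose_amt = np.ones((n, max_d))
        dose_dur = np.zeros((n, max_d))
        dose_mask = np.zeros((n, max_d), bool)
        for i, r in enumerate(self.records):
            m, d = r.n_obs, len(r.doses)
            obs_t[i, :m] = r.times
            obs_y[i, :m] = r.conc
            obs_mask[i, :m] = True
            dose_t[i, :d] = [x.time for x in r.doses]
            dose_amt[i, :d] = [x.amount for x in r.doses]
            dose_dur[i, :d] = [x.infusion_duration for x in r.doses]
            dose_mask[i, :d] = True
        cov = {
            "age": np.array([r.subject.age for r in self.records], float),
            "bw": np.array([r.subject.body_weight for r in self.records], float),
            "scr": np.array([r.subject.serum_creatinine for r in self.records], float),
            "ccr": np.array([r.subject.creatinine_clearance for r in self.records], float),
            "alb": np.array([r.subject.albumin for r in self.records], float),
            "sex_male": np.array([1.0 if r.subject.sex == "male" else 0.0 for r in self.records]),
            "procedure_open": np.array(
                [1.0 if r.subject.procedure == "open" else 0.0 for r in self.records]
            ),
            "stage": np.array([float(r.subject.stage) for r in self.records]),
        }
        cov["inv_scr"] = 1.0 / cov["scr"]
        cov["stage_score"] = 1.0 + (4.0 - cov["stage"])
        return PackedData(
            ids=[r.subject.id for r in self.records],
            obs_t=obs_t, obs_y=obs_y, obs_mask=obs_mask,
            dose_t=dose_t, dose_amt=dose_amt, dose_dur=dose_dur, dose_mask=dose_mask,
            covariates=cov,
        )

    # -- frame round-trip ------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            s = r.subject
            base = {
                "ID": s.id,
                "AGE": s.age,
                "SEX": 1 if s.sex == "male" else 0,
                "BW": s.body_weight,
                "SCR": s.serum_creatinine,
                "CCR": s.creatinine_clearance,
                "STAGE": int(s.stage),
                "PROC": 1 if s.procedure == "open" else 0,
                "ALB": s.albumin,
            }
            for d in r.doses:
                rate = d.amount / d.infusion_duration if d.infusion_duration > 0 else 0.0
                rows.append({**base, "TIME": d.time, "AMT": d.amount, "RATE": rate,
                             "DV": np.nan, "MDV": 1, "EVID": 1})
            for t, y in zip(r.times, r.conc):
                rows.append({**base, "TIME": t, "AMT": np.nan, "RATE": np.nan,
                             "DV": y, "MDV": 0, "EVID": 0})
        frame = pd.DataFrame(rows, columns=COLUMNS)
        return frame.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                                 kind="stable").reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PKDataset":
        missing = [c for c in COLUMNS if c not in frame.columns]
        if missing:
            raise DataError(f"missing mandatory column(s): {', '.join(missing)}")
        if (frame["TIME"] < 0).any():
            row = int(frame.index[frame["TIME"] < 0][0])
            raise DataError(f"negative TIME at row {row}")
        dup = frame.duplicated(subset=["ID", "TIME", "EVID"])
        if dup.any():
            row = int(frame.index[dup][0])
            raise DataError(f"duplicate (ID, TIME, EVID) at row {row}")
        records = []
        for sid, grp in frame.groupby("ID", sort=True):
            grp = grp.sort_values(["TIME", "EVID"], ascending=[True, False], kind="stable")
            first = grp.iloc[0]
            subj = Subject(
                id=sid,
                age=float(first["AGE"]),
                sex="male" if int(first["SEX"]) == 1 else "female",
                body_weight=float(first["BW"]),
                serum_creatinine=float(first["SCR"]),
                creatinine_clearance=float(first["CCR"]),
                stage=int(first["STAGE"]),
                procedure="open" if int(first["PROC"]) == 1 else "laparoscopic",
                albumin=float(first["ALB"]),
            )
            doses, times, conc = [], [], []
            first_dose_time = None
            for _, row in grp.iterrows():
                if int(row["EVID"]) == 1:
                    rate = float(row["RATE"]) if pd.notna(row["RATE"]) else 0.0
                    amt = float(row["AMT"])
                    dur = amt / rate if rate > 0 else 0.0
                    doses.append(DoseEvent(float(row["TIME"]), amt, dur))
                    if first_dose_time is None:
                        first_dose_time = float(row["TIME"])
                else:
                    if first_dose_time is None:
                        warnings.warn(
                            f"subject {sid}: observation at t={row['TIME']} precedes "
                            "any dose; row retained",
                            stacklevel=2,
                        )
                    times.append(float(row["TIME"]))
                    conc.append(float(row["DV"]))
            if not doses:
                raise DataError(f"subject {sid} has no dose record")
            records.append(SubjectRecord(subj, doses, np.array(times), np.array(conc)))
        return cls(records)


def read_dataset(path) -> PKDataset:
    """Read a NONMEM-style rectangular CSV (see module docstring)."""
    frame = pd.read_csv(path)
    return PKDataset.from_frame(frame)


def write_dataset(dataset: PKDataset, path) -> None:
    """Write the dataset as a NONMEM-style rectangular CSV."""
    dataset.to_frame().to_csv(path, index=False)
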