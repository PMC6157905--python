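"""Longitudinal cohort container and long-format CSV I/O.

A cohort is a list of subjects, each with an ordered visit list carrying a
visit month, clinical scores (MMSE in [0, 30], ADAS-13 in [0, 85]) and an
optional cortical-thickness vector of one mean thickness per atlas region
(78 regions by default, AAL-style). Scores and thickness cells may be
missing; missingness is encoded as empty CSV cells, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Default number of atlas regions per cortical-thickness vector.
DEFAULT_ATLAS_SIZE = 78

#: Valid score ranges per assessment scale. MMSE decreases with worsening
#: cognition; ADAS-13 increases.
SCALE_RANGES: dict[str, tuple[float, float]] = {
    "mmse": (0.0, 30.0),
    "adas13": (0.0, 85.0),
}

#: Scales on which a *higher* score means worse cognition.
INCREASING_SEVERITY_SCALES = frozenset({"adas13"})

VALID_SEX = frozenset({"M", "F"})
VALID_DIAGNOSES = frozenset({"CN", "SMC", "EMCI", "LMCI", "MCI", "AD"})


class CohortValidationError(ValueError):
    """Raised when a cohort table or record violates an invariant."""


@dataclass
class VisitRecord:
    """One subject-visit: month since baseline plus measurements."""

    month: int
    mmse: Optional[float] = None
    adas13: Optional[float] = None
    ct: Optional[np.ndarray] = None  # (n_rois,) mean thickness, mm

    def score(self, scale: str) -> Optional[float]:
        if scale not in SCALE_RANGES:
            raise CohortValidationError(f"unknown scale {scale!r}")
        return getattr(self, scale)

    def validate(self, atlas_size: int = DEFAULT_ATLAS_SIZE, where: str = "") -> None:
        if self.month < 0:
            raise CohortValidationError(f"{where}: month {self.month} < 0")
        for scale, (lo, hi) in SCALE_RANGES.items():
            v = getattr(self, scale)
            if v is not None and not (lo <= v <= hi):
                raise CohortValidationError(
                    f"{where}: {scale}={v} outside [{lo}, {hi}]"
                )
        if self.ct is not None:
            if len(self.ct) != atlas_size:
                raise CohortValidationError(
                    f"{where}: ct vector has {len(self.ct)} values, expected {atlas_size}"
                )
            if not np.all(np.asarray(self.ct) > 0):
                raise CohortValidationError(f"{where}: ct values must be > 0 mm")


@dataclass
class SubjectRecord:
    """A subject's demographics, APOE4 allele count, and ordered visits."""

    subject_id: str
    age: float
    sex: str
    apoe4: int
    diagnosis: str
    cohort: str
    visits: list[VisitRecord] = field(default_factory=list)

    def validate(self, atlas_size: int = DEFAULT_ATLAS_SIZE) -> None:
        sid = self.subject_id
        if self.apoe4 not in (0, 1, 2):
            raise CohortValidationError(f"subject {sid}: apoe4={self.apoe4} not in {{0,1,2}}")
        if self.sex not in VALID_SEX:
            raise CohortValidationError(f"subject {sid}: sex={self.sex!r}")
        if not self.visits:
            raise CohortValidationError(f"subject {sid}: no visits")
        if self.visits[0].month != 0:
            raise CohortValidationError(
                f"subject {sid}: first visit month is {self.visits[0].month}, baseline month 0 required"
            )
        months = [v.month for v in self.visits]
        if any(b <= a for a, b in zip(months, months[1:])):
            raise CohortValidationError(f"subject {sid}: visit months {months} not strictly increasing")
        for v in self.visits:
            v.validate(atlas_size, where=f"subject {sid} month {v.month}")

    def scored_months(self, scale: str) -> list[int]:
        """Months of visits with a non-missing score on *scale*."""
        return [v.month for v in self.visits if v.score(scale) is not None]

    def baseline(self) -> VisitRecord:
        return self.visits[0]


@dataclass
class Cohort:
    """The canonical in-memory cohort all pipeline stages consume."""

    subjects: list[SubjectRecord]
    roi_names: list[str] = field(default_factory=lambda: default_roi_names(DEFAULT_ATLAS_SIZE))
    scale_ranges: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(SCALE_RANGES))

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortValidationError(f"duplicate subject ids: {dup}")

    @property
    def atlas_size(self) -> int:
        return len(self.roi_names)

    def validate(self) -> None:
        for s in self.subjects:
            s.validate(self.atlas_size)

    def __len__(self) -> int:
        return len(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def default_roi_names(n: int) -> list[str]:
    return [f"roi_{i + 1}" for i in range(n)]


def _ct_columns(atlas_size: int) -> list[str]:
    return [f"ct_{i + 1}" for i in range(atlas_size)]


_BASE_COLUMNS = ["subject_id", "month", "age", "sex", "apoe4", "diagnosis", "cohort", "mmse", "adas13"]


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Long-format DataFrame view: one row per subject-visit."""
    ct_cols = _ct_columns(cohort.atlas_size)
    rows = []
    for s in cohort.subjects:
        for v in s.visits:
            row: dict[str, object] = {
                "subject_id": s.subject_id,
                "month": v.month,
                "age": s.age,
                "sex": s.sex,
                "apoe4": s.apoe4,
                "diagnosis": s.diagnosis,
                "cohort": s.cohort,
                "mmse": v.mmse,
                "adas13": v.adas13,
            }
            if v.ct is not None:
                row.update(zip(ct_cols, (float(x) for x in v.ct)))
            rows.append(row)
    return pd.DataFrame(rows, columns=_BASE_COLUMNS + ct_cols)


def frame_to_cohort(df: pd.DataFrame, atlas_size: int = DEFAULT_ATLAS_SIZE) -> Cohort:
    """Build and validate a Cohort from a long-format DataFrame."""
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    ct_cols = _ct_columns(atlas_size)
    present_ct = [c for c in df.columns if c.startswith("ct_")]
    if present_ct and sorted(present_ct) != sorted(ct_cols):
        raise CohortValidationError(
            f"ct columns do not match atlas size {atlas_size}: found {len(present_ct)} columns"
        )

    dup = df.duplicated(subset=["subject_id", "month"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortValidationError(
            f"row {i}: duplicate (subject_id, month) = "
            f"({df.iloc[i]['subject_id']!r}, {df.iloc[i]['month']})"
        )

    subjects = []
    for sid, g in df.groupby("subject_id", sort=False):
        g = g.sort_values("month")
        first = g.iloc[0]
        visits = []
        for _, r in g.iterrows():
            ct = None
            if present_ct:
                vals = r[ct_cols].to_numpy(dtype=float)
                if not np.all(np.isnan(vals)):
                    if np.any(np.isnan(vals)):
                        raise CohortValidationError(
                            f"subject {sid} month {int(r['month'])}: partially missing ct vector"
                        )
                    ct = vals
            visits.append(
                VisitRecord(
                    month=int(r["month"]),
                    mmse=None if pd.isna(r["mmse"]) else float(r["mmse"]),
                    adas13=None if pd.isna(r["adas13"]) else float(r["adas13"]),
                    ct=ct,
                )
            )
        apoe4_raw = first["apoe4"]
        if pd.isna(apoe4_raw) or float(apoe4_raw) != int(apoe4_raw):
            raise CohortValidationError(f"subject {sid}: apoe4 column must be an integer, got {apoe4_raw!r}")
        subjects.append(
            SubjectRecord(
                subject_id=str(sid),
                age=float(first["age"]),
                sex=str(first["sex"]),
                apoe4=int(apoe4_raw),
                diagnosis=str(first["diagnosis"]),
                cohort=str(first["cohort"]),
                visits=visits,
            )
        )
    cohort = Cohort(subjects=subjects, roi_names=default_roi_names(atlas_size))
    cohort.validate()
    return cohort


def read_cohort_table(path, atlas_size: int = DEFAULT_ATLAS_SIZE) -> Cohort:
    """Read a long-format cohort CSV (one row per subject-visit).

    Empty cells become missing values. Raises CohortValidationError naming
    the offending row/column on malformed input.
    """
    df = pd.read_csv(path)
    return frame_to_cohort(df, atlas_size=atlas_size)


def write_cohort_table(cohort: Cohort, path) -> None:
    """Write the long-format CSV dialect ``read_cohort_table`` consumes."""
    df = cohort_to_frame(cohort)
    df.to_csv(path, index=False, float_format="%.10g")


def filter_eligible(
    cohort: Cohort,
    scale: str,
    min_visits: int = 3,
    min_span_months: int = 12,
) -> Cohort:
    """Keep subjects eligible for trajectory assignment on *scale*.

    A subject is eligible with at least ``min_visits`` visits carrying a
    non-missing score on the scale, spanning strictly more than
    ``min_span_months`` months ("at least three visits, in timespan longer
    than one year"). A span of exactly 12 months is therefore excluded;
    relax via ``min_span_months`` if a different protocol applies.
    Returns a new Cohort; the input is unchanged.
    """
    if scale not in SCALE_RANGES:
        raise CohortValidationError(f"unknown scale {scale!r}")
    kept = []
    for s in cohort.subjects:
        months = s.scored_months(scale)
        if len(months) >= min_visits and (max(months) - min(months)) > min_span_months:
            kept.append(dataclasses.replace(s, visits=list(s.visits)))
    return Cohort(subjects=kept, roi_names=list(cohort.roi_names), scale_ranges=dict(cohort.scale_ranges))


def cohorts_equal(a: Cohort, b: Cohort, rtol: float = 1e-9, atol: float = 1e-9) -> bool:
    """Field-by-field equality up to float tolerance (round-trip checks)."""
    if len(a) != len(b) or a.roi_names != b.roi_names:
        return False
    for sa, sb in zip(a.subjects, b.subjects):
        if (sa.subject_id, sa.sex, sa.apoe4, sa.diagnosis, sa.cohort) != (
            sb.subject_id, sb.sex, sb.apoe4, sb.diagnosis, sb.cohort
        ):
            return False
        if not math.isclose(sa.age, sb.age, rel_tol=rtol, abs_tol=atol):
            return False
        if len(sa.visits) != len(sb.visits):
            return False
        for va, vb in zip(sa.visits, sb.visits):
            if va.month != vb.month:
                return False
            for scale in SCALE_RANGES:
                x, y = va.score(scale), vb.score(scale)
                if (x is None) != (y is None):
                    return False
                if x is not None and not math.isclose(x, y, rel_tol=rtol, abs_tol=atol):
                    return False
            if (va.ct is None) != (vb.ct is None):
                return False
            if va.ct is not None and not np.allclose(va.ct, vb.ct, rtol=rtol, atol=atol):
                return False
    return True
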