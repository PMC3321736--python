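"""Longitudinal survival data: reading, validation, person-period expansion.

The raw input is long-format visit data: one row per subject per clinic
visit, carrying the visit day, the covariate values measured at that
visit, and the subject's terminal status (died / censored / transplanted)
with the final follow-up day.  Consecutive visit days define the interval
boundaries; the final interval ends at the subject's last follow-up day.
Expansion produces the person-period table: one Bernoulli row per
subject-visit with response ``y = 1`` only on the last interval of a
subject who died, which is the likelihood's unit of observation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "VisitRecord",
    "SubjectHistory",
    "PersonPeriodTable",
    "read_longitudinal",
    "expand_person_period",
    "compute_midpoint",
    "encode_transplant",
    "write_person_period",
]

#: Recognised terminal states for a subject.
TERMINAL_STATES = ("died", "censored", "transplanted")

#: Default integer status coding in input files (common PBC convention).
DEFAULT_STATUS_CODES = {0: "censored", 1: "transplanted", 2: "died"}


def compute_midpoint(t_start: float, t_end: float) -> float:
    """Midpoint of a visit interval ``[t_start, t_end]`` in days.

    Raises ``ValueError`` unless ``t_start < t_end``.
    """
    if not t_start < t_end:
        raise ValueError(
            f"interval must have positive length, got [{t_start}, {t_end}]"
        )
    return 0.5 * (t_start + t_end)


@dataclass
class VisitRecord:
    """One subject-visit: an interval, its covariate values, and the event flag.

    ``event`` is 1 only if the subject died in this interval; ``transplant``
    is the time-dependent competing-risk indicator (0 before transplantation,
    1 at the transplant visit).
    """

    subject_id: str
    index: int  # 1-based interval index l
    t_start: float
    t_end: float
    covariates: dict[str, float] = field(default_factory=dict)
    event: int = 0
    transplant: int = 0

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"interval index must be >= 1, got {self.index}")
        if not self.t_start < self.t_end:
            raise ValueError(
                f"subject {self.subject_id!r}, interval {self.index}: "
                f"t_start {self.t_start} must be < t_end {self.t_end}"
            )
        if self.event not in (0, 1):
            raise ValueError(f"event flag must be 0/1, got {self.event}")
        if self.transplant not in (0, 1):
            raise ValueError(f"transplant flag must be 0/1, got {self.transplant}")

    @property
    def midpoint(self) -> float:
        return compute_midpoint(self.t_start, self.t_end)


@dataclass
class SubjectHistory:
    """Ordered visit intervals for one subject with their terminal status.

    Invariants checked on construction: interval indices run 1..l_d
    consecutively, the event flag is zero on every non-final visit, and the
    final visit's flag agrees with ``terminal_status`` (1 iff died).
    """

    subject_id: str
    visits: list[VisitRecord]
    terminal_status: str

    def __post_init__(self) -> None:
        if self.terminal_status not in TERMINAL_STATES:
            raise ValueError(
                f"terminal_status must be one of {TERMINAL_STATES}, "
                f"got {self.terminal_status!r}"
            )
        if not self.visits:
            raise ValueError(f"subject {self.subject_id!r} has no visits")
        for pos, v in enumerate(self.visits, start=1):
            if v.index != pos:
                raise ValueError(
                    f"subject {self.subject_id!r}: interval indices must be "
                    f"consecutive from 1, found {v.index} at position {pos}"
                )
        for prev, nxt in zip(self.visits, self.visits[1:]):
            if not np.isclose(prev.t_end, nxt.t_start):
                raise ValueError(
                    f"subject {self.subject_id!r}: intervals are not contiguous "
                    f"({prev.t_end} -> {nxt.t_start})"
                )
        for v in self.visits[:-1]:
            if v.event != 0:
                raise ValueError(
                    f"subject {self.subject_id!r}: event flagged on non-final "
                    f"visit {v.index}"
                )
        want = 1 if self.terminal_status == "died" else 0
        if self.visits[-1].event != want:
            raise ValueError(
                f"subject {self.subject_id!r}: final event flag "
                f"{self.visits[-1].event} inconsistent with terminal status "
                f"{self.terminal_status!r}"
            )

    @property
    def n_visits(self) -> int:
        """Number of observation intervals l_d."""
        return len(self.visits)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.visits[0].covariates)


@dataclass
class PersonPeriodTable:
    """Expanded Bernoulli table: one row per subject-visit.

    ``frame`` columns: subject_id, interval, t_start, t_end, midpoint,
    one column per covariate, and the binary response ``y``.
    """

    frame: pd.DataFrame
    covariate_names: list[str]

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def subject_ids(self) -> list[str]:
        # unique ids in first-appearance order
        return list(dict.fromkeys(self.frame["subject_id"]))

    def rows_of(self, subject_id: str) -> pd.DataFrame:
        return self.frame[self.frame["subject_id"] == subject_id]

    def subject_row_indices(self) -> dict[str, np.ndarray]:
        """Positional row indices grouped by subject (insertion order)."""
        groups: dict[str, list[int]] = {}
        for pos, sid in enumerate(self.frame["subject_id"]):
            groups.setdefault(sid, []).append(pos)
        return {sid: np.asarray(ix, dtype=np.intp) for sid, ix in groups.items()}


def _as_str_id(value) -> str:
    # integer-valued floats from CSV become clean ids
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def read_longitudinal(
    path,
    schema: Mapping[str, object] | None = None,
    *,
    sep: str = ",",
) -> list[SubjectHistory]:
    """Read long-format visit data into per-subject histories.

    Parameters
    ----------
    path
        Delimited text file with one row per subject-visit.
    schema
        Column mapping with keys:

        - ``id``: subject identifier column (default ``"id"``),
        - ``day``: day of the visit (default ``"day"``),
        - ``futime``: final follow-up day, constant within subject
          (default ``"futime"``),
        - ``status``: terminal status code, constant within subject
          (default ``"status"``),
        - ``covariates``: list of covariate columns (default: every column
          not otherwise claimed),
        - ``status_codes``: mapping of integer codes to
          ``died``/``censored``/``transplanted`` (default 0/1/2 =
          censored/transplanted/died).

    Interval boundaries are reconstructed from consecutive visit days: the
    l-th interval runs from visit day l to visit day l+1, and the last
    interval ends at the subject's final follow-up day.  Rows may appear in
    any order; visits are sorted by day within subject.
    """
    schema = dict(schema or {})
    id_col = str(schema.get("id", "id"))
    day_col = str(schema.get("day", "day"))
    futime_col = str(schema.get("futime", "futime"))
    status_col = str(schema.get("status", "status"))
    status_codes = {
        int(k): str(v)
        for k, v in dict(schema.get("status_codes", DEFAULT_STATUS_CODES)).items()
    }

    df = pd.read_csv(path, sep=sep)
    if df.empty:
        return []
    required = [id_col, day_col, futime_col, status_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    cov_cols = schema.get("covariates")
    if cov_cols is None:
        cov_cols = [c for c in df.columns if c not in required]
    cov_cols = [str(c) for c in cov_cols]
    absent = [c for c in cov_cols if c not in df.columns]
    if absent:
        raise ValueError(f"covariate columns not found: {absent}")

    subjects: list[SubjectHistory] = []
    for sid, grp in df.groupby(id_col, sort=False):
        grp = grp.sort_values(day_col, kind="stable")
        days = grp[day_col].to_numpy(dtype=float)
        if np.any(np.diff(days) <= 0):
            raise ValueError(f"subject {sid!r}: visit days are not strictly increasing")
        futime = float(grp[futime_col].iloc[-1])
        if not futime > days[-1]:
            raise ValueError(
                f"subject {sid!r}: follow-up time {futime} must exceed the "
                f"last visit day {days[-1]}"
            )
        code = int(grp[status_col].iloc[-1])
        if code not in status_codes:
            raise ValueError(f"subject {sid!r}: unknown status code {code}")
        status = status_codes[code]
        bounds = np.append(days, futime)
        visits = []
        for l in range(len(days)):
            row = grp.iloc[l]
            visits.append(
                VisitRecord(
                    subject_id=_as_str_id(sid),
                    index=l + 1,
                    t_start=float(bounds[l]),
                    t_end=float(bounds[l + 1]),
                    covariates={c: float(row[c]) for c in cov_cols},
                    event=1 if (status == "died" and l == len(days) - 1) else 0,
                )
            )
        subjects.append(
            SubjectHistory(
                subject_id=_as_str_id(sid), visits=visits, terminal_status=status
            )
        )
    return subjects


def expand_person_period(subjects: Iterable[SubjectHistory]) -> PersonPeriodTable:
    """Expand subject histories into the person-period Bernoulli table.

    One row per subject-visit; response ``y`` is 1 only on the final row of
    a subject who died.  Row count is the sum of visit counts over subjects.
    """
    subjects = list(subjects)
    cov_names: list[str] = []
    for s in subjects:
        for name in s.covariate_names:
            if name not in cov_names:
                cov_names.append(name)
    records = []
    for s in subjects:
        for v in s.visits:
            rec = {
                "subject_id": s.subject_id,
                "interval": v.index,
                "t_start": v.t_start,
                "t_end": v.t_end,
                "midpoint": v.midpoint,
            }
            for name in cov_names:
                rec[name] = v.covariates.get(name, np.nan)
            rec["y"] = v.event
            records.append(rec)
    columns = ["subject_id", "interval", "t_start", "t_end", "midpoint", *cov_names, "y"]
    frame = pd.DataFrame.from_records(records, columns=columns)
    return PersonPeriodTable(frame=frame, covariate_names=cov_names)


def encode_transplant(
    subjects: Iterable[SubjectHistory], name: str = "transplant"
) -> list[SubjectHistory]:
    """Attach the time-dependent transplantation indicator as a covariate.

    The indicator is 0 on every visit before transplantation and 1 at the
    transplant visit (necessarily the subject's last); it is identically 0
    for subjects who died or were censored.  Transplanted subjects never
    contribute an event row: their response stays 0 throughout, i.e. the
    competing risk is treated as censoring plus this indicator.
    """
    out: list[SubjectHistory] = []
    for s in subjects:
        for v in s.visits[:-1]:
            if v.transplant != 0:
                raise ValueError(
                    f"subject {s.subject_id!r}: transplant flagged on "
                    f"non-final visit {v.index}"
                )
        is_tx = s.terminal_status == "transplanted"
        visits = []
        for v in s.visits:
            flag = 1 if (is_tx and v.index == s.n_visits) else 0
            cov = dict(v.covariates)
            cov[name] = float(flag)
            visits.append(
                VisitRecord(
                    subject_id=v.subject_id,
                    index=v.index,
                    t_start=v.t_start,
                    t_end=v.t_end,
                    covariates=cov,
                    event=v.event,
                    transplant=flag,
                )
            )
        out.append(
            SubjectHistory(
                subject_id=s.subject_id, visits=visits, terminal_status=s.terminal_status
            )
        )
    return out


def write_person_period(table: PersonPeriodTable, path) -> None:
    """Write the expanded table as CSV (documented column order)."""
    table.frame.to_csv(path, index=False)
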