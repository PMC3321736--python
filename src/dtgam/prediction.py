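"""Survival curves and short-term conditional survival from fitted hazards.

The discrete survival function is the cumulative product

    S(t_l) = prod_{i <= l} (1 - h_i)

over a subject's visit intervals, and the probability of surviving a
further window Dt beyond time t is the ratio Pr(t, Dt) = S(t + Dt) / S(t).
Because a six-month window rarely aligns with a subject's irregular visit
grid, S is interpolated between interval boundaries by treating each
interval's discrete hazard as a constant daily rate
r_i = -ln(1 - h_i) / (interval length); past the last observed interval
the last rate is carried forward (last observation carried forward for
the covariates).  This keeps Pr multiplicative over adjacent windows and
reproduces 1 - h_i exactly over a whole interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PersonPeriodTable
from .pgam import FitResult, predict_hazard

__all__ = [
    "SurvivalCurve",
    "GroupCurve",
    "survival_curve",
    "subject_curves",
    "conditional_survival",
    "conditional_at_visits",
    "group_average",
    "visit_quantiles",
    "SIX_MONTHS_DAYS",
]

#: Default short-term prediction window (days).
SIX_MONTHS_DAYS = 182.625


@dataclass
class SurvivalCurve:
    """Per-subject discrete survival curve S(t_l) on the visit-interval grid."""

    subject_id: str
    t_start: np.ndarray  # interval starts, days
    t_end: np.ndarray  # interval ends, days
    hazards: np.ndarray  # discrete hazard per interval
    survival: np.ndarray  # S at each interval end

    def __post_init__(self) -> None:
        for arr in ("t_start", "t_end", "hazards", "survival"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
        if not (len(self.t_start) == len(self.t_end) == len(self.hazards) == len(self.survival)):
            raise ValueError("curve arrays must have equal length")

    @property
    def n_intervals(self) -> int:
        return len(self.hazards)


def survival_curve(
    hazards, t_start=None, t_end=None, subject_id: str = ""
) -> SurvivalCurve:
    """Cumulative-product survival curve from per-interval hazards.

    With no boundaries given, intervals default to the unit grid.
    """
    h = np.asarray(hazards, dtype=float)
    if h.size == 0:
        raise ValueError("empty hazard sequence")
    if np.any((h < 0) | (h >= 1)):
        raise ValueError("hazards must lie in [0, 1)")
    if t_start is None or t_end is None:
        t_start = np.arange(h.size, dtype=float)
        t_end = t_start + 1.0
    S = np.cumprod(1.0 - h)
    return SurvivalCurve(
        subject_id=subject_id,
        t_start=np.asarray(t_start, dtype=float),
        t_end=np.asarray(t_end, dtype=float),
        hazards=h,
        survival=S,
    )


def subject_curves(fit: FitResult, table: PersonPeriodTable) -> dict[str, SurvivalCurve]:
    """One survival curve per subject from model hazards on the table's rows."""
    h = predict_hazard(fit, table)
    frame = table.frame
    out: dict[str, SurvivalCurve] = {}
    for sid, rows in table.subject_row_indices().items():
        sub = frame.iloc[rows]
        out[sid] = survival_curve(
            h[rows],
            sub["t_start"].to_numpy(dtype=float),
            sub["t_end"].to_numpy(dtype=float),
            subject_id=sid,
        )
    return out


def _cumulative_rate(curve: SurvivalCurve, t: float) -> float:
    """Integral of the piecewise-constant daily hazard rate from entry to t.

    The rate on interval i is -ln(1 - h_i) / length_i; beyond the last
    interval the final rate is carried forward, before entry it is zero.
    """
    lengths = curve.t_end - curve.t_start
    rates = -np.log1p(-curve.hazards) / lengths
    total = 0.0
    if t <= curve.t_start[0]:
        return 0.0
    for i in range(curve.n_intervals):
        a, b = curve.t_start[i], curve.t_end[i]
        if t <= a:
            break
        total += rates[i] * (min(t, b) - a)
    if t > curve.t_end[-1]:
        total += rates[-1] * (t - curve.t_end[-1])
    return total


def conditional_survival(curve: SurvivalCurve, t: float, dt: float) -> float:
    """Pr(t, Dt) = S(t + Dt) / S(t): survive a further Dt days given alive at t.

    Raises if S(t) is numerically zero.  Dt = 0 returns exactly 1.
    """
    if dt < 0:
        raise ValueError("window must be non-negative")
    if dt == 0:
        return 1.0
    H_t = _cumulative_rate(curve, t)
    if not np.isfinite(H_t) or np.exp(-H_t) <= 0.0:
        raise ValueError(f"S({t}) is zero; conditional survival undefined")
    H_tt = _cumulative_rate(curve, t + dt)
    return float(np.exp(-(H_tt - H_t)))


def conditional_at_visits(
    curve: SurvivalCurve, window: float = SIX_MONTHS_DAYS
) -> np.ndarray:
    """Pr(t_l, window) at the start of each visit interval."""
    return np.array(
        [conditional_survival(curve, t, window) for t in curve.t_start]
    )


@dataclass
class GroupCurve:
    """Average short-term survival per clinic visit within an outcome group."""

    group: str  # "died" or "censored"
    visit: np.ndarray  # visit index l = 1, 2, ...
    mean_probability: np.ndarray
    n_subjects: np.ndarray  # patients contributing at each visit


def group_average(
    curves: dict[str, SurvivalCurve],
    statuses: dict[str, str],
    window: float = SIX_MONTHS_DAYS,
    groups: tuple[str, ...] = ("died", "censored"),
) -> dict[str, GroupCurve]:
    """Mean conditional six-month survival per visit index, by outcome group.

    At visit l each group's average runs over the patients in that group
    with at least l observed visits.
    """
    per_subject = {sid: conditional_at_visits(c, window) for sid, c in curves.items()}
    out: dict[str, GroupCurve] = {}
    for g in groups:
        members = [sid for sid in curves if statuses.get(sid) == g]
        if not members:
            continue
        max_l = max(len(per_subject[sid]) for sid in members)
        visit, means, counts = [], [], []
        for l in range(max_l):
            vals = [per_subject[sid][l] for sid in members if len(per_subject[sid]) > l]
            if not vals:
                continue
            visit.append(l + 1)
            means.append(float(np.mean(vals)))
            counts.append(len(vals))
        out[g] = GroupCurve(
            group=g,
            visit=np.asarray(visit),
            mean_probability=np.asarray(means),
            n_subjects=np.asarray(counts),
        )
    return out


def visit_quantiles(
    curves: dict[str, SurvivalCurve],
    subject_ids: list[str] | None = None,
    window: float = SIX_MONTHS_DAYS,
    qs: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
) -> pd.DataFrame:
    """Box-plot style per-visit quantiles of conditional six-month survival."""
    ids = subject_ids if subject_ids is not None else list(curves)
    per_subject = {sid: conditional_at_visits(curves[sid], window) for sid in ids}
    max_l = max((len(v) for v in per_subject.values()), default=0)
    rows = []
    for l in range(max_l):
        vals = np.array([v[l] for v in per_subject.values() if len(v) > l])
        row = {"visit": l + 1, "n": len(vals)}
        for q in qs:
            row[f"q{int(round(100 * q)):02d}"] = float(np.quantile(vals, q))
        rows.append(row)
    return pd.DataFrame(rows)
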