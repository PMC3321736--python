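"""Synthetic longitudinal cohorts with known discrete-time hazard structure.

The generator emulates the shape of the Mayo PBC sequential data: a few
hundred patients seen at six months, twelve months, and then yearly (with
schedule jitter), slowly drifting positive covariates (a random-walk
bilirubin on the log scale, stationary prothrombin time, linearly
increasing age), one terminal event or censoring per subject, and an
optional competing transplantation event triggered by high bilirubin.
Each interval's death indicator is drawn from the true discrete hazard

    h = logistic(b0 + f_age(age) + f_pro(pro) + f_bili(bili)),

evaluated at the covariates measured at the interval's opening visit, so
the generated data satisfy the person-period model by construction and
every ground-truth hazard is recorded for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .data_model import SubjectHistory, VisitRecord, encode_transplant

__all__ = ["SimulationConfig", "simulate_cohort", "write_cohort", "default_bili_effect"]


def default_age_effect(age: float) -> float:
    """Linear log-odds increase of 0.04 per year of age, centred at 50."""
    return 0.04 * (age - 50.0)


def default_pro_effect(pro: float) -> float:
    """Linear effect of prothrombin time (seconds), centred at 10.5 s."""
    return 0.3 * (pro - 10.5)


def default_bili_effect(bili: float) -> float:
    """Saturating log-shaped bilirubin effect (mg/dL).

    Rises steeply through the clinically relevant 1-10 mg/dL range and
    levels off for extreme values -- genuinely nonlinear, so spline-versus-
    linear comparisons have something to find.
    """
    return 2.0 * math.tanh(0.8 * (math.log(bili) - 1.0))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the PBC visit pattern: entry visit, six-month and
    twelve-month follow-ups, then yearly visits with +/- 30 days jitter,
    for at most ``max_visits`` intervals.  Covariate units: age in years,
    prothrombin time in seconds, bilirubin in mg/dL; time in days.
    """

    n_subjects: int = 312
    # visit schedule: gaps to the 2nd and 3rd visits, then yearly
    first_gaps: tuple[float, ...] = (183.0, 182.0)
    yearly_gap: float = 365.0
    jitter_days: float = 30.0
    max_visits: int = 11
    # staggered entry: per-subject administrative censoring time (years)
    followup_years_range: tuple[float, float] = (3.0, 11.0)
    # covariate dynamics
    age_mean: float = 50.0
    age_sd: float = 10.0
    pro_mean: float = 10.5
    pro_sd: float = 0.8
    pro_ar: float = 0.5  # AR(1) persistence of prothrombin fluctuations
    bili_log_mean: float = 0.4
    bili_log_sd: float = 0.7
    bili_drift: float = 0.08  # per-visit drift of log-bilirubin
    bili_step_sd: float = 0.3
    # true predictor
    intercept: float = -3.0
    f_age: Callable[[float], float] = field(default=default_age_effect)
    f_pro: Callable[[float], float] = field(default=default_pro_effect)
    f_bili: Callable[[float], float] = field(default=default_bili_effect)
    # censoring and competing risk
    censor_prob: float = 0.02  # per-interval random censoring
    transplant_threshold: float | None = 15.0  # bilirubin trigger; None disables
    transplant_prob: float = 0.4
    seed: int | None = None


def _true_hazard(cfg: SimulationConfig, age: float, pro: float, bili: float) -> float:
    eta = cfg.intercept + cfg.f_age(age) + cfg.f_pro(pro) + cfg.f_bili(bili)
    return 1.0 / (1.0 + math.exp(-eta))


def simulate_cohort(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[list[SubjectHistory], dict]:
    """Generate a cohort and its ground truth.

    Returns the subject histories (with the transplantation indicator
    attached as a covariate) and a ground-truth record holding, per
    subject, the true hazard of every generated interval, plus the true
    effect functions and the configuration.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    subjects: list[SubjectHistory] = []
    truth_rows: list[dict] = []
    for d in range(cfg.n_subjects):
        sid = str(d + 1)
        age0 = rng.normal(cfg.age_mean, cfg.age_sd)
        pro_dev = rng.normal(0.0, cfg.pro_sd)
        log_bili = rng.normal(cfg.bili_log_mean, cfg.bili_log_sd)
        admin_end = 365.25 * rng.uniform(*cfg.followup_years_range)
        day = 0.0
        visits: list[VisitRecord] = []
        status = "censored"
        for l in range(1, cfg.max_visits + 1):
            if l > 1 and day >= admin_end:
                break  # staggered-entry administrative censoring
            gap = (
                cfg.first_gaps[l - 1] if l - 1 < len(cfg.first_gaps) else cfg.yearly_gap
            )
            gap += rng.uniform(-cfg.jitter_days, cfg.jitter_days)
            t_start, t_end = day, day + gap
            age = age0 + t_start / 365.25
            pro = cfg.pro_mean + pro_dev
            bili = float(np.exp(log_bili))
            h = _true_hazard(cfg, age, pro, bili)
            if not 0.0 < h < 1.0:
                raise ValueError(f"true hazard {h} outside (0, 1); check config")
            transplanted_now = (
                cfg.transplant_threshold is not None
                and l > 1
                and bili > cfg.transplant_threshold
                and rng.random() < cfg.transplant_prob
            )
            died_now = (not transplanted_now) and rng.random() < h
            visits.append(
                VisitRecord(
                    subject_id=sid,
                    index=l,
                    t_start=t_start,
                    t_end=t_end,
                    covariates={"age": age, "pro": pro, "bili": bili},
                    event=1 if died_now else 0,
                    transplant=1 if transplanted_now else 0,
                )
            )
            truth_rows.append(
                {
                    "subject_id": sid,
                    "interval": l,
                    "age": age,
                    "pro": pro,
                    "bili": bili,
                    "true_hazard": h,
                }
            )
            if transplanted_now:
                status = "transplanted"
                break
            if died_now:
                status = "died"
                break
            if rng.random() < cfg.censor_prob:
                status = "censored"
                break
            # advance dynamics to the next visit
            day = t_end
            pro_dev = cfg.pro_ar * pro_dev + rng.normal(
                0.0, cfg.pro_sd * math.sqrt(1.0 - cfg.pro_ar**2)
            )
            log_bili += cfg.bili_drift + rng.normal(0.0, cfg.bili_step_sd)
        subjects.append(
            SubjectHistory(subject_id=sid, visits=visits, terminal_status=status)
        )
    subjects = encode_transplant(subjects)
    truth = {
        "config": cfg,
        "rows": pd.DataFrame(truth_rows),
        "f_age": cfg.f_age,
        "f_pro": cfg.f_pro,
        "f_bili": cfg.f_bili,
        "intercept": cfg.intercept,
    }
    return subjects, truth


#: Status coding used by :func:`write_cohort` (common PBC convention).
STATUS_TO_CODE = {"censored": 0, "transplanted": 1, "died": 2}


def write_cohort(subjects: list[SubjectHistory], path) -> None:
    """Write a cohort as long-format CSV readable by ``read_longitudinal``.

    Columns: id, day (visit day), futime (final follow-up day), status
    (0 censored / 1 transplanted / 2 died), then one column per covariate
    (the transplantation indicator is re-derived on read, not stored).
    """
    records = []
    cov_names: list[str] = []
    for s in subjects:
        for name in s.covariate_names:
            if name != "transplant" and name not in cov_names:
                cov_names.append(name)
    for s in subjects:
        futime = s.visits[-1].t_end
        for v in s.visits:
            rec = {
                "id": s.subject_id,
                "day": v.t_start,
                "futime": futime,
                "status": STATUS_TO_CODE[s.terminal_status],
            }
            for name in cov_names:
                rec[name] = v.covariates.get(name, np.nan)
            records.append(rec)
    frame = pd.DataFrame.from_records(
        records, columns=["id", "day", "futime", "status", *cov_names]
    )
    frame.to_csv(path, index=False)
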