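"""Small reference records from the Mayo PBC sequential study.

The Mayo Clinic primary biliary cirrhosis trial followed 312 patients
with scheduled visits at six months, twelve months, and then yearly,
yielding 1945 visit records; the full data ship with the R ``survival``
package as ``pbcseq``.  This module carries two published example
patients (one deceased, one liver-transplanted) and the published
model-comparison summaries for that cohort, as tiny in-memory tables for
documentation and arithmetic cross-checks.  Visit days are reconstructed
from the published interval midpoints assuming study entry at day 0
(day_{l+1} = 2 * midpoint_l - day_l), since only midpoints were printed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import SubjectHistory, VisitRecord

__all__ = [
    "deceased_patient_example",
    "transplanted_patient_example",
    "pbc_model_comparison",
    "pbc_spline_lr_summary",
    "pbc_transplant_deviances",
    "PBC_N_SUBJECTS",
    "PBC_N_ROWS",
]

PBC_N_SUBJECTS = 312
PBC_N_ROWS = 1945

# deceased patient: (midpoint day, age yr, prothrombin s, bilirubin mg/dL, death flag)
_DECEASED_VISITS = [
    (92.0, 42.54, 11.0, 3.2, 0),
    (272.5, 43.04, 12.5, 7.0, 0),
    (542.0, 43.53, 11.2, 4.2, 0),
    (875.0, 44.52, 14.1, 13.5, 0),
    (1211.5, 45.35, 11.5, 12.0, 0),
    (1837.0, 46.36, 11.5, 16.2, 0),
    (2339.0, 48.78, 13.0, 14.8, 1),
]

# liver-transplanted patient: (midpoint, age, prothrombin, bilirubin, transplant flag)
_TRANSPLANTED_VISITS = [
    (99.5, 38.11, 10.9, 3.4, 0),
    (295.0, 38.65, 10.7, 1.9, 0),
    (580.0, 39.18, 10.5, 2.5, 0),
    (933.5, 40.21, 11.4, 5.7, 0),
    (1276.5, 41.11, 11.3, 5.2, 0),
    (1480.0, 42.09, 13.9, 19.0, 1),
]


def _days_from_midpoints(midpoints: list[float]) -> np.ndarray:
    """Interval boundaries t_1..t_{L+1} with t_1 = 0 and midpoint recursion."""
    days = [0.0]
    for m in midpoints:
        days.append(2.0 * m - days[-1])
    return np.asarray(days)


def _build_history(rows, subject_id: str, status: str) -> SubjectHistory:
    bounds = _days_from_midpoints([r[0] for r in rows])
    visits = []
    for l, (mid, age, pro, bili, flag) in enumerate(rows, start=1):
        visits.append(
            VisitRecord(
                subject_id=subject_id,
                index=l,
                t_start=float(bounds[l - 1]),
                t_end=float(bounds[l]),
                covariates={"age": age, "pro": pro, "bili": bili},
                event=flag if status == "died" else 0,
                transplant=flag if status == "transplanted" else 0,
            )
        )
    return SubjectHistory(subject_id=subject_id, visits=visits, terminal_status=status)


def deceased_patient_example() -> SubjectHistory:
    """A deceased PBC patient with seven clinic visits (published values)."""
    return _build_history(_DECEASED_VISITS, "9", "died")


def transplanted_patient_example() -> SubjectHistory:
    """A liver-transplanted PBC patient with six clinic visits."""
    return _build_history(_TRANSPLANTED_VISITS, "5", "transplanted")


def pbc_model_comparison() -> pd.DataFrame:
    """Published model comparison for the PBC sequential cohort.

    Columns: model label, term structure, deviance, residual df, the
    leave-one-patient-out CV score and AIC (both on the deviance scale).
    """
    rows = [
        ("I", "s(time) + s(age) + s(pro) + s(bili)", 661.77, 1933.16, 691.99, 685.44),
        ("II", "s(age) + s(pro) + s(bili)", 663.65, 1934.57, 690.54, 684.52),
        ("III", "s(time) + s(pro) + s(bili)", 705.50, 1933.93, 739.03, 727.64),
        ("IV", "age + s(pro) + s(bili)", 663.65, 1934.57, 690.51, 684.51),
        ("V", "age + s(pro) + bili", 686.63, 1937.58, 708.44, 701.46),
        ("VI", "age + pro + s(bili)", 675.80, 1938.02, 696.53, 689.77),
    ]
    return pd.DataFrame(
        rows, columns=["model", "terms", "deviance", "residual_df", "cv", "aic"]
    ).set_index("model")


def pbc_spline_lr_summary() -> pd.DataFrame:
    """Published spline-versus-linear deviance reductions for that cohort."""
    rows = [
        ("age", "IV", "II", 0.0039, 0.005),
        ("pro", "VI", "IV", 12.15, 3.45),
        ("bili", "V", "IV", 22.97, 3.01),
    ]
    return pd.DataFrame(
        rows, columns=["covariate", "nested", "full", "delta", "df"]
    ).set_index("covariate")


def pbc_transplant_deviances() -> pd.DataFrame:
    """Published deviances with and without the transplantation covariate."""
    rows = [
        ("IV", "age + s(pro) + s(bili)", 663.65, 1934.57),
        ("IV'", "age + s(pro) + s(bili) + transplant", 653.00, 1934.00),
    ]
    return pd.DataFrame(
        rows, columns=["model", "terms", "deviance", "residual_df"]
    ).set_index("model")
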