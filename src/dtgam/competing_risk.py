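"""Liver transplantation as a time-dependent competing-risk covariate.

Transplanted patients are treated as censored at transplantation (they
never contribute an event row), and transplantation additionally enters
the model as a binary time-dependent covariate -- 0 on every visit before
the transplant, 1 at the transplant visit.  The significance of the
competing risk is tested by the deviance reduction from adding this
single linear, unpenalized column, referred to a chi-square with the
(fractional) difference in effective degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

from .data_model import PersonPeriodTable
from .pgam import DiscreteHazardGAM, FitResult
from .selection import lr_test
from .splines import LinearTermSpec

__all__ = ["TransplantTestResult", "transplant_lr_test"]


@dataclass
class TransplantTestResult:
    delta_deviance: float
    df: float
    p_value: float
    fit_base: FitResult
    fit_extended: FitResult


def transplant_lr_test(
    model: DiscreteHazardGAM,
    table: PersonPeriodTable,
    transplant_column: str = "transplant",
) -> TransplantTestResult:
    """Deviance-reduction test for the transplantation covariate.

    Fits the base model and the base model plus a linear transplant
    indicator at matched smoothing parameters, and compares the deviances.
    Raises if the table has no transplanted subject (the indicator would
    be identically zero and the test undefined).
    """
    if transplant_column not in table.frame.columns:
        raise ValueError(f"table has no column {transplant_column!r}")
    if table.frame[transplant_column].sum() == 0:
        raise ValueError(
            "no transplanted subjects: the transplantation indicator is "
            "identically zero and its test is undefined"
        )
    base_fit = model.fit(table)
    extended = DiscreteHazardGAM(
        [*model.terms, LinearTermSpec(transplant_column)], dict(model.lambdas)
    )
    ext_fit = extended.fit(table)
    delta, df, p = lr_test(base_fit, ext_fit)
    return TransplantTestResult(
        delta_deviance=delta, df=df, p_value=p, fit_base=base_fit, fit_extended=ext_fit
    )
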