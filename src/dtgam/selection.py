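"""Smoothing-parameter selection and model comparison.

The smoothing parameters are chosen by a variant v-fold cross-validation
that leaves out one *patient* at a time: all of a patient's person-period
rows are deleted together, the model is refit on the remaining patients,
and the held-out patient's partial log likelihood is accumulated.  The
score is reported on the -2 log-likelihood (deviance) scale so it is
directly comparable with the deviance and AIC.  A GCV comparator, AIC,
likelihood-ratio tests with fractional degrees of freedom, and approximate
per-term Wald tests round out model comparison.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model import PersonPeriodTable
from .pgam import DiscreteHazardGAM, FitResult, fit_pgam

__all__ = [
    "CVResult",
    "variant_cv",
    "grid_search_cv",
    "gcv_score",
    "aic",
    "lr_test",
    "term_pvalues",
]


@dataclass
class CVResult:
    """Grid-search outcome of the leave-one-patient-out CV."""

    grid: list[dict[str, float]]  # candidate lambda combinations
    scores: np.ndarray  # CV score (deviance scale) per grid point
    best_lambdas: dict[str, float]
    best_score: float
    contributions: dict[str, float]  # per-patient held-out loglik at optimum


def _held_out_logliks(
    model: DiscreteHazardGAM,
    table: PersonPeriodTable,
    lambdas: dict[str, float],
    *,
    design=None,
    beta_warm=None,
) -> dict[str, float]:
    """Leave-one-subject-out held-out log likelihood per subject."""
    if design is None:
        design = model.build(table)
    Z = design.Z
    y = table.frame["y"].to_numpy(dtype=float)
    penalties = {name: design.embedded_penalty(name) for name in design.penalties}
    groups = table.subject_row_indices()
    if len(groups) < 2:
        raise ValueError("variant CV needs at least two subjects")
    if beta_warm is None:
        beta_warm = fit_pgam(Z, y, penalties, lambdas, blocks=design.blocks).beta
    contributions: dict[str, float] = {}
    for sid, rows in groups.items():
        mask = np.ones(len(y), dtype=bool)
        mask[rows] = False
        y_train = y[mask]
        if y_train.sum() == 0:
            warnings.warn(
                f"training fold without events when leaving out subject {sid!r}; "
                "the fold's fit is driven by the penalty and intercept alone",
                stacklevel=2,
            )
        fold = fit_pgam(
            Z[mask], y_train, penalties, lambdas, beta0=beta_warm, blocks=design.blocks
        )
        eta = Z[rows] @ fold.beta
        contributions[sid] = float(np.sum(y[rows] * eta - np.logaddexp(0.0, eta)))
    return contributions


def variant_cv(
    model: DiscreteHazardGAM,
    table: PersonPeriodTable,
    lambdas: dict[str, float] | None = None,
    *,
    design=None,
) -> float:
    """Leave-one-patient-out CV score on the -2 log-likelihood scale.

    For each subject the model is refit on every other subject's rows and
    the deleted subject's rows are scored with their held-out Bernoulli log
    likelihood; the score is -2 times the sum over subjects.  When every
    subject has a single row this reduces to ordinary leave-one-out CV.
    """
    lambdas = dict(lambdas if lambdas is not None else model.lambdas)
    contributions = _held_out_logliks(model, table, lambdas, design=design)
    return -2.0 * sum(contributions.values())


def grid_search_cv(
    model: DiscreteHazardGAM,
    table: PersonPeriodTable,
    grid: dict[str, list[float]],
    *,
    verbose: bool = False,
) -> CVResult:
    """Exhaustive CV over a per-term grid of smoothing parameters.

    The grid is the cartesian product of each smooth term's candidate
    values (log-spaced grids such as 1e-4..1e2 are typical).  Ties are
    broken toward the largest lambdas, i.e. the smoothest model.
    """
    names = list(grid)
    if not names or any(len(v) == 0 for v in grid.values()):
        raise ValueError("empty smoothing-parameter grid")
    design = model.build(table)
    combos = [
        dict(zip(names, values))
        for values in itertools.product(*(grid[n] for n in names))
    ]
    scores = np.empty(len(combos))
    all_contribs: list[dict[str, float]] = []
    for i, combo in enumerate(combos):
        lambdas = dict(model.lambdas)
        lambdas.update(combo)
        contribs = _held_out_logliks(model, table, lambdas, design=design)
        scores[i] = -2.0 * sum(contribs.values())
        all_contribs.append(contribs)
        if verbose:
            print(f"[cv] {combo} -> {scores[i]:.4f}")
    # smallest score; ties go to the largest (smoothest) lambdas
    order = sorted(
        range(len(combos)),
        key=lambda i: (scores[i], [-combos[i][n] for n in names]),
    )
    best = order[0]
    best_lambdas = dict(model.lambdas)
    best_lambdas.update(combos[best])
    return CVResult(
        grid=combos,
        scores=scores,
        best_lambdas=best_lambdas,
        best_score=float(scores[best]),
        contributions=all_contribs[best],
    )


def gcv_score(fit: FitResult) -> float:
    """Generalized cross-validation: N * Dev / (N - edf)^2 (comparator only)."""
    if fit.edf >= fit.n_rows:
        raise ValueError("effective df >= number of rows; GCV undefined")
    return fit.n_rows * fit.deviance / (fit.n_rows - fit.edf) ** 2


def aic(fit: FitResult) -> float:
    """AIC on the deviance scale: Dev + 2 * edf."""
    return fit.deviance + 2.0 * fit.edf


def lr_test(
    fit_nested: FitResult, fit_full: FitResult, *, tol: float = 1e-6
) -> tuple[float, float, float]:
    """Likelihood-ratio test between nested penalized fits.

    Returns (delta, df, p) with delta the deviance reduction, df the
    difference in effective degrees of freedom (fractional df allowed; the
    reference distribution is the chi-square, i.e. gamma, with that df),
    and p the upper tail probability.
    """
    delta = fit_nested.deviance - fit_full.deviance
    df = fit_full.edf - fit_nested.edf
    if delta < -tol * max(1.0, abs(fit_full.deviance)):
        raise ValueError(
            f"full model has larger deviance (delta={delta:.6g}); models are "
            "not nested or a fit failed to converge"
        )
    delta = max(delta, 0.0)
    if df <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(stats.chi2.sf(delta, df))
    return float(delta), float(df), p


def term_pvalues(fit: FitResult) -> dict[str, float]:
    """Approximate Wald chi-square p-value per model term.

    For each term block, T = beta_j' V_jj^{-1} beta_j with V the inverse
    penalized information, referred to a chi-square with the term's
    effective df.  This is a convenient approximation, not an exact test.
    """
    if fit.design is None or fit.cov is None:
        raise ValueError("fit carries no design/covariance information")
    out: dict[str, float] = {}
    for name, sl in fit.design.blocks.items():
        b = fit.beta[sl]
        Vjj = fit.cov[sl, sl]
        T = float(b @ np.linalg.pinv(Vjj) @ b)
        df = max(fit.edf_by_term.get(name, len(b)), 1e-8)
        out[name] = float(stats.chi2.sf(T, df)) if T > 0 else 1.0
    return out
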