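"""Penalized likelihood fitting of the discrete-time hazard GAM.

The person-period table is a set of independent Bernoulli trials whose
success probability is the discrete hazard h, with

    logit(h) = Z beta

for the stacked B-spline/linear design Z.  The partial log likelihood of
the survival model is algebraically the Bernoulli log likelihood of this
table, so estimation is penalized logistic regression:

    maximize  lnL(beta) - (1/2) sum_i lambda_i beta' S_i beta,

where S_i penalizes the integrated squared second derivative of the i-th
smooth.  Maximization uses iteratively reweighted least squares (Fisher
scoring) with step halving, so the penalized objective never decreases.
The effective degrees of freedom are tr[(Z'WZ + S_lambda)^-1 Z'WZ] at
convergence -- the trace of the influence matrix -- and the deviance is
-2 lnL(beta_hat), the saturated model's log likelihood being zero for
binary data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .data_model import PersonPeriodTable
from .splines import DesignMatrix, build_design

__all__ = [
    "FitResult",
    "partial_loglik",
    "fit_pgam",
    "deviance",
    "predict_hazard",
    "DiscreteHazardGAM",
]

_MIN_WEIGHT = 1e-10


def _logistic(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def partial_loglik(beta: np.ndarray, Z: np.ndarray, y: np.ndarray) -> float:
    """Bernoulli log likelihood sum y*eta - log(1 + e^eta) with eta = Z beta.

    Identical to the survival partial log likelihood: every non-terminal
    row contributes log(1-h), terminal rows contribute log h (death) or
    log(1-h) (censoring).
    """
    eta = Z @ np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class FitResult:
    """A converged penalized fit and its summaries."""

    beta: np.ndarray
    lambdas: dict[str, float]
    hazard: np.ndarray  # fitted h per person-period row
    loglik: float
    deviance: float
    edf: float
    edf_by_term: dict[str, float]
    residual_df: float
    n_rows: int
    iterations: int
    converged: bool
    grad_norm: float
    design: DesignMatrix | None = field(default=None, repr=False)
    cov: np.ndarray | None = field(default=None, repr=False)  # (Z'WZ + S)^-1
    y: np.ndarray | None = field(default=None, repr=False)

    def summary_dict(self) -> dict:
        """JSON-serializable fit summary."""
        return {
            "coefficients": self.beta.tolist(),
            "lambdas": dict(self.lambdas),
            "loglik": self.loglik,
            "deviance": self.deviance,
            "edf": self.edf,
            "edf_by_term": dict(self.edf_by_term),
            "residual_df": self.residual_df,
            "n_rows": self.n_rows,
            "iterations": self.iterations,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
        }


def _solve_spd(A: np.ndarray, B: np.ndarray, ridge: float = 1e-10):
    """Cholesky solve with a tiny ridge fallback for near-singular systems."""
    try:
        return cho_solve(cho_factor(A, lower=True), B), False
    except np.linalg.LinAlgError:
        warnings.warn(
            f"penalized normal equations near-singular; adding ridge {ridge:g}",
            stacklevel=3,
        )
        bumped = A + ridge * np.eye(A.shape[0]) * max(1.0, np.trace(A) / A.shape[0])
        return cho_solve(cho_factor(bumped, lower=True), B), True


def fit_pgam(
    Z: np.ndarray,
    y: np.ndarray,
    penalties: dict[str, np.ndarray] | None = None,
    lambdas: dict[str, float] | None = None,
    *,
    beta0: np.ndarray | None = None,
    tol: float = 1e-11,
    max_iter: int = 200,
    blocks: dict[str, slice] | None = None,
    design: DesignMatrix | None = None,
) -> FitResult:
    """Maximize the penalized Bernoulli log likelihood by IRLS.

    Parameters
    ----------
    Z, y
        Design matrix (leading intercept column) and 0/1 response.
    penalties
        Per-smooth penalty matrices embedded in full coefficient space.
    lambdas
        Non-negative smoothing parameter per smooth term.
    beta0
        Warm start (defaults to the intercept-only fit).
    blocks
        Column slices per term, for per-term effective df.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = Z.shape
    penalties = penalties or {}
    lambdas = dict(lambdas or {})
    for name in penalties:
        lam = lambdas.setdefault(name, 0.0)
        if lam < 0:
            raise ValueError(f"negative smoothing parameter for {name!r}: {lam}")
    S = np.zeros((q, q))
    for name, P in penalties.items():
        S += lambdas[name] * P

    if beta0 is not None:
        beta = np.asarray(beta0, dtype=float).copy()
    else:
        beta = np.zeros(q)
        ybar = min(max(y.mean(), 1e-8), 1 - 1e-8)
        beta[0] = np.log(ybar / (1 - ybar))

    def objective(b):
        eta = Z @ b
        if not np.all(np.isfinite(eta)):
            return -np.inf
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(b @ S @ b)

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = Z @ beta
        h = _logistic(eta)
        w = np.clip(h * (1.0 - h), _MIN_WEIGHT, None)
        # Fisher scoring step: (Z'WZ + S) b_new = Z'W eta + Z'(y - h)
        ZtW = Z.T * w
        A = ZtW @ Z + S
        rhs = ZtW @ eta + Z.T @ (y - h)
        full_step, _ = _solve_spd(A, rhs)
        direction = full_step - beta
        # step-halving keeps the penalized objective non-decreasing
        step = 1.0
        beta_new = full_step
        obj_new = objective(beta_new)
        while (not np.isfinite(obj_new) or obj_new < obj) and step > 1e-12:
            step *= 0.5
            beta_new = beta + step * direction
            obj_new = objective(beta_new)
        if not np.isfinite(obj_new):
            raise FloatingPointError("penalized objective became non-finite")
        rel_change = abs(obj_new - obj) / (abs(obj_new) + 0.1)
        beta, obj = beta_new, obj_new
        if rel_change < tol:
            converged = True
            break

    if converged:
        # one polishing Newton step: quadratic convergence takes the
        # solution to machine precision once the tolerance has triggered
        h = _logistic(Z @ beta)
        w = np.clip(h * (1.0 - h), _MIN_WEIGHT, None)
        ZtW = Z.T * w
        polish, _ = _solve_spd(ZtW @ Z + S, ZtW @ (Z @ beta) + Z.T @ (y - h))
        obj_polish = objective(polish)
        if obj_polish >= obj - 1e-12 * (abs(obj) + 1.0):
            beta, obj = polish, obj_polish

    eta = Z @ beta
    if np.max(np.abs(eta)) > 30.0:
        warnings.warn(
            "fitted log-odds exceed 30 in magnitude; coefficients are "
            "diverging and the data may be perfectly separated",
            stacklevel=2,
        )
    h = _logistic(eta)
    w = np.clip(h * (1.0 - h), _MIN_WEIGHT, None)
    ZtWZ = (Z.T * w) @ Z
    A = ZtWZ + S
    V, _ = _solve_spd(A, np.eye(q))
    F = V @ ZtWZ  # influence matrix in coefficient space
    edf_diag = np.diag(F)
    edf = float(np.sum(edf_diag))
    edf_by_term: dict[str, float] = {"intercept": float(edf_diag[0])}
    if blocks:
        for name, sl in blocks.items():
            edf_by_term[name] = float(np.sum(edf_diag[sl]))
    grad = Z.T @ (y - h) - S @ beta
    ll = partial_loglik(beta, Z, y)
    if not converged:
        warnings.warn(
            f"IRLS did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g})",
            stacklevel=2,
        )
    return FitResult(
        beta=beta,
        lambdas=lambdas,
        hazard=h,
        loglik=ll,
        deviance=-2.0 * ll,
        edf=edf,
        edf_by_term=edf_by_term,
        residual_df=float(n - edf),
        n_rows=n,
        iterations=it,
        converged=converged,
        grad_norm=float(np.linalg.norm(grad)),
        design=design,
        cov=V,
        y=y.copy(),
    )


def deviance(fit: FitResult) -> float:
    """Dev = -2 lnL(beta_hat): the saturated binary model has lnL = 0."""
    return -2.0 * fit.loglik


def predict_hazard(fit: FitResult, rows: PersonPeriodTable | np.ndarray) -> np.ndarray:
    """Fitted discrete hazards for new person-period rows.

    ``rows`` may be a person-period table (the fit's design evaluates its
    terms on the new covariate values, clamping out-of-range values to the
    knot range) or a ready-made design matrix.
    """
    if isinstance(rows, np.ndarray):
        Z = rows
    else:
        if fit.design is None:
            raise ValueError("fit carries no design; pass a design matrix instead")
        Z = fit.design.rows_for(rows)
    return _logistic(Z @ fit.beta)


class DiscreteHazardGAM:
    """Model front-end: a term list plus smoothing parameters.

    Examples
    --------
    >>> model = DiscreteHazardGAM(
    ...     [LinearTermSpec("age"), SmoothTermSpec("bili")],
    ...     lambdas={"bili": 0.1},
    ... )
    >>> fit = model.fit(table)                      # doctest: +SKIP
    >>> h = model.predict_hazard(fit, new_table)    # doctest: +SKIP
    """

    def __init__(self, terms: list, lambdas: dict[str, float] | None = None):
        self.terms = list(terms)
        self.lambdas = dict(lambdas or {})
        for t in self.terms:
            if t.is_smooth:
                self.lambdas.setdefault(t.covariate, 1.0)

    def build(self, table: PersonPeriodTable) -> DesignMatrix:
        return build_design(table, self.terms)

    def fit(
        self,
        table: PersonPeriodTable,
        design: DesignMatrix | None = None,
        **kwargs,
    ) -> FitResult:
        if design is None:
            design = self.build(table)
        y = table.frame["y"].to_numpy(dtype=float)
        penalties = {name: design.embedded_penalty(name) for name in design.penalties}
        return fit_pgam(
            design.Z,
            y,
            penalties,
            dict(self.lambdas),
            blocks=design.blocks,
            design=design,
            **kwargs,
        )

    def predict_hazard(self, fit: FitResult, table: PersonPeriodTable) -> np.ndarray:
        return predict_hazard(fit, table)
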