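"""B-spline bases, the stacked design matrix Z, and curvature penalties.

Each continuous covariate may enter the logit-hazard predictor through a
smooth term s(x) represented in a clamped B-spline basis (default: cubic,
10 interior knots at quantiles of the observed values).  Smooth blocks are
centered with a sum-to-zero reparameterization so the model with a free
intercept stays identifiable.  The roughness of each smooth is measured by
the integrated squared second derivative, a quadratic form b' S b in the
basis coefficients; S is integrated exactly span-by-span with
Gauss-Legendre quadrature of sufficient order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import null_space

from .data_model import PersonPeriodTable

__all__ = [
    "SmoothTermSpec",
    "LinearTermSpec",
    "DesignMatrix",
    "place_knots",
    "evaluate_basis",
    "build_design",
    "penalty_matrix",
]


def place_knots(values, n_interior: int = 10, degree: int = 3) -> np.ndarray:
    """Knot vector with interior knots at equally spaced quantiles.

    Boundary knots sit at the data min and max, each replicated
    ``degree + 1`` times (clamped basis).  Raises if the data carry too few
    distinct values to support the requested knots, or if quantiles
    coincide (reduce ``n_interior`` in that case).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("values must be a non-empty 1-d array")
    distinct = np.unique(values)
    if distinct.size < n_interior + 2:
        raise ValueError(
            f"need at least {n_interior + 2} distinct values to place "
            f"{n_interior} interior knots, got {distinct.size}"
        )
    lo, hi = distinct[0], distinct[-1]
    if n_interior > 0:
        probs = np.arange(1, n_interior + 1) / (n_interior + 1)
        interior = np.quantile(values, probs)
        if np.any(np.diff(interior) <= 0) or interior[0] <= lo or interior[-1] >= hi:
            raise ValueError(
                "quantile knots are not strictly increasing inside the data "
                "range; reduce n_interior for this covariate"
            )
    else:
        interior = np.empty(0)
    return np.concatenate(
        [np.repeat(lo, degree + 1), interior, np.repeat(hi, degree + 1)]
    )


@dataclass
class SmoothTermSpec:
    """A penalized B-spline term s(x) for one covariate.

    ``n_interior`` interior knots and degree-``degree`` pieces give a raw
    basis of dimension ``n_interior + degree + 1``; sum-to-zero centering
    (applied when the design is built) removes one column.
    """

    covariate: str
    n_interior: int = 10
    degree: int = 3
    knots: np.ndarray | None = None
    center: bool = True
    # filled in by build_design: centering transform (basis_dim x basis_dim-1)
    constraint: np.ndarray | None = field(default=None, repr=False)

    @property
    def is_smooth(self) -> bool:
        return True

    @property
    def basis_dim(self) -> int:
        """Raw (uncentered) basis dimension."""
        if self.knots is not None:
            return len(self.knots) - self.degree - 1
        return self.n_interior + self.degree + 1

    @property
    def n_columns(self) -> int:
        """Columns this term contributes to the design."""
        return self.basis_dim - 1 if self.center else self.basis_dim

    def ensure_knots(self, values) -> None:
        if self.knots is None:
            self.knots = place_knots(values, self.n_interior, self.degree)


@dataclass
class LinearTermSpec:
    """An unpenalized single-column linear term."""

    covariate: str

    @property
    def is_smooth(self) -> bool:
        return False

    @property
    def n_columns(self) -> int:
        return 1


def evaluate_basis(x, spec: SmoothTermSpec, *, clamp: bool = True) -> np.ndarray:
    """Raw (uncentered) B-spline basis values at ``x``, shape (n, basis_dim).

    Values outside the boundary knots are clamped to the boundary with a
    warning when ``clamp`` is set, otherwise they raise.  Inside the range
    the basis is a partition of unity.
    """
    if spec.knots is None:
        raise ValueError(f"term {spec.covariate!r}: knots not yet placed")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    t = np.asarray(spec.knots, dtype=float)
    lo, hi = t[0], t[-1]
    if np.any(x < lo) or np.any(x > hi):
        if not clamp:
            raise ValueError(
                f"term {spec.covariate!r}: values outside knot range "
                f"[{lo}, {hi}] with clamping disabled"
            )
        warnings.warn(
            f"term {spec.covariate!r}: clamping out-of-range values to "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
        x = np.clip(x, lo, hi)
    return BSpline.design_matrix(x, t, spec.degree, extrapolate=False).toarray()


def penalty_matrix(spec: SmoothTermSpec, *, centered: bool | None = None) -> np.ndarray:
    """Second-derivative penalty S with S_jk = integral of b_j'' b_k''.

    Exact for polynomial splines: each knot span contributes a Gauss-
    Legendre quadrature whose order covers the degree-2(d-2) integrand.
    The null space of the raw S contains constants and linear functions.
    When ``centered`` (default: the spec's own centering flag), S is
    transformed into the sum-to-zero parameterization used by the design.
    """
    if spec.degree < 2:
        raise ValueError("second-derivative penalty requires degree >= 2")
    if spec.knots is None:
        raise ValueError(f"term {spec.covariate!r}: knots not yet placed")
    t = np.asarray(spec.knots, dtype=float)
    k = spec.degree
    n = spec.basis_dim
    d2 = BSpline(t, np.eye(n), k).derivative(2)

    # Gauss-Legendre: m points integrate degree 2m-1 exactly; need 2(k-2).
    m = max(k - 1, 1)
    nodes, weights = np.polynomial.legendre.leggauss(m)
    S = np.zeros((n, n))
    spans = np.unique(t)
    for a, b in zip(spans[:-1], spans[1:]):
        half = 0.5 * (b - a)
        xq = a + half * (nodes + 1.0)
        Bq = d2(xq)  # (m, n)
        S += half * (Bq * weights[:, None]).T @ Bq
    S = 0.5 * (S + S.T)
    if centered is None:
        centered = spec.center
    if centered:
        if spec.constraint is None:
            raise ValueError(
                f"term {spec.covariate!r}: centering constraint not yet built"
            )
        S = spec.constraint.T @ S @ spec.constraint
        S = 0.5 * (S + S.T)
    return S


@dataclass
class DesignMatrix:
    """Stacked design Z: intercept column followed by one block per term.

    ``blocks`` maps term names to column slices of ``Z``; ``penalties``
    maps each smooth term's name to its (centered) penalty matrix embedded
    in that block's coordinates.
    """

    Z: np.ndarray
    terms: list
    blocks: dict[str, slice]
    penalties: dict[str, np.ndarray]

    @property
    def n_rows(self) -> int:
        return self.Z.shape[0]

    @property
    def n_columns(self) -> int:
        return self.Z.shape[1]

    def embedded_penalty(self, name: str) -> np.ndarray:
        """The term's penalty embedded in full coefficient space."""
        q = self.n_columns
        S = np.zeros((q, q))
        sl = self.blocks[name]
        S[sl, sl] = self.penalties[name]
        return S

    def rows_for(self, table: PersonPeriodTable) -> np.ndarray:
        """Evaluate the fitted design on new person-period rows."""
        return _assemble(table, self.terms, fit=False)


def _term_values(table: PersonPeriodTable, covariate: str) -> np.ndarray:
    if covariate in ("time", "midpoint"):
        return table.frame["midpoint"].to_numpy(dtype=float)
    if covariate not in table.frame.columns:
        raise ValueError(f"covariate {covariate!r} not present in the table")
    vals = table.frame[covariate].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)):
        raise ValueError(f"covariate {covariate!r} contains non-finite values")
    return vals


def _assemble(table: PersonPeriodTable, terms: list, *, fit: bool) -> np.ndarray:
    n = table.n_rows
    cols = [np.ones((n, 1))]
    for term in terms:
        x = _term_values(table, term.covariate)
        if term.is_smooth:
            if fit:
                term.ensure_knots(x)
            B = evaluate_basis(x, term)
            if term.center:
                if fit and term.constraint is None:
                    # sum-to-zero over the training rows: columns of the
                    # transform span the null space of the column-mean row
                    term.constraint = null_space(B.mean(axis=0, keepdims=True))
                if term.constraint is None:
                    raise ValueError(
                        f"term {term.covariate!r}: constraint missing for prediction"
                    )
                B = B @ term.constraint
            cols.append(B)
        else:
            cols.append(x[:, None])
    return np.hstack(cols)


def build_design(table: PersonPeriodTable, terms: list) -> DesignMatrix:
    """Build the N x q design matrix for a term list.

    The first column is the intercept; each smooth term contributes a
    centered B-spline block (knots placed at quantiles of the training
    values if not already set), each linear term one raw column.  Raises on
    rank deficiency of the assembled design.
    """
    terms = list(terms)
    names = [t.covariate for t in terms]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate term covariates: {names}")
    Z = _assemble(table, terms, fit=True)
    blocks: dict[str, slice] = {}
    start = 1
    for term in terms:
        blocks[term.covariate] = slice(start, start + term.n_columns)
        start += term.n_columns
    penalties = {
        t.covariate: penalty_matrix(t) for t in terms if t.is_smooth
    }
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Z.shape[1]} "
            "columns); check for collinear or constant terms"
        )
    return DesignMatrix(Z=Z, terms=terms, blocks=blocks, penalties=penalties)
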