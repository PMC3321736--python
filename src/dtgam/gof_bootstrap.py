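"""Bootstrap goodness-of-fit test for the deviance.

For ungrouped binary responses the deviance has no usable chi-square
reference distribution, so the fit is judged against a bootstrap
reference: resample whole patients with replacement, refit the model with
the same smoothing parameters, and collect the replicate deviances.  The
100(1-alpha)-th percentile of the replicates (the order statistic of rank
j with alpha = 1 - j/(B+1)) is the critical value; an observed deviance
above it indicates a poor fit.  Resampling the *subject*, not the row,
preserves the within-patient dependence of the person-period rows.

A caution the diagnostics of this package make measurable: for ungrouped
binary responses the minimized deviance is nearly a deterministic
function of the fitted coefficients, so the bootstrap distribution of
Dev(b) -- whether cases are resampled or responses are redrawn from the
fitted hazards (``method="parametric"``) -- is centered close to the
observed deviance.  The resulting decision is therefore very
conservative: an observed deviance below the critical value is weak
evidence of fit, while one above it is a strong signal of trouble.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import PersonPeriodTable
from .pgam import DiscreteHazardGAM, fit_pgam

__all__ = ["BootstrapGoFResult", "bootstrap_gof"]


@dataclass
class BootstrapGoFResult:
    """Bootstrap deviance reference and the resulting decision."""

    B: int  # requested replicates
    effective_B: int  # replicates that produced a usable fit
    deviances: np.ndarray  # replicate deviances, ascending
    alpha: float
    rank: int  # order-statistic rank j of the critical value
    critical_value: float
    observed_deviance: float
    poor_fit: bool  # observed > critical value

    def histogram(self, bins: int = 30) -> tuple[np.ndarray, np.ndarray]:
        """Bin counts and edges of the replicate deviances."""
        return np.histogram(self.deviances, bins=bins)


def bootstrap_gof(
    model: DiscreteHazardGAM,
    table: PersonPeriodTable,
    *,
    B: int = 400,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    min_effective_frac: float = 0.8,
    method: str = "case",
) -> BootstrapGoFResult:
    """Bootstrap the deviance to calibrate a goodness-of-fit decision.

    Parameters
    ----------
    model
        Term structure and smoothing parameters (held fixed across
        replicates).
    B
        Number of bootstrap replicates; at least 39 so the alpha = 0.05
        order statistic exists.
    alpha
        Significance level; critical value is the order statistic of rank
        round((1 - alpha) * (B + 1)).
    seed
        Seed (or SeedSequence) for the replicate streams; results are
        reproducible bit-for-bit for a fixed seed.
    method
        ``"case"`` resamples whole patients with replacement (the
        nonparametric bootstrap); ``"parametric"`` redraws every row's
        response from the fitted hazards on the original design.  Both
        reference distributions center near the observed deviance (see
        the module docstring), so the test is conservative either way.
    """
    if method not in ("case", "parametric"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    min_B = int(np.ceil(1.0 / alpha)) - 1
    if B < max(min_B, 2):
        raise ValueError(
            f"B = {B} too small for alpha = {alpha}; need at least {min_B}"
        )
    design = model.build(table)
    Z = design.Z
    y = table.frame["y"].to_numpy(dtype=float)
    penalties = {name: design.embedded_penalty(name) for name in design.penalties}
    lambdas = dict(model.lambdas)
    base = fit_pgam(Z, y, penalties, lambdas, blocks=design.blocks, design=design)

    groups = table.subject_row_indices()
    ids = list(groups)
    n = len(ids)
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = seq.spawn(B)
    devs: list[float] = []
    failures = 0
    for b in range(B):
        rng = np.random.default_rng(streams[b])
        if method == "case":
            picks = rng.integers(0, n, size=n)
            rows = np.concatenate([groups[ids[i]] for i in picks])
            Zb, yb = Z[rows], y[rows]
        else:
            Zb, yb = Z, rng.binomial(1, base.hazard).astype(float)
        try:
            rep = fit_pgam(
                Zb, yb, penalties, lambdas, beta0=base.beta, blocks=design.blocks
            )
            devs.append(rep.deviance)
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            failures += 1
            warnings.warn(f"bootstrap replicate {b} failed: {exc}", stacklevel=2)
    effective_B = len(devs)
    if failures:
        warnings.warn(
            f"{failures} of {B} bootstrap replicates failed; "
            f"effective B = {effective_B}",
            stacklevel=2,
        )
    if effective_B < max(min_B, int(min_effective_frac * B)):
        raise RuntimeError(
            f"too few usable bootstrap replicates ({effective_B} of {B})"
        )
    dev_sorted = np.sort(np.asarray(devs))
    # quantile of order j/(B+1): fractional ranks round to nearest integer
    rank = int(round((1.0 - alpha) * (effective_B + 1)))
    rank = min(max(rank, 1), effective_B)
    critical = float(dev_sorted[rank - 1])
    return BootstrapGoFResult(
        B=B,
        effective_B=effective_B,
        deviances=dev_sorted,
        alpha=alpha,
        rank=rank,
        critical_value=critical,
        observed_deviance=base.deviance,
        poor_fit=bool(base.deviance > critical),
    )
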