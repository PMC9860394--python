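"""Sample-size and statistical-power planning for PTM experiments.

Planning a protein-adjusted PTM experiment needs two variance components --
the anticipated variance of the PTM summaries (sigma2_ptm) and of the
unmodified-protein summaries (sigma2_protein) -- because the adjusted fold
change pools both.  With a target FDR q, average type II error beta, minimal
adjusted log2 fold change delta, and prior odds of null to alternative
m0/m1, the per-test significance level is

    alpha = (1 - beta) * q / (1 + (1 - q) * m0/m1),

and the balanced design needs J' replicates per condition with

    J' >= (2 sigma2_ptm + 2 sigma2_protein) (z_{1-beta} + z_{1-alpha/2})^2
          / delta^2.

With J' fixed instead, the same variance bound is solved for the achieved
FDR (or for power at fixed q).  Standard-normal quantiles are used
throughout.  The allocation generalization replaces the balanced
2(sigma2_ptm + sigma2_protein)/J' with 2 sigma2_ptm/J_ptm +
2 sigma2_protein/J_protein, allowing unequal numbers of enrichment and
global profiling runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm


class InfeasibleDesignError(ValueError):
    pass


@dataclass
class PowerSpec:
    """Inputs to the sample-size / power calculations.

    q : target false discovery rate, in (0, 1).
    beta : average type II error rate, in (0, 1).
    delta_adj : minimal adjusted log2 fold change of interest (> 0).
    m0_over_m1 : anticipated ratio of true nulls to true alternatives.
    var_ptm, var_protein : anticipated contrast variances of the PTM and
        protein run summaries (log2 scale).
    n_conditions : number of conditions I (>= 2).
    j_fixed : optional fixed number of replicates per condition, for the
        solve-for-q / power direction.
    """

    q: float = 0.05
    beta: float = 0.2
    delta_adj: float = 1.0
    m0_over_m1: float = 1.0
    var_ptm: float = 0.0
    var_protein: float = 0.0
    n_conditions: int = 2
    j_fixed: int | None = None

    def __post_init__(self):
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0,1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0,1)")
        if self.var_ptm < 0 or self.var_protein < 0:
            raise ValueError("variances must be non-negative")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")


MIN_REPLICATES = 2  # residual variance inestimable below two per condition


def alpha_from_fdr(q: float, beta: float, m0_over_m1: float) -> float:
    """Per-test significance level achieving FDR q at power 1-beta."""
    return (1 - beta) * q / (1 + (1 - q) * m0_over_m1)


def sample_size(spec: PowerSpec) -> int:
    """Minimal replicates per condition meeting the spec, floored at 2."""
    if spec.delta_adj <= 0:
        raise InfeasibleDesignError("delta_adj must be positive")
    alpha = alpha_from_fdr(spec.q, spec.beta, spec.m0_over_m1)
    z = norm.ppf(1 - spec.beta) + norm.ppf(1 - alpha / 2)
    j = (2 * spec.var_ptm + 2 * spec.var_protein) * z**2 / spec.delta_adj**2
    return max(MIN_REPLICATES, math.ceil(j))


def _se2(spec: PowerSpec, j_ptm: float, j_protein: float) -> float:
    return 2 * spec.var_ptm / j_ptm + 2 * spec.var_protein / j_protein


def solve_power(spec: PowerSpec) -> dict:
    """Achieved FDR q at fixed J' and the spec's beta.

    Solves the variance bound as an equality for the significance level
    and maps it back to the FDR.  Returns ``{"q": ..., "alpha": ...,
    "power": 1-beta, "boundary": bool}``; ``boundary=True`` flags specs
    whose bound cannot be met for any q in (0, 1).
    """
    if spec.j_fixed is None or spec.j_fixed < MIN_REPLICATES:
        raise ValueError("solve_power needs j_fixed >= 2")
    se = math.sqrt(_se2(spec, spec.j_fixed, spec.j_fixed))
    if se == 0:
        return {"q": 0.0, "alpha": 0.0, "power": 1 - spec.beta, "boundary": True}
    z_alpha_half = spec.delta_adj / se - norm.ppf(1 - spec.beta)
    if z_alpha_half <= 0:
        return {"q": 1.0, "alpha": 1.0, "power": 1 - spec.beta, "boundary": True}
    alpha = 2 * norm.sf(z_alpha_half)
    # invert alpha = (1-beta) q / (1 + (1-q) r) for q
    r = spec.m0_over_m1
    q = alpha * (1 + r) / ((1 - spec.beta) + alpha * r)
    boundary = not (0 < q < 1)
    return {"q": float(np.clip(q, 0.0, 1.0)), "alpha": float(alpha),
            "power": 1 - spec.beta, "boundary": boundary}


def power_at(
    spec: PowerSpec,
    j_ptm: float,
    j_protein: float,
    delta: float | None = None,
) -> float:
    """Power of detecting ``delta`` at the spec's FDR target.

    The per-test alpha depends on the attained power through the FDR
    relation, so the power solves a fixed point; a bracketing root search
    on g(beta) = beta - Phi(z_{1-alpha(beta)/2} - delta/se) is used.
    """
    d = spec.delta_adj if delta is None else delta
    se = math.sqrt(_se2(spec, j_ptm, j_protein))
    if se == 0:
        return 1.0

    def g(beta):
        alpha = alpha_from_fdr(spec.q, beta, spec.m0_over_m1)
        power = norm.sf(norm.ppf(1 - alpha / 2) - d / se)
        return beta - (1 - power)

    lo, hi = 1e-12, 1 - 1e-12
    if g(lo) >= 0:
        return 1.0
    if g(hi) <= 0:
        return 0.0
    beta = optimize.brentq(g, lo, hi, xtol=1e-12)
    return float(1 - beta)


def allocation_curves(spec: PowerSpec, j_ptm_grid, j_protein_grid) -> np.ndarray:
    """Power surface over unequal (enrichment, global) replicate counts.

    Entry [a, b] is the power at j_ptm_grid[a] enrichment replicates and
    j_protein_grid[b] global-profiling replicates per condition.
    """
    out = np.empty((len(j_ptm_grid), len(j_protein_grid)))
    for a, jp in enumerate(j_ptm_grid):
        for b, jg in enumerate(j_protein_grid):
            if jp <= 0 or jg <= 0:
                raise ValueError("replicate counts must be positive")
            out[a, b] = power_at(spec, jp, jg)
    return out
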