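"""Protein-level adjustment of PTM contrasts.

The observed change of a modified peptide confounds a change in modification
occupancy with a change in overall protein abundance.  The adjusted log2
fold change subtracts the protein-level contrast from the PTM-level
contrast,

    delta_adj = delta_PTM - delta_protein,

its standard error pools the two model fits, se_adj^2 = se_PTM^2 +
se_protein^2 (the two fits use disjoint features and are treated as
independent), and the degrees of freedom of the pooled variance come from
the Satterthwaite approximation.  Sites without a matching protein fit are
passed through untested against the protein and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .modeling import ComparisonResult


@dataclass
class AdjustedResult(ComparisonResult):
    """Protein-adjusted PTM contrast with its two components."""

    ptm: ComparisonResult | None = None
    protein: ComparisonResult | None = None


def satterthwaite_df(se1: float, df1: float, se2: float, df2: float) -> float:
    """Effective df of se1^2 + se2^2 by the Welch-Satterthwaite formula.

    When one component's variance is zero the df of the other component is
    returned (the exact limit of the formula).
    """
    v1, v2 = se1**2, se2**2
    if v1 == 0 and v2 == 0:
        return df1 + df2
    if v1 == 0:
        return df2
    if v2 == 0:
        return df1
    return (v1 + v2) ** 2 / (v1**2 / df1 + v2**2 / df2)


def adjust_contrast(ptm: ComparisonResult, protein: ComparisonResult) -> AdjustedResult:
    """Combine a PTM and a protein contrast into the adjusted test."""
    if ptm.contrast != protein.contrast:
        raise ValueError(
            f"contrast mismatch: {ptm.contrast} vs {protein.contrast}"
        )
    est = ptm.estimate - protein.estimate
    if not (np.isfinite(ptm.se) and np.isfinite(protein.se)):
        issue = ptm.issue or protein.issue or "inestimable"
        return AdjustedResult(
            ptm.target, "ADJUSTED", ptm.contrast, est, np.nan, np.nan,
            np.nan, np.nan, issue=issue, ptm=ptm, protein=protein,
        )
    se = float(np.sqrt(ptm.se**2 + protein.se**2))
    df = satterthwaite_df(ptm.se, ptm.df, protein.se, protein.df)
    if se == 0:
        t = np.inf if est != 0 else 0.0
        p = 0.0 if est != 0 else 1.0
    else:
        t = est / se
        p = float(2 * stats.t.sf(abs(t), df))
    return AdjustedResult(
        ptm.target, "ADJUSTED", ptm.contrast, float(est), se, float(df),
        float(t), p, ptm=ptm, protein=protein,
    )


def adjust_all(
    ptm_results: list[ComparisonResult],
    protein_results: list[ComparisonResult],
    correct: bool = True,
    family: str = "per_contrast",
) -> list[ComparisonResult]:
    """Adjust every PTM contrast that has a matching protein contrast.

    Results are joined on (protein accession, contrast).  Sites lacking
    global profiling information cannot be adjusted; their unadjusted PTM
    result is passed through with ``issue='no_protein_match'``.  BH
    correction is applied afterwards, by default one family per contrast
    (adjusted and passed-through results together).
    """
    prot_by_key = {
        (r.protein_id, r.contrast): r
        for r in protein_results
        if np.isfinite(r.estimate)
    }
    out: list[ComparisonResult] = []
    for r in ptm_results:
        prot = prot_by_key.get((r.protein_id, r.contrast))
        if prot is None or not np.isfinite(r.estimate):
            passthrough = ComparisonResult(
                r.target, r.label, r.contrast, r.estimate, r.se, r.df,
                r.tstat, r.pvalue, issue=r.issue or "no_protein_match",
            )
            out.append(passthrough)
        else:
            out.append(adjust_contrast(r, prot))
    if correct:
        apply_bh(out, family=family)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Missing entries are excluded from the family size and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def apply_bh(results: list[ComparisonResult], family: str = "per_contrast") -> None:
    """Fill ``adj_pvalue`` in place, one BH family per contrast (or global)."""
    if family not in ("per_contrast", "global"):
        raise ValueError(f"unknown BH family {family!r}")
    if family == "global":
        groups = {None: results}
    else:
        groups = {}
        for r in results:
            groups.setdefault(r.contrast, []).append(r)
    for members in groups.values():
        adj = bh_adjust([r.pvalue for r in members])
        for r, a in zip(members, adj):
            r.adj_pvalue = float(a) if np.isfinite(a) else np.nan
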