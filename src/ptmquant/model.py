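"""Top-level modeling interface.

:class:`PTMAdjustmentModel` is built from an enriched (modification-level)
and a global (protein-level) feature table; :meth:`PTMAdjustmentModel.fit`
summarizes, fits per-target models, performs the protein adjustment and BH
correction, and returns a :class:`PTMAdjustmentResults` holding the
per-site estimates, standard errors, degrees of freedom and p-values.

Example
-------
>>> from ptmquant import PTMAdjustmentModel, simulate
>>> enriched, global_, truth = simulate.simulate(simulate.sim1_config(seed=1))
>>> res = PTMAdjustmentModel(enriched, global_).fit()
>>> res.table.head()
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import dataio, design, modeling, summarize
from .adjust import adjust_all, apply_bh
from .modeling import all_pairwise, fit_all, results_to_frame, test_contrasts


class PTMAdjustmentModel:
    """Protein-adjusted differential PTM abundance model.

    Parameters
    ----------
    enriched : canonical feature table of modified features (enrichment
        runs).  Unmodified records are dropped with
        :func:`ptmquant.dataio.clean_enriched`.
    global_ : optional canonical feature table of unmodified features
        (global profiling runs).  Without it every site is tested
        unadjusted and flagged.
    contrasts : list of (condition, condition) pairs; all pairwise by
        default.
    """

    def __init__(
        self,
        enriched: pd.DataFrame,
        global_: pd.DataFrame | None = None,
        contrasts: list[tuple] | None = None,
    ):
        dataio.validate_feature_table(enriched)
        if (enriched["origin"] == "enriched").all():
            enriched = dataio.clean_enriched(enriched)
        self.enriched = enriched
        if global_ is not None:
            dataio.validate_feature_table(global_)
            global_ = global_[~global_["is_modified"]].reset_index(drop=True)
            if len(global_) == 0:
                global_ = None
        self.global_ = global_
        self.contrasts = contrasts

    @classmethod
    def from_files(
        cls,
        enriched_path,
        global_path=None,
        dialect: str = "generic_long",
        fasta=None,
        contrasts=None,
        **read_kw,
    ) -> "PTMAdjustmentModel":
        """Build the model from delimited feature tables on disk."""
        enriched = dataio.read_feature_table(
            enriched_path, dialect=dialect, origin="enriched", **read_kw
        )
        if fasta is not None:
            enriched = dataio.locate_sites(enriched, fasta)
        global_ = None
        if global_path is not None:
            global_ = dataio.read_feature_table(
                global_path, dialect=dialect, origin="global", **read_kw
            )
        return cls(enriched, global_, contrasts=contrasts)

    def fit(
        self,
        summarization: str = "median_polish",
        impute_protein: bool = False,
        moderate: bool = False,
        design_kind: str = "auto",
        bh_family: str = "per_contrast",
    ) -> "PTMAdjustmentResults":
        """Run summarization -> per-target models -> adjustment -> BH.

        Parameters
        ----------
        summarization : {"median_polish", "log_sum"}.
        impute_protein : AFT-impute missing values in the protein matrices
            before summarization (modified features are never imputed).
        moderate : empirical-Bayes moderation of the residual variances
            (off by default; the headline method is unmoderated).
        design_kind : {"auto", "oneway", "tmt_mixed"} model selection.
        """
        contrasts = self.contrasts or all_pairwise(self.enriched["condition"])
        ptm_sum = summarize.summarize_runs(self.enriched, method=summarization)
        ptm_fits = fit_all(ptm_sum, design=design_kind)
        prot_sum = prot_fits = None
        if self.global_ is not None:
            prot_sum = summarize.summarize_runs(
                self.global_, method=summarization, impute=impute_protein
            )
            prot_fits = fit_all(prot_sum, design=design_kind)
        if moderate:
            ptm_fits = modeling.moderate_variance(ptm_fits)
            if prot_fits is not None:
                prot_fits = modeling.moderate_variance(prot_fits)
        ptm_results = test_contrasts(ptm_fits, contrasts)
        if prot_fits is None:
            from dataclasses import replace

            results = [replace(r, issue=r.issue or "no_protein_match") for r in ptm_results]
            apply_bh(results, family=bh_family)
        else:
            prot_results = test_contrasts(prot_fits, contrasts)
            results = adjust_all(ptm_results, prot_results, family=bh_family)
        return PTMAdjustmentResults(
            self, results, ptm_sum, prot_sum, ptm_fits, prot_fits, contrasts
        )


class PTMAdjustmentResults:
    """Fitted results of a :class:`PTMAdjustmentModel`.

    Attributes
    ----------
    table : tidy frame with one row per (site, contrast): ``log2FC``,
        ``SE``, ``df``, ``tstat``, ``pvalue``, ``adj_pvalue``, ``issue``.
    ptm_summaries, protein_summaries : the run-level summaries used.
    ptm_fits, protein_fits : the per-target model fits.
    """

    def __init__(self, model, results, ptm_sum, prot_sum, ptm_fits, prot_fits, contrasts):
        self.model = model
        self.results = results
        self.table = results_to_frame(results)
        self.ptm_summaries = ptm_sum
        self.protein_summaries = prot_sum
        self.ptm_fits = ptm_fits
        self.protein_fits = prot_fits
        self.contrasts = contrasts

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        """Rows with BH-adjusted p-value at or below ``alpha``."""
        t = self.table
        return t[t["adj_pvalue"] <= alpha].reset_index(drop=True)

    def median_variances(self) -> tuple[float, float]:
        """Median residual variance of the PTM and protein fits.

        These are the natural inputs to power planning for a follow-up
        experiment with the same workflow.
        """
        ptm = np.nanmedian([f.resid_var for f in self.ptm_fits if f.estimable])
        if self.protein_fits:
            prot = np.nanmedian(
                [f.resid_var for f in self.protein_fits if f.estimable]
            )
        else:
            prot = np.nan
        return float(ptm), float(prot)

    def power_spec(self, **kw) -> design.PowerSpec:
        """A :class:`ptmquant.design.PowerSpec` seeded with the fitted
        median variances (contrast variance = 2 sigma^2 / J is handled by
        the design module; the spec stores the per-summary variances)."""
        var_ptm, var_prot = self.median_variances()
        kw.setdefault("var_ptm", var_ptm)
        kw.setdefault("var_protein", 0.0 if np.isnan(var_prot) else var_prot)
        return design.PowerSpec(**kw)

    def summary(self, alpha: float = 0.05) -> str:
        """Plain-text summary of the fit and the test outcomes."""
        t = self.table
        n_sites = t.loc[t["label"] != "PROTEIN", ["protein_id", "site_id"]].drop_duplicates().shape[0]
        lines = [
            "Protein-adjusted PTM differential abundance",
            "=" * 46,
            f"PTM sites tested:        {n_sites}",
            f"Contrasts:               {', '.join(f'{a}-{b}' for a, b in self.contrasts)}",
            f"Adjusted results:        {(t['label'] == 'ADJUSTED').sum()}",
            f"Unadjusted pass-through: {(t['issue'] == 'no_protein_match').sum()}",
            f"Inestimable/flagged:     {t['issue'].isin(['inestimable', 'single_condition']).sum()}",
            f"Significant at BH<= {alpha:g}: {(t['adj_pvalue'] <= alpha).sum()}",
        ]
        var_ptm, var_prot = self.median_variances()
        lines.append(f"Median residual variance (PTM):     {var_ptm:.4f}")
        if not np.isnan(var_prot):
            lines.append(f"Median residual variance (protein): {var_prot:.4f}")
        return "\n".join(lines)
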