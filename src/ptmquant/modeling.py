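"""Per-target statistical models on run-level summaries.

Each PTM site and each protein is modeled separately from its run summaries.
Label-free group-comparison designs use a one-way fixed-effects model
(condition means, pooled residual variance); multi-mixture TMT designs add a
random mixture intercept estimated by REML.  Contrasts of condition means
carry a standard error and degrees of freedom (residual df for the one-way
model, Satterthwaite df for the mixed model).  An optional empirical-Bayes
step shrinks the per-target residual variances toward a consensus prior, as
in limma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

VAR_FLOOR = 1e-12


@dataclass
class ModelFit:
    """Fitted per-target model.

    ``condition_means`` maps condition -> estimated mean log2 abundance;
    ``resid_var`` is the residual variance with ``resid_df`` degrees of
    freedom; ``mixture_var`` is the mixture (random intercept) variance for
    TMT designs.  ``design`` records which model was actually fit,
    including fallbacks.
    """

    target: tuple
    design: str  # oneway_fixed | tmt_mixed | fallback_oneway
    condition_means: dict
    condition_counts: dict
    resid_var: float
    resid_df: float
    mixture_var: float | None = None
    converged: bool = True
    n_runs: int = 0
    # mixed-model internals needed for Satterthwaite contrasts
    _mixed: dict | None = field(default=None, repr=False)

    @property
    def estimable(self) -> bool:
        return self.resid_df > 0 and np.isfinite(self.resid_var)


@dataclass
class ComparisonResult:
    """One tested contrast for one target."""

    target: tuple
    label: str  # PTM | PROTEIN | ADJUSTED
    contrast: tuple
    estimate: float
    se: float
    df: float
    tstat: float
    pvalue: float
    adj_pvalue: float = np.nan
    issue: str | None = None

    @property
    def protein_id(self) -> str:
        return self.target[1]

    @property
    def site_id(self):
        return self.target[2] if self.target[0] == "site" else None


def fit_oneway(summaries: pd.DataFrame, design: str = "oneway_fixed") -> ModelFit:
    """One-way fixed-effects fit: condition means and pooled residual variance.

    ``summaries`` must carry ``condition`` and ``value`` columns for a single
    target.  The residual df is sum_i (J_i - 1), i.e. I(J-1) in balanced
    designs; a fit where every condition has a single summary is returned
    with zero df and flagged inestimable downstream.
    """
    groups = summaries.groupby("condition")["value"]
    means = groups.mean().to_dict()
    counts = groups.size().to_dict()
    n = int(sum(counts.values()))
    ss = float(sum(((g - g.mean()) ** 2).sum() for _, g in groups))
    df = float(n - len(means))
    var = ss / df if df > 0 else np.nan
    target = summaries["_target"].iloc[0] if "_target" in summaries else ("target",)
    return ModelFit(
        target=target,
        design=design,
        condition_means=means,
        condition_counts=counts,
        resid_var=var,
        resid_df=df,
        n_runs=n,
    )


# ---------------------------------------------------------------------------
# TMT mixed model: y_imj = mu_i + Mixture_m + e_imj, Mixture ~ N(0, sigma_M^2)
# ---------------------------------------------------------------------------


def _reml_negloglik(theta, y, X, groups_idx):
    """-2x restricted log-likelihood (up to a constant) of the random-
    intercept model with theta = (sigma2, sigma2_M)."""
    s2, s2m = theta
    n = y.size
    Sigma = s2 * np.eye(n)
    for idx in groups_idx:
        Sigma[np.ix_(idx, idx)] += s2m
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        return np.inf
    logdet = 2 * np.log(np.diag(L)).sum()
    Si_y = np.linalg.solve(Sigma, y)
    Si_X = np.linalg.solve(Sigma, X)
    XtSiX = X.T @ Si_X
    sign, logdet_x = np.linalg.slogdet(XtSiX)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(XtSiX, X.T @ Si_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(Sigma, r))
    return logdet + logdet_x + quad


def _gls_beta_cov(theta, y, X, groups_idx):
    s2, s2m = theta
    n = y.size
    Sigma = s2 * np.eye(n)
    for idx in groups_idx:
        Sigma[np.ix_(idx, idx)] += s2m
    Si_X = np.linalg.solve(Sigma, X)
    XtSiX = X.T @ Si_X
    cov = np.linalg.inv(XtSiX)
    beta = cov @ (Si_X.T @ y)
    return beta, cov


def fit_tmt_mixed(summaries: pd.DataFrame) -> ModelFit:
    """REML fit of condition means with a random mixture intercept.

    Falls back to :func:`fit_oneway` (design ``fallback_oneway``) when only
    one mixture is present (the random intercept is confounded with the
    grand mean) or when the REML optimization fails.
    """
    mixtures = summaries["mixture_id"].dropna().unique()
    if len(mixtures) < 2:
        return replace(fit_oneway(summaries), design="fallback_oneway")

    conditions = sorted(summaries["condition"].unique())
    y = summaries["value"].to_numpy(dtype=float)
    X = np.column_stack(
        [(summaries["condition"] == c).to_numpy(dtype=float) for c in conditions]
    )
    groups_idx = [
        np.flatnonzero((summaries["mixture_id"] == m).to_numpy()) for m in mixtures
    ]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        return replace(fit_oneway(summaries), design="fallback_oneway")

    # method-of-moments start from the one-way residual variance
    ow = fit_oneway(summaries)
    s2_0 = ow.resid_var if ow.estimable else float(np.var(y)) or 1.0
    x0 = np.array([max(s2_0, 1e-6), max(s2_0 / 2, 1e-6)])
    res = optimize.minimize(
        _reml_negloglik,
        x0,
        args=(y, X, groups_idx),
        method="L-BFGS-B",
        bounds=[(1e-10, None), (0.0, None)],
    )
    if not res.success or not np.isfinite(res.fun):
        return replace(fit_oneway(summaries), design="fallback_oneway", converged=False)
    s2, s2m = res.x
    s2m = max(s2m, 0.0)
    beta, cov = _gls_beta_cov((s2, s2m), y, X, groups_idx)
    means = dict(zip(conditions, beta))
    counts = summaries.groupby("condition").size().to_dict()
    return ModelFit(
        target=summaries["_target"].iloc[0] if "_target" in summaries else ("target",),
        design="tmt_mixed",
        condition_means=means,
        condition_counts=counts,
        resid_var=float(s2),
        resid_df=float(y.size - len(conditions)),
        mixture_var=float(s2m),
        converged=True,
        n_runs=int(y.size),
        _mixed={
            "y": y,
            "X": X,
            "groups_idx": groups_idx,
            "theta": np.array([s2, s2m]),
            "conditions": conditions,
            "cov": cov,
        },
    )


def _satterthwaite_df_mixed(fit: ModelFit, c: np.ndarray) -> float:
    """Delta-method Satterthwaite df for contrast c of a mixed fit.

    df = 2 var_c^2 / (g' H^{-1} g) with g the gradient of var_c(theta) and
    H the observed REML information, both by central finite differences.
    """
    m = fit._mixed
    y, X, gidx, theta = m["y"], m["X"], m["groups_idx"], m["theta"]
    n, p = X.shape

    if theta[1] <= 1e-8:
        # variance component at the boundary: the model degenerates to
        # one-way; use its residual df
        return float(n - p)

    def var_c(th):
        _, cov = _gls_beta_cov(th, y, X, gidx)
        return float(c @ cov @ c)

    v0 = var_c(theta)
    h = np.maximum(np.abs(theta), 1e-6) * 1e-4
    g = np.zeros(2)
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h[k]
        tm[k] = max(tm[k] - h[k], 1e-12)
        g[k] = (var_c(tp) - var_c(tm)) / (tp[k] - tm[k])

    def nll(th):
        return 0.5 * _reml_negloglik(np.maximum(th, 1e-12), y, X, gidx)

    e = np.eye(2)
    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            H[i, j] = (
                nll(theta + h[i] * e[i] + h[j] * e[j])
                - nll(theta + h[i] * e[i] - h[j] * e[j])
                - nll(theta - h[i] * e[i] + h[j] * e[j])
                + nll(theta - h[i] * e[i] - h[j] * e[j])
            ) / (4 * h[i] * h[j])
    try:
        Hinv = np.linalg.inv(H)
        var_var = float(g @ Hinv @ g)
    except np.linalg.LinAlgError:
        var_var = np.nan
    if not np.isfinite(var_var) or var_var <= 0:
        return float(n - p)
    df = 2 * v0**2 / var_var
    return float(np.clip(df, 1.0, n - 1))


def estimate_contrast(fit: ModelFit, pair: tuple) -> ComparisonResult:
    """Test the difference of two condition means, ``pair = (i, i')``.

    Returns estimate, SE, df and a two-sided Student-t p-value.  Conditions
    absent from the fit yield ``issue='single_condition'``; fits without an
    estimable residual variance yield ``issue='inestimable'``.
    """
    ci, cj = pair
    label = "PTM" if fit.target[0] == "site" else "PROTEIN"
    if ci not in fit.condition_means or cj not in fit.condition_means:
        return ComparisonResult(
            fit.target, label, pair, np.nan, np.nan, np.nan, np.nan, np.nan,
            issue="single_condition",
        )
    est = fit.condition_means[ci] - fit.condition_means[cj]
    if not fit.estimable:
        return ComparisonResult(
            fit.target, label, pair, est, np.nan, np.nan, np.nan, np.nan,
            issue="inestimable",
        )
    if fit.design == "tmt_mixed" and fit._mixed is not None:
        conditions = fit._mixed["conditions"]
        c = np.zeros(len(conditions))
        c[conditions.index(ci)] = 1.0
        c[conditions.index(cj)] = -1.0
        se2 = float(c @ fit._mixed["cov"] @ c)
        df = _satterthwaite_df_mixed(fit, c)
    else:
        ji, jj = fit.condition_counts[ci], fit.condition_counts[cj]
        se2 = fit.resid_var * (1.0 / ji + 1.0 / jj)
        df = fit.resid_df
    if se2 < VAR_FLOOR:
        # zero residual variance: infinite-t convention
        if abs(est) > 0:
            warnings.warn("zero variance with nonzero estimate; p set to 0")
            return ComparisonResult(fit.target, label, pair, est, 0.0, df, np.inf, 0.0)
        return ComparisonResult(fit.target, label, pair, est, 0.0, df, 0.0, 1.0)
    se = float(np.sqrt(se2))
    t = est / se
    p = float(2 * stats.t.sf(abs(t), df))
    return ComparisonResult(fit.target, label, pair, float(est), se, float(df), float(t), p)


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation (limma-style)
# ---------------------------------------------------------------------------


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Fit the scaled inverse-chi-square prior (d0, s0^2) by marginal ML.

    Marginally, each sample variance follows s2 ~ s0^2 F(df, d0).  Returns
    (d0, s0sq); d0 = inf when the variances are (nearly) identical.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.asarray(df, dtype=float)
    keep = (df > 0) & (s2 > 0) & np.isfinite(s2)
    s2, df = s2[keep], df[keep]
    if s2.size < 2 or np.allclose(s2, s2[0], rtol=1e-12):
        return np.inf, float(s2.mean()) if s2.size else np.nan

    def nll(params):
        log_d0, log_s0 = params
        d0 = np.exp(log_d0)
        s0sq = np.exp(log_s0)
        return -np.sum(stats.f.logpdf(s2 / s0sq, df, d0) - np.log(s0sq))

    x0 = np.array([np.log(4.0), np.log(np.median(s2))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    d0 = float(np.exp(res.x[0]))
    s0sq = float(np.exp(res.x[1]))
    if d0 > 1e6:
        # effectively a point prior
        return np.inf, float(np.sum(df * s2) / np.sum(df))
    return d0, s0sq


def moderate_variance(fits: list[ModelFit]) -> list[ModelFit]:
    """Shrink residual variances toward the fitted consensus prior.

    Each fit's residual variance becomes the posterior mean
    ``(d0*s0^2 + df*s^2) / (d0 + df)`` and its residual df gains d0.
    Fits without positive residual df are passed through untouched.
    """
    est = [(i, f) for i, f in enumerate(fits) if f.resid_df > 0 and np.isfinite(f.resid_var)]
    if len(est) < 2:
        return list(fits)
    s2 = np.array([f.resid_var for _, f in est])
    df = np.array([f.resid_df for _, f in est])
    d0, s0sq = fit_variance_prior(s2, df)
    out = list(fits)
    for (i, f), v, d in zip(est, s2, df):
        if np.isinf(d0):
            new_var, new_df = s0sq, np.inf
        else:
            new_var = (d0 * s0sq + d * v) / (d0 + d)
            new_df = d + d0
        out[i] = replace(f, resid_var=float(new_var), resid_df=float(new_df))
    return out


# ---------------------------------------------------------------------------
# Fitting over whole summary tables
# ---------------------------------------------------------------------------


def _iter_targets(summaries: pd.DataFrame):
    site_rows = summaries[summaries["target_type"] == "site"]
    for (protein, site), sub in site_rows.groupby(["protein_id", "site_id"], sort=True):
        yield ("site", protein, site), sub
    prot_rows = summaries[summaries["target_type"] == "protein"]
    for protein, sub in prot_rows.groupby("protein_id", sort=True):
        yield ("protein", protein), sub


def fit_all(summaries: pd.DataFrame, design: str = "auto") -> list[ModelFit]:
    """Fit every target in a run-summary frame.

    ``design='auto'`` uses the mixed model when more than one mixture is
    annotated and the one-way model otherwise.
    """
    fits = []
    for target, sub in _iter_targets(summaries):
        sub = sub.assign(_target=[target] * len(sub))
        use_mixed = design == "tmt_mixed" or (
            design == "auto" and sub["mixture_id"].dropna().nunique() > 1
        )
        fit = fit_tmt_mixed(sub) if use_mixed else fit_oneway(sub)
        fits.append(fit)
    return fits


def all_pairwise(conditions) -> list[tuple]:
    conds = sorted(set(conditions))
    return [(b, a) for i, a in enumerate(conds) for b in conds[i + 1 :]]


def test_contrasts(fits: list[ModelFit], contrasts: list[tuple]) -> list[ComparisonResult]:
    """Apply :func:`estimate_contrast` to every fit x contrast pair."""
    return [estimate_contrast(f, pair) for f in fits for pair in contrasts]


def fit_baseline(
    method: str,
    summaries: pd.DataFrame,
    contrasts: list[tuple] | None = None,
) -> list[ComparisonResult]:
    """Baseline competitor fits on precomputed summaries.

    ``anova_unadj``/``limma_unadj`` expect log-sum site summaries;
    ``anova_ratio``/``limma_ratio`` expect the per-run modified-minus-
    unmodified differences from :func:`ptmquant.summarize.ratio_summaries`.
    The limma variants moderate the residual variances across targets
    before testing.  BH correction is left to the caller (one family per
    contrast).
    """
    if method not in ("anova_unadj", "anova_ratio", "limma_unadj", "limma_ratio"):
        raise ValueError(f"unknown baseline {method!r}")
    fits = fit_all(summaries, design="oneway")
    if method.startswith("limma"):
        fits = moderate_variance(fits)
    if contrasts is None:
        contrasts = all_pairwise(summaries["condition"])
    return test_contrasts(fits, contrasts)


def results_to_frame(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flatten comparison results into a tidy frame."""
    rows = []
    for r in results:
        rows.append(
            {
                "protein_id": r.protein_id,
                "site_id": r.site_id,
                "label": r.label,
                "contrast": f"{r.contrast[0]}-{r.contrast[1]}",
                "log2FC": r.estimate,
                "SE": r.se,
                "df": r.df,
                "tstat": r.tstat,
                "pvalue": r.pvalue,
                "adj_pvalue": r.adj_pvalue,
                "issue": r.issue,
            }
        )
    return pd.DataFrame(rows)
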