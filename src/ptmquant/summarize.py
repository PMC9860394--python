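"""Run-level summarization of feature intensities.

Collapses the feature x run/channel matrix of each target (a PTM site or a
protein) into one log2 abundance per run, either robustly by Tukey's two-way
median polish or by log-sum (log2 of the summed linear-scale intensities).
Also provides the replicate-wise log-ratio used by ratio-based baseline
methods and an optional censored-regression (accelerated failure time)
imputation of missing intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

SUMMARY_COLUMNS = [
    "target_type",  # "site" or "protein"
    "protein_id",
    "site_id",
    "run_id",
    "channel",
    "condition",
    "mixture_id",
    "replicate_id",
    "value",
    "n_features",
    "method",
]


def log_sum(values) -> float:
    """Summarize by summing intensities on the linear scale: log2(sum 2^y).

    Missing entries are ignored; returns NaN if nothing is observed.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return np.nan
    # subtract the max for numerical stability on large log2 values
    m = v.max()
    return m + np.log2(np.exp2(v - m).sum())


summarize_log_sum = log_sum


@dataclass
class MedianPolishFit:
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iter: int


def median_polish(
    matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-4
) -> MedianPolishFit:
    """Tukey's two-way median polish with missing-cell support.

    Alternately sweeps row and column medians (NaN-aware) out of the
    residual matrix, accumulating an overall effect, row effects and column
    effects.  Stops after ``max_iter`` sweeps or when the total absolute
    residual changes by less than ``tol`` times itself.
    """
    z = np.array(matrix, dtype=float)
    if z.ndim != 2 or z.size == 0:
        raise ValueError("median_polish expects a non-empty 2-d matrix")
    nrow, ncol = z.shape
    overall = 0.0
    row = np.zeros(nrow)
    col = np.zeros(ncol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        last = np.nansum(np.abs(z))
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            rmed = np.nanmedian(z, axis=1)
            rmed = np.where(np.isfinite(rmed), rmed, 0.0)
            z -= rmed[:, None]
            row += rmed
            cdelta = np.nanmedian(row)
            row -= cdelta
            overall += cdelta

            cmed = np.nanmedian(z, axis=0)
            cmed = np.where(np.isfinite(cmed), cmed, 0.0)
            z -= cmed[None, :]
            col += cmed
            rdelta = np.nanmedian(col)
            col -= rdelta
            overall += rdelta

            total = np.nansum(np.abs(z))
            if total < tol * last or total < 1e-12:
                converged = True
                break
            last = total
    return MedianPolishFit(overall, row, col, z, converged, it)


def median_polish_summarize(matrix: pd.DataFrame) -> pd.Series:
    """Per-run summaries from a feature (rows) x run (columns) matrix.

    The run summary is overall effect + column effect; columns with no
    observed value yield no summary.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        return pd.Series(dtype=float)
    fit = median_polish(matrix.to_numpy(dtype=float))
    values = fit.overall + fit.col_effects
    observed = np.isfinite(matrix.to_numpy(dtype=float)).any(axis=0)
    return pd.Series(values, index=matrix.columns, dtype=float)[observed]


def log_sum_summarize(matrix: pd.DataFrame) -> pd.Series:
    """Per-run log-sum summaries of a feature x run matrix."""
    arr = matrix.to_numpy(dtype=float)
    observed = np.isfinite(arr).any(axis=0)
    vals = pd.Series(
        [log_sum(arr[:, j]) for j in range(arr.shape[1])],
        index=matrix.columns,
        dtype=float,
    )
    return vals[observed]


def ratio_summarize(mod_values, unmod_values) -> float:
    """Replicate-wise log2 ratio of summed modified over unmodified intensity.

    Equals ``log_sum(mod) - log_sum(unmod)``; NaN if either side is entirely
    missing (that run is then lost to ratio-based methods).
    """
    return log_sum(mod_values) - log_sum(unmod_values)


def group_targets(table: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    """Group features by summarization target.

    Modified features group by (protein, site); peptides carrying several
    modified residues keep their composite site key and are never merged
    into the single-site groups.  Unmodified features group by protein.

    Returns a map from ``("site", protein_id, site_id)`` or
    ``("protein", protein_id)`` to the records of that target.
    """
    out: dict[tuple, pd.DataFrame] = {}
    if len(table) == 0:
        return out
    mod = table[table["is_modified"]]
    for (protein, site), sub in mod.groupby(["protein_id", "site_id"], sort=True):
        out[("site", protein, site)] = sub
    unmod = table[~table["is_modified"]]
    for protein, sub in unmod.groupby("protein_id", sort=True):
        out[("protein", protein)] = sub
    return out


def _run_key(df: pd.DataFrame) -> pd.Series:
    """Composite run/channel key: the columns of the polish matrix."""
    ch = df["channel"].astype(object)
    key = df["run_id"].astype(str)
    has_ch = ch.notna()
    if has_ch.any():
        key = key.where(~has_ch, key + "::" + ch.astype(str))
    return key


def summarize_runs(
    table: pd.DataFrame,
    method: str = "median_polish",
    impute: bool = False,
) -> pd.DataFrame:
    """Summarize every target in a feature table into run-level abundances.

    Parameters
    ----------
    table : canonical feature table (one origin).
    method : {"median_polish", "log_sum"}.
    impute : apply AFT imputation to each target's matrix before
        summarization.  Intended for unmodified-protein tables; off by
        default so that results are imputation-free unless requested.

    Returns a run-summary frame (see ``SUMMARY_COLUMNS``) with one row per
    (target, run, channel) having at least one observed feature.
    """
    if method not in ("median_polish", "log_sum"):
        raise ValueError(f"unknown summarization method {method!r}")
    # run/channel -> design metadata, taken from the input records
    rc = _run_key(table)
    rc_codes, rc_levels = pd.factorize(rc, sort=True)
    meta = (
        table.assign(_rc=rc)[
            ["_rc", "run_id", "channel", "condition", "mixture_id", "replicate_id"]
        ]
        .drop_duplicates("_rc")
        .set_index("_rc")
        .loc[rc_levels]
    )
    n_rc = len(rc_levels)
    work = table[["feature_id", "log2_intensity"]].assign(_rc_code=rc_codes)

    parts = []
    for key, records in group_targets(work.join(_target_cols(table))).items():
        feat_codes, feats = pd.factorize(records["feature_id"], sort=True)
        matrix = np.full((len(feats), n_rc), np.nan)
        matrix[feat_codes, records["_rc_code"].to_numpy()] = records[
            "log2_intensity"
        ].to_numpy(dtype=float)
        if impute:
            matrix = (
                impute_aft(pd.DataFrame(matrix)).to_numpy()
                if np.isnan(matrix).any()
                else matrix
            )
        observed = np.isfinite(matrix)
        keep = observed.any(axis=0)
        if not keep.any():
            continue
        if method == "median_polish":
            fit = median_polish(matrix)
            values = fit.overall + fit.col_effects
        else:
            shifted = np.exp2(matrix - 20.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                values = 20.0 + np.log2(np.nansum(shifted, axis=0))
        target_type, protein = key[0], key[1]
        site = key[2] if target_type == "site" else np.nan
        part = meta.iloc[keep.nonzero()[0]].reset_index(drop=True)
        part.insert(0, "target_type", target_type)
        part.insert(1, "protein_id", protein)
        part.insert(2, "site_id", site)
        part["value"] = values[keep]
        part["n_features"] = observed.sum(axis=0)[keep]
        part["method"] = method
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=SUMMARY_COLUMNS)
    return pd.concat(parts, ignore_index=True)[SUMMARY_COLUMNS]


def _target_cols(table: pd.DataFrame) -> pd.DataFrame:
    return table[["protein_id", "site_id", "is_modified"]]


def ratio_summaries(
    ptm_summaries: pd.DataFrame, protein_summaries: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Per-run modified-minus-unmodified differences for ratio baselines.

    Joins site-level and protein-level run summaries on (protein, run,
    channel); runs present on only one side are discarded, and the discard
    fractions (relative to each side's available summaries) are returned as
    a loss accounting dict.
    """
    on = ["protein_id", "run_id", "channel"]
    left = ptm_summaries.rename(columns={"value": "value_ptm"})
    right = protein_summaries.rename(columns={"value": "value_protein"})[
        on + ["value_protein"]
    ]
    merged = left.merge(right, on=on, how="inner")
    merged["value"] = merged["value_ptm"] - merged["value_protein"]
    merged["method"] = "ratio"

    # protein summaries with no same-run PTM summary, and vice versa
    ptm_runs = ptm_summaries[on].drop_duplicates()
    n_prot = len(protein_summaries)
    n_ptm = len(ptm_summaries)
    prot_matched = protein_summaries.merge(ptm_runs, on=on, how="inner")
    prot_runs = protein_summaries[on].drop_duplicates()
    ptm_matched = ptm_summaries.merge(prot_runs, on=on, how="inner")
    loss = {
        "protein_summaries": n_prot,
        "ptm_summaries": n_ptm,
        "protein_discarded": n_prot - len(prot_matched),
        "ptm_discarded": n_ptm - len(ptm_matched),
        "protein_discard_fraction": (n_prot - len(prot_matched)) / n_prot
        if n_prot
        else 0.0,
        "ptm_discard_fraction": (n_ptm - len(ptm_matched)) / n_ptm if n_ptm else 0.0,
    }
    cols = [c for c in SUMMARY_COLUMNS if c != "value"] + ["value"]
    return merged[cols], loss


def impute_aft(matrix: pd.DataFrame, enabled: bool = True) -> pd.DataFrame:
    """Impute missing cells by a censored Gaussian two-way regression.

    Missing intensities are treated as left-censored at the feature's
    observed minimum (an accelerated-failure-time model on the log2 scale:
    absent features are assumed at or below the lowest level at which they
    were ever observed).  A model with feature and run effects and Gaussian
    error is fit by maximum likelihood over observed (density) and censored
    (CDF) cells; missing cells are replaced by the model prediction capped
    at the censoring bound.

    Cells that cannot be predicted (a run or feature with no observations)
    are left missing with a warning.
    """
    if not enabled:
        return matrix
    arr = matrix.to_numpy(dtype=float)
    obs = np.isfinite(arr)
    if obs.all() or not obs.any():
        return matrix
    nrow, ncol = arr.shape
    row_has = obs.any(axis=1)
    col_has = obs.any(axis=0)
    if not row_has.all() or not col_has.all():
        warnings.warn("rows/runs with no observations left unimputed")
    ri, ci = np.where(obs)
    mi_r, mi_c = np.where(~obs & row_has[:, None] & col_has[None, :])
    if mi_r.size == 0:
        return matrix
    # censoring bound: each feature's observed minimum
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_min = np.nanmin(arr, axis=1)

    # parameters: mu, row effects (rows 1..), col effects (cols 1..), log sigma
    def unpack(theta):
        mu = theta[0]
        a = np.concatenate([[0.0], theta[1:nrow]])
        b = np.concatenate([[0.0], theta[nrow : nrow + ncol - 1]])
        sigma = np.exp(theta[-1])
        return mu, a, b, sigma

    y_obs = arr[ri, ci]
    cens = row_min[mi_r]

    def negloglik(theta):
        mu, a, b, sigma = unpack(theta)
        pred_o = mu + a[ri] + b[ci]
        ll = stats.norm.logpdf(y_obs, pred_o, sigma).sum()
        pred_c = mu + a[mi_r] + b[mi_c]
        ll += stats.norm.logcdf(cens, pred_c, sigma).sum()
        return -ll

    theta0 = np.zeros(nrow + ncol)
    theta0[0] = y_obs.mean()
    theta0[-1] = np.log(max(y_obs.std(), 0.1))
    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B")
    mu, a, b, _ = unpack(res.x)
    out = arr.copy()
    out[mi_r, mi_c] = np.minimum(mu + a[mi_r] + b[mi_c], cens)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
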