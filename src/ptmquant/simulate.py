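"""Ground-truth simulators and benchmark harness.

Two synthetic study designs emulate label-free group-comparison PTM
experiments with known ground truth:

* the *clean* design: 1000 proteins, one PTM site each, 10 modified and 10
  unmodified features per target, no missing values;
* the *noisy* design: 2 modified features per PTM, 10 unmodified features,
  and 20% of observations missing completely at random.

Each protein belongs to one of four equally sized truth classes describing
how the observed PTM change decomposes into modification occupancy and
protein abundance:

``diff_direct``
    the modified features shift by the effect, the protein is flat
    (adjusted change = effect);
``diff_masked``
    the observed modified features are flat because the protein shifts by
    minus the effect (adjusted change = effect, invisible without
    adjustment);
``null_flat``
    nothing changes;
``null_protein_driven``
    modified features and protein both shift by the effect (adjusted
    change = 0 -- the confounding scenario that inflates unadjusted
    analyses).

Feature observations add iid Gaussian noise on the log2 scale to the
deterministic abundances.  The benchmark runner pushes each simulated
dataset through the protein-adjusted pipeline and through ratio- and
summary-based ANOVA/limma baselines, and scores empirical FDR, accuracy,
recall and fold-change error against the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import modeling, summarize
from .adjust import adjust_all, apply_bh
from .modeling import ComparisonResult, fit_all, results_to_frame, test_contrasts

TRUTH_CLASSES = ("diff_direct", "diff_masked", "null_flat", "null_protein_driven")
DIFF_CLASSES = frozenset({"diff_direct", "diff_masked"})

METHODS = (
    "msstatsptm_adj",
    "msstatsptm_unadj",
    "anova_adj",
    "anova_unadj",
    "limma_adj",
    "limma_unadj",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated dataset.

    Defaults are the clean design; :func:`sim2_config` switches to the
    noisy design (2 modified features, 20% missingness).
    """

    n_proteins: int = 1000
    n_conditions: int = 2
    n_replicates: int = 10
    n_mod_features: int = 10
    n_unmod_features: int = 10
    sigma2: float = 0.2
    effect: float = 0.75
    missing_rate: float = 0.0
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    feature_sd: float = 1.0
    masked_sign: int = -1  # direction of the protein shift masking the PTM
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0 or self.n_mod_features <= 0 or self.n_unmod_features <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        if self.n_conditions < 2 or self.n_replicates < 1:
            raise ValueError("need >=2 conditions and >=1 replicate")


def sim1_config(**kw) -> SimConfig:
    """Clean design: 10 modified features, no missing values."""
    return SimConfig(**kw)


def sim2_config(**kw) -> SimConfig:
    """Noisy design: 2 modified features, 20% MCAR missingness."""
    kw.setdefault("n_mod_features", 2)
    kw.setdefault("missing_rate", 0.20)
    return SimConfig(**kw)


def sim1_grid(sigma2=(0.2, 0.3), conditions=(2, 3, 4), replicates=(2, 3, 5, 10), **kw):
    """The full 24-dataset clean-design grid."""
    return [
        sim1_config(n_conditions=i, n_replicates=j, sigma2=s, **kw)
        for s in sigma2
        for i in conditions
        for j in replicates
    ]


def sim2_grid(sigma2=(0.2, 0.3), conditions=(2, 3, 4), replicates=(2, 3, 5, 10), **kw):
    """The full 24-dataset noisy-design grid."""
    return [
        sim2_config(n_conditions=i, n_replicates=j, sigma2=s, **kw)
        for s in sigma2
        for i in conditions
        for j in replicates
    ]


def _truth_classes(n: int) -> np.ndarray:
    idx = (np.arange(n) * len(TRUTH_CLASSES)) // n
    return np.array(TRUTH_CLASSES, dtype=object)[idx]


def _feature_frame(values, mask_missing, proteins, feat_tag, modified):
    """Flatten a (protein, feature, condition, replicate) value array."""
    n, k, i, j = values.shape
    vals = values.reshape(-1)
    vals = np.where(mask_missing.reshape(-1), np.nan, vals)
    prot = np.repeat(proteins, k * i * j)
    feat = np.tile(np.repeat(np.arange(k), i * j), n)
    cond = np.tile(np.repeat(np.arange(i), j), n * k)
    rep = np.tile(np.arange(j), n * k * i)
    peptide = np.char.add(
        np.char.add(prot.astype(str), f"_{feat_tag}"), feat.astype(str)
    )
    cond_lab = np.char.add("C", (cond + 1).astype(str))
    run_lab = np.char.add(np.char.add(cond_lab, "R"), (rep + 1).astype(str))
    df = pd.DataFrame(
        {
            "protein_id": prot,
            "site_id": "S1" if modified else np.nan,
            "peptide": peptide,
            "charge": 2,
            "feature_id": np.char.add(peptide, "/2"),
            "run_id": run_lab,
            "condition": cond_lab,
            "mixture_id": np.nan,
            "channel": np.nan,
            "replicate_id": run_lab,
            "log2_intensity": vals,
            "is_modified": modified,
            "origin": "enriched" if modified else "global",
        }
    )
    return df


def simulate(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one dataset: (enriched table, global table, truth table).

    Deterministic given ``config.seed``.  The truth table records, per
    protein, the class and the true observed-PTM, protein and adjusted
    log2 fold changes for any contrast of condition 1 against another
    condition (effects are applied between condition 1 and each of the
    others).
    """
    rng = np.random.default_rng(config.seed)
    n, I, J = config.n_proteins, config.n_conditions, config.n_replicates
    K, L = config.n_mod_features, config.n_unmod_features
    classes = _truth_classes(n)

    base = rng.normal(config.baseline_mean, config.baseline_sd, n)
    mod_off = rng.normal(0.0, config.feature_sd, (n, K))
    unmod_off = rng.normal(0.0, config.feature_sd, (n, L))

    eff = config.effect
    ptm_shift = np.zeros((n, I))
    prot_shift = np.zeros((n, I))
    ptm_shift[classes == "diff_direct", 1:] = eff
    prot_shift[classes == "diff_masked", 1:] = config.masked_sign * eff
    ptm_shift[classes == "null_protein_driven", 1:] = eff
    prot_shift[classes == "null_protein_driven", 1:] = eff

    sd = np.sqrt(config.sigma2)
    proteins = np.array([f"P{p:04d}" for p in range(n)], dtype=object)

    y_mod = (
        base[:, None, None, None]
        + mod_off[:, :, None, None]
        + ptm_shift[:, None, :, None]
        + rng.normal(0.0, sd, (n, K, I, J))
    )
    y_unmod = (
        base[:, None, None, None]
        + unmod_off[:, :, None, None]
        + prot_shift[:, None, :, None]
        + rng.normal(0.0, sd, (n, L, I, J))
    )
    miss_mod = rng.random((n, K, I, J)) < config.missing_rate
    miss_unmod = rng.random((n, L, I, J)) < config.missing_rate

    enriched = _feature_frame(y_mod, miss_mod, proteins, "mod", True)
    global_ = _feature_frame(y_unmod, miss_unmod, proteins, "unmod", False)

    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "site_id": "S1",
            "truth_class": classes,
            "true_delta_ptm_observed": ptm_shift[:, 1] if I > 1 else 0.0,
            "true_delta_protein": prot_shift[:, 1] if I > 1 else 0.0,
        }
    )
    truth["true_delta_adj"] = (
        truth["true_delta_ptm_observed"] - truth["true_delta_protein"]
    )
    return enriched, global_, truth


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionMetrics:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def accuracy(self) -> float:
        tot = self.TP + self.TN + self.FP + self.FN
        return (self.TP + self.TN) / tot if tot else 0.0

    @property
    def recall(self) -> float:
        pos = self.TP + self.FN
        return self.TP / pos if pos else 0.0

    @property
    def efdr(self) -> float:
        called = self.TP + self.FP
        return self.FP / called if called else 0.0


def evaluate(
    results: list[ComparisonResult] | pd.DataFrame,
    truth: pd.DataFrame,
    alpha: float = 0.05,
    contrast: str = "C2-C1",
) -> ConfusionMetrics:
    """Score calls at BH-adjusted p <= alpha against the ground truth.

    Truth positives are the two differential classes.  PTMs with no
    testable result (missing, inestimable, NaN p-value) count as negative
    calls.
    """
    if isinstance(results, pd.DataFrame):
        frame = results
    else:
        frame = results_to_frame(results)
    frame = frame[frame["contrast"] == contrast]
    called = frame.loc[frame["adj_pvalue"] <= alpha, "protein_id"]
    called_set = set(called)
    truth_pos = truth["truth_class"].isin(DIFF_CLASSES).to_numpy()
    is_called = truth["protein_id"].isin(called_set).to_numpy()
    tp = int((truth_pos & is_called).sum())
    fp = int((~truth_pos & is_called).sum())
    fn = int((truth_pos & ~is_called).sum())
    tn = int((~truth_pos & ~is_called).sum())
    return ConfusionMetrics(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# Analysis pipelines
# ---------------------------------------------------------------------------


def analyze(
    enriched: pd.DataFrame,
    global_: pd.DataFrame | None,
    method: str = "msstatsptm_adj",
    contrasts: list[tuple] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run one full analysis method on feature tables.

    Returns (results frame, loss accounting).  ``msstatsptm_*`` methods use
    median-polish summaries and the protein adjustment; ``*_adj`` baselines
    use the per-run ratio summaries; ``*_unadj`` baselines test the PTM
    summaries directly.  limma variants add empirical-Bayes variance
    moderation.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if contrasts is None:
        contrasts = modeling.all_pairwise(enriched["condition"])
    loss: dict = {}

    if method.startswith("msstatsptm"):
        ptm_sum = summarize.summarize_runs(enriched, method="median_polish")
        ptm_results = test_contrasts(fit_all(ptm_sum, design="auto"), contrasts)
        if method == "msstatsptm_unadj" or global_ is None or len(global_) == 0:
            results = [
                replace(r, issue=r.issue or ("no_protein_match" if method == "msstatsptm_adj" else None))
                for r in ptm_results
            ]
            apply_bh(results)
        else:
            prot_sum = summarize.summarize_runs(global_, method="median_polish")
            prot_results = test_contrasts(fit_all(prot_sum, design="auto"), contrasts)
            results = adjust_all(ptm_results, prot_results)
        return results_to_frame(results), loss

    moderate = method.startswith("limma")
    ptm_sum = summarize.summarize_runs(enriched, method="log_sum")
    if method.endswith("_adj"):
        if global_ is None or len(global_) == 0:
            raise ValueError("ratio-based baselines require a global table")
        prot_sum = summarize.summarize_runs(global_, method="log_sum")
        ratios, loss = summarize.ratio_summaries(ptm_sum, prot_sum)
        input_sum = ratios
        label = "ADJUSTED"
    else:
        input_sum = ptm_sum
        label = "PTM"
    fits = fit_all(input_sum, design="oneway")
    if moderate:
        fits = modeling.moderate_variance(fits)
    results = test_contrasts(fits, contrasts)
    results = [replace(r, label=label) for r in results]
    apply_bh(results)
    return results_to_frame(results), loss


# ---------------------------------------------------------------------------
# Benchmark runner
# ---------------------------------------------------------------------------


def fold_change_stats(frame: pd.DataFrame, truth: pd.DataFrame, contrast: str = "C2-C1") -> dict:
    """Bias and IQR of estimated fold changes among truly differential PTMs."""
    diff = truth[truth["truth_class"].isin(DIFF_CLASSES)]
    sub = frame[(frame["contrast"] == contrast) & frame["protein_id"].isin(set(diff["protein_id"]))]
    est = sub["log2FC"].dropna()
    if est.empty:
        return {"fc_mean": np.nan, "fc_bias": np.nan, "fc_iqr": np.nan, "fc_n": 0}
    true_adj = diff["true_delta_adj"].iloc[0]
    q75, q25 = np.percentile(est, [75, 25])
    return {
        "fc_mean": float(est.mean()),
        "fc_bias": float(est.mean() - true_adj),
        "fc_iqr": float(q75 - q25),
        "fc_n": int(est.size),
    }


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Independent per-dataset substream seeds from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def run_benchmark(
    configs: list[SimConfig],
    methods=METHODS,
    alpha: float = 0.05,
    master_seed: int | None = None,
) -> pd.DataFrame:
    """Simulate every config, analyze with every method, score everything.

    If ``master_seed`` is given, per-config seeds are derived from it,
    overriding the configs' own seeds.  Returns one row per
    (config, method) with confusion metrics, fold-change error summaries
    and, for ratio baselines, the fraction of run summaries discarded by
    one-sided missingness.
    """
    if master_seed is not None:
        seeds = spawn_seeds(master_seed, len(configs))
        configs = [replace(c, seed=s) for c, s in zip(configs, seeds)]
    rows = []
    for cfg in configs:
        enriched, global_, truth = simulate(cfg)
        contrasts = [("C2", "C1")]
        for method in methods:
            frame, loss = analyze(enriched, global_, method, contrasts)
            cm = evaluate(frame, truth, alpha=alpha)
            row = {
                "n_conditions": cfg.n_conditions,
                "n_replicates": cfg.n_replicates,
                "sigma2": cfg.sigma2,
                "missing_rate": cfg.missing_rate,
                "n_mod_features": cfg.n_mod_features,
                "seed": cfg.seed,
                "method": method,
                "TP": cm.TP,
                "FP": cm.FP,
                "TN": cm.TN,
                "FN": cm.FN,
                "accuracy": cm.accuracy,
                "recall": cm.recall,
                "efdr": cm.efdr,
                "protein_discard_fraction": loss.get("protein_discard_fraction", 0.0),
                "ptm_discard_fraction": loss.get("ptm_discard_fraction", 0.0),
            }
            row.update(fold_change_stats(frame, truth))
            rows.append(row)
    return pd.DataFrame(rows)
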