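# Methods

## Problem and model

Bottom-up LC-MS/MS quantifies a posttranslational modification (PTM) site
through the spectral features (peptide ions) that span it. The observed
change of those features between conditions confounds two biological
signals: a change in modification occupancy and a change in overall protein
abundance. `ptmquant` separates them by modeling the enriched
(modification-level) and global (protein-level) data independently and
combining the two inferences.

For one site, let y*_ijk be the log2 intensity of modified feature k in
replicate j of condition i, and y_ijl the log2 intensity of unmodified
feature l of the same protein. Features are first collapsed to one summary
per target per run. The run summaries are then modeled per target:

* label-free group comparison: one-way fixed effects,
  `y_ij = mu_i + e_ij`, `e_ij ~ N(0, sigma^2)`, residual df `sum_i (J_i - 1)`
  (`I(J-1)` when balanced);
* multi-mixture TMT: `y_imj = mu_i + M_m + e_imj` with a random mixture
  intercept `M_m ~ N(0, sigma_M^2)`, estimated by REML.

A contrast Delta_PTM = mu*_i - mu*_i' from the site model and
Delta_protein = mu_i - mu_i' from the protein model are combined into the
adjusted test

    Delta_adj = Delta_PTM - Delta_protein,
    se_adj^2  = se_PTM^2 + se_protein^2,
    df_adj    = (se_PTM^2 + se_protein^2)^2 /
                (se_PTM^4/df_PTM + se_protein^4/df_protein),

the Welch–Satterthwaite combination of two independent variance estimates
(the two fits use disjoint features, so independence is the modeling
assumption, stated rather than tested). `t = Delta_adj / se_adj` is referred
to Student's t with df_adj, and p-values are Benjamini–Hochberg corrected,
by default one family per contrast (adjusted and non-adjustable
pass-through results together; a global family is available). Sites with no
protein-level information cannot be adjusted; they are tested on
Delta_PTM alone and flagged `no_protein_match`.

## Summarization

Two run-level summaries are implemented:

* **Tukey median polish** (the default): two-way polish of the
  feature x run matrix with NaN-aware medians, at most 10 sweeps, stopping
  when the total absolute residual changes by less than 1e-4 of itself.
  The run summary is overall + column effect. The row sweep runs first,
  matching the classical algorithm (cross-checked against R's
  `stats::medpolish`). Robust to single-feature outliers.
* **log-sum**: log2 of the summed linear-scale intensities, the input
  convention of the ratio-based baselines. Sensitive to the most abundant
  feature by construction.

Peptides carrying several modified residues form their own composite
target (e.g. `S70+T81`) and are never merged into single-site groups.
Runs with no observed feature for a target yield no summary — there is no
zero filling. The baseline ratio summary `u_ij` is the difference of the
two log-sums in the same run and is lost whenever either side is entirely
missing; this loss is tracked because it is one of the two mechanisms
behind the adjusted pipeline's accuracy advantage.

## Degrees of freedom for the mixed model

For TMT contrasts the df comes from the same delta-method Satterthwaite
approximation used for the adjustment: with theta = (sigma^2, sigma_M^2),
`df = 2 var(c'beta)^2 / (g' H^{-1} g)` where g is the finite-difference
gradient of the contrast variance in theta and H the observed REML
information (central differences, relative step 1e-4). At the boundary
sigma_M^2 ~ 0 the model degenerates to the one-way fit and its residual df
is used; df is clipped to [1, n-1]. In balanced randomized-block designs
this reproduces the closed-form (I-1)(M-1) within numerical error (tested).
Negative variance components are truncated at zero. Non-convergence or a
single mixture triggers the documented fallback ladder: mixed -> one-way
(`fallback_oneway`) -> flagged untestable.

## Empirical-Bayes moderation

Optional, off by default for the headline method (the adjusted analysis is
reported unmoderated); on inside the limma-style baselines. Residual
variances are assumed drawn from a scaled inverse-chi-square prior
(d0, s0^2); marginally s^2 ~ s0^2 F(df, d0), and (d0, s0^2) are estimated
by maximizing that marginal likelihood (Nelder–Mead on log scale).
Variances are replaced by the posterior mean `(d0 s0^2 + df s^2)/(d0 + df)`
and df by `df + d0`; identical input variances map to d0 = infinity and the
common value. Recovery of (d0, s0^2) from simulated variances is tested to
15%.

## Missing-value imputation

Optional (off by default everywhere; intended for unmodified-protein
matrices only). Missing cells are treated as left-censored at the feature's
observed minimum; a two-way (feature + run) Gaussian model on the log2
scale is fit by maximum likelihood with censored-likelihood contributions
(an accelerated-failure-time formulation), and missing cells receive the
model prediction capped at the censoring bound. Modified features are not
imputed: their low feature counts and non-abundance missingness mechanisms
violate the censoring assumption. Benchmarks in this package are run
imputation-free so that reported error rates owe nothing to imputation.

## Numerical conventions

* Intensities <= 0 or NA-encoded are missing; all modeling is on log2.
* Residual variance below 1e-12 is treated as exactly zero: p = 0 (with a
  warning) for a nonzero estimate, p = 1 otherwise.
* When one component of the adjustment has zero SE, df_adj is the other
  component's df (the exact limit of the Satterthwaite formula).
* Contrast orientation is (i - i') as specified by the user; antisymmetry
  of estimate and invariance of se/p under reversal are guaranteed.
* BH adjustment excludes missing p-values from the family size.

## Synthetic data

The generator emulates label-free group-comparison experiments with known
ground truth. Per protein: a baseline log2 abundance ~ N(25, 2), fixed
per-feature offsets ~ N(0, 1), condition shifts per truth class, iid
N(0, sigma2) noise per observation, and optional MCAR deletion applied
independently to enriched and global tables at the same rate. The four
truth classes (equal proportions) decompose the observed PTM change:
`diff_direct` (modification shifts, protein flat), `diff_masked` (observed
modification flat because the protein shifts by the negative effect — the
sign is configurable), `null_flat`, and `null_protein_driven` (both shift
together; the class that floods unadjusted analyses with false positives).
Defaults: 1000 proteins, one single-site PTM each, effect 0.75 on log2,
sigma2 in {0.2, 0.3}; the clean design uses 10 modified and 10 unmodified
features and no missingness, the noisy design 2 modified features and 20%
MCAR. Effects apply between condition 1 and every other condition;
evaluation uses the condition 2 vs 1 contrast.

What the generator does **not** emulate: between-run normalization needs,
correlated (non-MCAR) missingness, outlier contamination beyond Gaussian
noise, shared peptides across proteins, multi-site occupancy interplay, or
TMT channel effects. Passing benchmarks therefore demonstrates correctness
of the statistical machinery under its own assumptions, not robustness to
every real-data pathology.

A master seed spawns independent per-dataset substreams
(`numpy.random.SeedSequence`), so any dataset of a grid is reproducible in
isolation and identical seeds give byte-identical tables.

## Benchmark design and problem sizes

The benchmark runner scores each method against ground truth at
BH-adjusted p <= 0.05: empirical FDR (FP/(TP+FP), 0 when nothing is
called), recall, accuracy, fold-change bias and IQR among truly
differential PTMs, and — for ratio baselines — the fraction of run
summaries discarded by one-sided missingness (analytically the squared
per-observation missingness rate when there are two modified features:
0.2^2 = 4%). Untestable sites count as negative calls.

The shipped evaluation uses the full noisy-design grid
({2,3,4} conditions x {2,3,5,10} replicates x sigma2 {0.2, 0.3}) for the
data-loss statistic, a single clean-design config (I=2, J=10,
sigma2=0.2) for eFDR calibration and effect recovery, and a reduced
noisy-design diagonal ((2,3), (3,5), (4,10) at both noise levels) for the
fold-change IQR comparison. These sizes keep a full rerun in minutes while
leaving Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The fold-change IQR advantage over ratio-based baselines is
  direction-stable but its magnitude depends on the spread of the
  per-feature abundance offsets, because the log-sum summary's variance is
  weight-concentrated on abundant features while median polish is not.
  With the documented N(0, 1) offsets the measured average reduction is
  larger than a third.
* Peptides shared across protein groups are surfaced as an ambiguity error
  (optionally resolved to the first FASTA occurrence), never silently
  assigned.
* Only group-comparison designs are modeled; paired and time-course
  designs are out of scope.
* Site-occupancy (stoichiometry) inference and deconvolution of multi-site
  peptides are out of scope; multi-site peptides are kept as separate
  composite targets.
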