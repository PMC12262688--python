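# Methods

## Scope and model

`evmirna` analyzes paired qPCR array-card experiments that profile the
miRNA cargo of extracellular vesicles (EVs) secreted after a receptor
stimulus. The design it assumes: each treated sample is paired with the
vehicle-control sample from the same experimental run; additional
cell-free **media controls** (culture medium processed identically, never
exposed to cells) flag serum-derived miRNA background; assays are split
over two array cards (A/B) that are pooled for analysis.

Cq is treated as a log2-scale abundance (perfect doubling per cycle), so
additive operations on Cq correspond to multiplicative changes in
abundance:

* ΔCq(a, s) = Cq(a, s) − mean normalizer Cq(s)
* ΔΔCq(a) = mean over complete pairs of [ΔCq(a, treated) − ΔCq(a, VC)]
* FC = 2^−ΔΔCq, log2 FC = −ΔΔCq

A 1.5-fold change is therefore 0.585 cycles and a 10-fold change 3.3
cycles; both constants recur as thresholds below.

## Stages and parameters

1. **Well QC** (`filtering.apply_well_qc`). A well is censored to missing
   when Cq > `cq_max` (34 cycles), CqConf < `cq_conf_min` (0.8) or
   AmpScore < `amp_score_min` (1.0). Inequalities are strict: a well at
   exactly the threshold is retained. A well with a Cq but no quality
   scores is censored with its own reason code, since the gates cannot be
   evaluated. Each censored cell records exactly the first failing rule,
   in the order the rules are listed.

2. **Media-control exclusion** (`filtering.media_control_filter`). An
   assay is removed when it is detected only in media controls, or when it
   is detected in ≥ 50% of media controls (`mc_presence_min`) and its mean
   Cq sits within `mc_delta_min` = 3.3 cycles (10-fold) of the
   vehicle-control mean. The difference is direction-agnostic. Group means
   use observed wells only — censored wells carry no usable Cq. If the
   rule applies but the vehicle-control arm has no observation at all, the
   10-fold separation cannot be demonstrated and the assay is excluded
   conservatively.

3. **Expression filter** (`filtering.expression_filter`). Assays must be
   detected (post-QC) in at least `detection_rate_min` = 80% of samples.
   Two readings are implemented because published descriptions of this
   rule differ on the conjunction: `BOTH_GROUPS` (default) requires both
   the vehicle-control and treated arms to reach 80%; `EITHER_GROUP`
   requires only the better arm. `compare_detection_modes` runs the full
   filter chain under both readings so a deposited dataset can be matched
   to its published analyzed-assay count. The comparison is ≥, so 5/6 =
   83% passes and 80% exactly passes.

4. **Normalizer selection** (`normalization.select_normalizers`). An
   assay joins the endogenous normalizer panel iff (1) its media-control
   detection rate is below 50% (zero included), (2) it is observed post-QC
   in *every* vehicle-control and treated sample, and (3) when its
   media-control rate is in (0, 0.5), its media-control mean Cq is more
   than 3.3 cycles away from the vehicle-control mean. The panel is pooled
   across both cards. Zero qualifying assays aborts the run with an
   instruction to review thresholds; a single-assay panel is allowed with
   a logged warning.

5. **ΔCq** (`normalization.delta_cq`). The default subtracts each
   sample's own normalizer mean ("per-run" normalization), which absorbs
   any per-sample additive shift — loading, reverse-transcription or
   run-to-run drift — exactly. The alternative `MEDIAN_BY_GROUP` mode
   subtracts each group's median normalizer score instead; it relaxes the
   assumption of no differential measurement drift but leaves per-run
   variation in place, so it is provided for sensitivity analysis only and
   is never the default.

6. **Effects and tests** (`differential`). The primary estimator is the
   matched-pairs mean of within-pair ΔCq differences, restricted to
   complete pairs; it equals the treatment coefficient of a regression
   with pair fixed effects (unit-tested against that oracle at 1e-9).
   `sd_log2fc` is the n−1 sample SD of the per-pair log2 fold changes;
   note this is a dispersion, not a standard error. The primary test is
   **Skillings-Mack**: within each pair (block) observed values get
   mid-ranks, centered ranks are weighted by sqrt(12/(k+1)), unobserved
   treatments contribute the centered value 0, and the quadratic form
   against the generalized-inverse covariance is referred to the
   chi-square upper tail with df = rank of the covariance. Pairs with a
   single observation carry no ranking information: they contribute
   nothing and are not counted. On complete blocks the statistic reduces
   exactly to Friedman's. For two treatments and n complete blocks with a
   unanimous within-block ordering the statistic equals n, giving the
   closed-form p-values 0.0455 (n=4), 0.0253 (n=5) and 0.0143 (n=6) that
   anchor the acceptance checks. The asymptotic chi-square null is the
   default; a within-block-permutation Monte-Carlo null is available for
   small-n caution.

   Sensitivity alternatives: the group-means estimator (difference of arm
   means, pairing ignored; identical to matched pairs on complete
   balanced data), a paired sign-flip permutation test (exact enumeration
   up to 2^12 patterns, Monte-Carlo beyond), a Wilcoxon–Mann–Whitney
   rank-sum test on the pooled arms, and Welch's unequal-variance t-test.
   `sensitivity_grid` crosses {matched pairs, group means} ×
   {Skillings-Mack, sign-flip, Welch} — six cells — with the rank-sum p as
   an extra column.

7. **Selection** (`differential.rank_and_select`). Assays are ranked by
   |ΔΔCq| descending (ties broken lexicographically for determinism) and
   screened three ways: **discovery** p < 0.2 (a deliberately liberal
   screen that favors discovery power over false-positive control; no
   multiple-testing correction is applied, by design), **enrichment**
   |log2 FC| ≥ 0.585 (≥, so exactly 1.5-fold is included), and
   **significant** p < 0.05. Significant ⊆ discovery by construction.

8. **Enrichment** (`enrichment`). Runs entirely on user-supplied files —
   no web services — so results are reproducible against pinned
   annotation snapshots. Multi-miRNA queries keep genes targeted by at
   least `min_mirnas` = 2 distinct query miRNAs; a single-miRNA query
   keeps its full target set. Over-representation uses the hypergeometric
   upper tail (identical to one-sided Fisher, verified to 1e-12),
   Benjamini–Hochberg FDR across tested sets, significance at FDR < 0.05
   with observed gene count > 2 (strict, i.e. ≥ 3), and ranking by
   log10(observed/expected). The gene universe defaults to the union of
   the GMT collection, the natural background of the annotation space;
   it is configurable. Hub genes are the top-k nodes by degree in the
   user-supplied interaction network (self-loops dropped, duplicate edges
   counted once, degree ties broken lexicographically).

## What the simulator emulates — and what it does not

`simulate.simulate_experiment` generates well tables in the exact format
the reader consumes. Defaults mirror the emulated experiment: 754 assays
over two cards, 6 treated/vehicle pairs, 7 media controls, baselines
uniform on 20–33 cycles, per-sample run shifts N(0, 0.25), residual noise
N(0, 0.3) cycles, 5% affected assays with |log2 FC| uniform on
[0.585, 2] and random sign, 10% serum-only background assays (present in
media controls only, with a configurable leakage rate into cell samples),
and 5% normalizer-like assays (zero effect, residual SD reduced 3-fold,
baselines at least 5 cycles under the detection limit). Censoring applies
at 34 cycles.

Stochastic dropout (2%) and AmpScore/CqConf failures (1% each) are drawn
only among wells whose latent Cq lies within 4 cycles of the detection
limit. This models the empirical behavior of amplification-quality flags,
which fire on late, weak curves rather than uniformly at random; it also
means the stated failure rates are per weak-stratum well, not per well
overall. Features deliberately not simulated: pre-amplification bias,
probe cross-hybridization, inter-card calibration chemistry, non-Gaussian
noise kernels (the residual model is additive Gaussian on the Cq scale,
standard for a log-scale quantity), and correlated missingness beyond
Cq-driven censoring. Passing recovery tests therefore demonstrate
correctness of the statistical machinery under this noise model, not
robustness to chemistry artifacts absent from it.

A property the noiseless tests make explicit: because the normalizer
criteria do not screen for treatment stability, affected assays can join
the panel, and global-mean normalization then re-injects the panel mean
of the injected effects into every estimate as a common offset
(log2fc_est = injected − panel mean of injected). With a realistic assay
count and a small affected fraction the offset is negligible; the
noiseless unit test asserts the exact closed form including it.

## Validation study sizes

The recovery and calibration studies run on scaled-down instances chosen
to make the suite quick while keeping the per-assay sampling distribution
identical to the defaults (6 pairs, residual SD 0.3, injected |log2 FC| ∈
[0.585, 2]): 500 simulated experiments at 40 assays for estimator bias,
500 null-only experiments at 30 assays for test calibration, and 100
replicates at 60 assays for the filter-behavior checks. Because effects
and noise are drawn per assay, reducing the assay count lowers only the
number of replicated draws, not the difficulty of any single estimation
problem. Null calibration is assessed two ways: the pooled rejection rate
at 0.05 must not exceed 0.05, and among assays with all six pairs
complete the rate must match the enumerated discrete mass 2/2^6 ≈ 0.031
(only unanimous sign patterns reject at this n).

## Numerical and design choices

* Per-sample normalizer mean (not the group-median alignment) is the
  default ΔCq mode; the group-median variant increases residual variance
  between matched pairs whenever quality filtering makes the panel
  incomplete, and is exposed only as a sensitivity mode.
* Criterion (3) of normalizer selection and the media-control rule use
  the absolute mean-Cq difference: "different from" has no direction.
* Media-control means are computed over detected wells only; censored
  wells are not imputed at the detection limit.
* The Skillings-Mack covariance uses `scipy.linalg.pinvh`; the degrees of
  freedom are the matrix rank, which is k−1 on connected designs.
* Exact sign-flip enumeration switches to Monte-Carlo above 2^12
  patterns; Monte-Carlo p-values use the add-one estimator so p > 0.
* The rank-sum test uses the exact null for combined n ≤ 12 without
  ties, otherwise the normal approximation with continuity correction.
* Welch's test with zero variance in both arms returns p = 1 for equal
  means and degenerates to p = 0 (with a warning) otherwise.
* All table outputs are TSV with floats at 6 significant digits and
  missing values rendered "NA"; assay and sample axes are sorted
  lexicographically so repeated runs are byte-identical.
* Input dialects: the well-table reader accepts a configurable
  column-name map (default matching ExpressionSuite-style exports:
  "Sample Name / Card / Well / Target Name / Cq / Amp Score / Cq Conf"),
  falls back to the package's canonical column names, and treats
  "Undetermined", "NA" and empty strings as missing Cq. Cq values above
  45 cycles (the instrument ceiling) are rejected as invalid rather than
  censored. `melt_wide_export` adapts wide per-sample matrices (as
  deposited in repositories) into the long well format under a
  user-supplied mapping; quality-score columns rarely survive
  deposition, so constant defaults may be injected.

## Reproducing deposited experiments

The analysis of the deposited series (GEO accessions GSE270077–GSE270080)
is supported but requires downloading the well tables and sample sheets
and placing them under `data/geo/` as `<accession>_wells.tsv` and
`<accession>_sheet.tsv` (converting wide supplementary matrices with
`melt_wide_export` if needed). The acceptance test
`test_deposited_accession_reproduction` then checks the per-receptor
analyzed-assay counts under both detection-mode readings; it fails — by
design, rather than skipping — when the files are absent. The published
pathway-enrichment outputs are not reproduction targets: they depend on
the versions and backgrounds of external annotation services.

## Known limitations

* No imputation of censored Cq values and no per-well outlier detection
  beyond the three QC gates above.
* No geNorm/NormFinder-style stability-ranked normalizer selection; only
  the detection-based criteria above.
* No moderated-variance (empirical Bayes) testing and no multiple-testing
  correction of per-miRNA p-values — the discovery screen is deliberately
  liberal.
* The Skillings-Mack asymptotic null is coarse at n = 4–6 pairs; its
  discreteness makes the 0.05 screen conservative (see the calibration
  study), and the Monte-Carlo option exists for small-n caution.
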