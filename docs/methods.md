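# Methods

This note documents the statistical model implemented by `ftdebm`, its
assumptions, the numerical choices that are the package's own, what the
synthetic-data generator does and does not emulate, and the known
limitations of the estimator at realistic cohort sizes.

## Model

### Preprocessing

Raw biomarker values pass through four deterministic steps, in this order:

1. **Log transform** — per biomarker: `never` (default), `always`, or
   `auto`, which applies a natural log iff a Shapiro–Wilk test on the pooled
   observed values rejects normality at α = 0.05 *and* all values are
   positive (an optional additive shift is available). Shapiro–Wilk was
   chosen as the standard omnibus test with good power at cohort-scale n.
2. **Control-referenced z-scoring** — per biomarker,
   z = (x − mean_nc) / sd_nc with statistics from non-carriers (≥ 2 observed
   required; error otherwise).
3. **Orientation** — z-scores are multiplied by +1 (abnormality increases
   the measured value, e.g. NfL) or −1 (decreases, e.g. volumes, FA,
   cognitive scores) so that *abnormal is positive* for every biomarker.
4. **Confound regression** — per biomarker, OLS with intercept on
   **presymptomatic carriers only** (most non-carriers come from a single
   site, so they cannot identify site effects), using each biomarker's
   declared confounders: age+sex for NfL; age+sex+education for cognition;
   age+sex+TIV+protocol for imaging. Only the covariate effects are
   subtracted, with the design centred at presymptomatic covariate means, so
   the presymptomatic intercept is retained and group means stay comparable
   to the control-referenced zero. Sex and protocol enter as dummies, no
   interactions. A categorical level that is unidentifiable on the
   presymptomatic subset (absent, or the reference level absent so the
   dummies alias the intercept) is pruned and folded into the reference; a
   degenerate numeric design is an error.

The ordering of z-scoring and residualisation is not uniquely dictated by
the problem; the order above keeps values in control-referenced units
throughout and is applied identically at fit and test time
(`PreprocessModel` is serialisable and reapplicable to new subjects).

### Abnormality mixtures

Each biomarker's oriented z-scores in carriers follow
f(x) = π·N(μ_ab, σ_ab²) + (1−π)·N(μ_no, σ_no²), with (μ_no, σ_no) **fixed**
at the non-carrier statistics (non-carriers are healthy, so their values
define "normal") and (μ_ab, σ_ab, π) estimated by bounded maximum
likelihood on carriers (presymptomatic + symptomatic, complete-case per
biomarker, ≥ 10 observations required).

Numerical choices:

* **Bounds**: μ_ab ∈ [μ_no + 0.1·σ_no, max(x)]; σ_ab ∈ [0.2·σ_no,
  1.25·σ_no]; π ∈ [10⁻³, 1−10⁻³]. The σ_ab cap deserves emphasis: with a
  loose cap (several control SDs) the *global* MLE for biomarkers whose
  carriers are predominantly abnormal is a single broad component (π → 1)
  that swallows both modes — the classic instability of mixture fits on
  poorly separated data. On the z-scored scale the abnormal dispersion is
  expected to be comparable to the normal one, and the 1.25·σ_no cap
  encodes that, removing the collapse mode entirely.
* **Optimiser**: L-BFGS-B on the negative log-likelihood, three starts for
  μ_ab (symptomatic mean when available, 75th percentile of carriers,
  μ_no + 2σ_no), ftol 10⁻⁶, 500 iterations.
* **Siamese fit**: one joint likelihood over the left and right vectors of
  a paired region with shared (fixed) normal and shared abnormal components
  and independent π_L, π_R. With identical inputs the fit is exactly
  symmetric and matches the standard fit on the pooled vector. The shared
  normal pools the per-side control statistics (mean of means, RMS of SDs)
  — a no-op after z-scoring.
* **Phenotype-shared fit**: Gaussians from the pooled symptomatic carriers,
  then a 1-D bounded likelihood maximisation of π per phenotype with the
  Gaussians held fixed. A phenotype with no observations gets an undefined
  mixing fraction rather than an error.

The forceps minor, a midline tract, is recorded as separate left/right
columns and paired by default; the pairing can be disabled in configuration.

### Consensus ordering

The probabilistic Kendall tau distance between a candidate cascade and one
subject's posteriors charges each *observed* pair placed u-before-v but
with p_v > p_u the gap p_v − p_u; unobserved biomarkers contribute nothing.
On 0/1 posteriors this is exactly the classic discordance count. The total
over subjects decomposes over ordered pairs, W[u, v] = Σ_j max(0, p_jv −
p_ju), making consensus estimation a linear ordering problem. Note that any
pairwise weight with the same asymmetry — e.g. the "probability the pair is
discordant" form p_v(1−p_u) — yields the identical minimiser, since
p_v(1−p_u) − p_u(1−p_v) = p_v − p_u.

Search: exhaustive for ≤ 8 events (configurable); otherwise descending
mean-posterior initialisation refined by best-improvement insertion moves
until no move helps. Insertion moves strictly include adjacent
transpositions, so the result is always locally optimal under adjacent
swaps; on random instances with ≤ 6 events the heuristic empirically
attains the exhaustive optimum. All ties break by configuration order, so
outputs are bit-reproducible.

Non-carriers are excluded from consensus estimation: their posteriors are
near zero everywhere and carry no ordering signal. Event centres on [0, 1]
are uniform by default, (k + 0.5)/M; a weighted variant (posterior-weighted
mean normalised rank, monotonised along the ordering by
pool-adjacent-violators) is available.

### Staging and validation

A subject at stage k has passed the first k cascade events:
L(k) = Π_{pos<k, obs} p · Π_{pos≥k, obs} (1−p), with posteriors clipped to
[10⁻⁶, 1−10⁻⁶] so one extreme value cannot zero the product. Severity is
the likelihood-weighted expectation Σ_k k·L(k) / (M·Σ_k L(k)) by default;
the discrete argmax stage (smallest k on ties) is available as a config
switch and is the function-level default of `estimate_severity`. The
expectation was preferred for the pipeline because the argmax stage is
tie-heavy and its ties interact with the number of observed biomarkers,
which differs by group under the cohort's missingness pattern; in null
simulations (no disease effect) the expectation-based held-out AUC is
centred on 0.5 while the argmax variant is biased slightly low.

* **Bootstrap positional variance**: subjects resampled with replacement
  within diagnostic groups (stratification preserves the cohort
  composition; an unstratified bootstrap can produce repetitions without
  symptomatic subjects), seeds `bootstrap_seed_base + b`; mixtures and the
  ordering are refit per repetition (preprocessing is held from the full
  data); a non-converging repetition is retried once with a fresh resample
  and otherwise dropped. Rows and columns of the counts matrix sum exactly
  to the number of successful repetitions.
* **Cross-validation**: stratified 10-fold by group with a fixed seed;
  preprocessing, mixtures and ordering are all refit inside each training
  fold; each subject is staged exactly once by a model that never saw it.
  For the multimodal model, symptomatic subjects with no observed imaging
  biomarker are excluded from validation.
* **Classification**: the severity cutoff maximises Youden's J over the
  held-out severities; on ties the larger threshold (higher specificity)
  wins. The metric is invariant to monotone transforms of severity.
* **Clinical correlations**: Pearson r and two-sided p on complete pairs
  (≥ 3 required), per phenotype, against years-since-onset and the
  functional score.
* **Phenotype cascades**: symptomatic subjects only; phenotypes with < 5
  subjects are skipped with a warning. Within a phenotype the ordering is
  bootstrapped with the phenotype-shared mixtures held fixed — the
  per-phenotype samples (~16–17 subjects) are too small to refit mixtures
  stably per repetition.

## Synthetic cohort generator

The generator plants a known cascade so every stage of the pipeline is
testable without access to the real cohort. Defaults define the study
conditions and are not tuning knobs:

* **Groups**: 35 non-carriers, 56 presymptomatic, 35 symptomatic.
* **Stages**: non-carriers s = 0; presymptomatic s ~ Beta(2,5) scaled to
  [0, 0.6]; symptomatic s ~ Beta(5,2) scaled to [0.4, 1] — overlapping but
  separable groups, mirroring a short prodrome with fast progression.
* **Events**: biomarker k is abnormal with probability
  sigmoid((s − t_k)/τ), τ = 0.05. Base event times span t ∈ [0.12, 0.76]
  with the qualitative structure reported for the disease (language and
  NfL earliest, white matter before grey matter); right-hemisphere
  homologues lag their left counterpart by δ = 0.15 (max 0.91). The times
  are spread across the range the stage distributions actually populate;
  with the above Beta stages a compressed layout leaves adjacent events
  with no subjects between them and no estimator could order them.
* **Non-carriers are drawn healthy** (no abnormal values), as in the
  emulated cohort, rather than receiving the sigmoid's tail probability;
  contaminated controls would mis-anchor every fixed normal component
  through the n=35 control SD estimate. A flag restores the literal rule
  for sensitivity analyses.
* **Values**: N(0, 1) normal vs N(Δ, ratio²) abnormal on the oriented z
  scale, Δ = 3, ratio = 1 by default; de-oriented and mapped to plausible
  raw scales (pg/mL-like NfL, volumes, FA). Linear confounder effects
  (age, sex, education, TIV, site; ≤ ~0.5 SD across the covariate range)
  are added so preprocessing is exercised but not dominant.
* **Missingness**: missing-completely-at-random at modality level (a
  subject loses a whole modality at once, like a skipped MRI) at the
  study's reported availability rates per modality × group (e.g. T1-derived
  biomarkers observed in 44.4% of symptomatic vs 96.4% of presymptomatic
  subjects).
* **Phenotypes**: symptomatic subjects are assigned bvFTD/nfvPPA/CBS at the
  reported proportions; per-phenotype event-time overrides let tests plant
  divergent cascades.
* The default biomarkers use `log_transform: never` — values are generated
  on a linear scale so the Gaussian ground truth is exact; the auto-log
  path is exercised by dedicated unit tests on log-normal draws.

What the generator does **not** emulate: non-Gaussian tails, longitudinal
correlation, informative missingness, site-by-biomarker interactions, item
level cognitive scoring, assay noise. Passing tests therefore demonstrate
correctness of the estimator under its own model assumptions, not
performance on real data.

## Problem sizes and determinism

Tests and the acceptance script run synthetic cohorts at the study's actual
scale (126 subjects, 22 biomarkers), with 10–25 bootstrap repetitions and
10–20 simulation seeds per property; a full study-style run uses 100
bootstrap repetitions. Every stochastic step is seeded (generator seed,
`bootstrap_seed_base + b`, CV seed), and identical inputs and configuration
produce byte-identical artifacts.

## Known limitations

* **Ordering noise floor.** At the default conditions (Δ = 3 SD separation,
  91 carriers, modality-wise missingness) the mean normalised Kendall error
  of the recovered 22-event cascade is ≈ 0.19, and left-before-right
  placement holds for ≈ 74% of pairs. This is close to the information
  limit of the estimator, not an implementation artifact: with the *true*
  mixture parameters (no estimation error) the same consensus procedure
  achieves ≈ 0.10–0.15, and only with perfect binary knowledge of each
  subject's abnormality pattern does it reach ≈ 0.05. Intermediate
  posteriors from overlapping components inject pairwise noise that the
  summed-discordance objective integrates. Early events and the coarse
  structure (non-imaging before imaging, left before right on average) are
  recovered reliably; exact placement of late, sparsely observed events is
  not — mirrored in the wide positional-variance bands the bootstrap
  reports for them.
* **Phenotype cascades are uncertain at n ≈ 16–40.** Only symptomatic
  subjects (stages ≥ 0.4) inform them, so events earlier than every
  symptomatic stage cannot be ordered among themselves.
* The mixture model assumes a single abnormal component per biomarker and
  no covariate-dependent mixing; the severity scale is a unitless timeline
  position, not time-to-onset in years.
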