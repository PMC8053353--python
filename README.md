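# ftdebm — event-based modelling of the biomarker cascade in genetic FTD

`ftdebm` estimates the *temporal ordering* in which biomarkers become
abnormal in genetic frontotemporal dementia (FTD) from purely
cross-sectional data, and places every subject on the resulting disease
timeline. It is built for cohorts of mutation carriers (e.g. *GRN*) observed
once each: some presymptomatic, some symptomatic, plus healthy non-carrier
relatives, with fluid (serum NfL), cognitive (MMSE and domain scores) and
regional imaging biomarkers (grey-matter volumes, white-matter fractional
anisotropy) that may be partially missing.

## The model

Discriminative event-based modelling proceeds in three steps.

**1. Abnormality mixtures.** After confound correction each biomarker's
oriented z-scores are modelled as a two-component Gaussian mixture

&nbsp;&nbsp;&nbsp;&nbsp;f(x) = π·N(x; μ_ab, σ_ab) + (1−π)·N(x; μ_no, σ_no),

with the *normal* component fixed at the non-carrier mean and SD and the
*abnormal* component and mixing fraction π estimated from carriers. Two
extensions share this likelihood:

* **Siamese GMM** — a left/right biomarker pair shares both Gaussians but
  keeps independent mixing fractions π_L, π_R. In an asymmetric disease the
  early hemisphere's abundant abnormal values stabilise the fit of the late
  hemisphere, whose abnormal tail is under-sampled.
* **Phenotype-shared GMM** — Gaussians estimated on pooled symptomatic
  carriers, mixing fractions re-estimated per clinical phenotype (bvFTD,
  nfvPPA), so small phenotype groups can still be compared.

Each observed value then yields a posterior probability that the biomarker
is abnormal, P(abnormal | x).

**2. Consensus ordering.** Every subject induces an ordering of their
observed biomarkers by descending posterior. The central cascade is the
permutation σ minimising the summed probabilistic Kendall tau distance

&nbsp;&nbsp;&nbsp;&nbsp;Σ_j Σ_{σ(u)<σ(v)} max(0, p_jv − p_ju),

which reduces to the classic Kendall discordance count on binary
posteriors; pairs involving unobserved biomarkers contribute nothing, which
is how missing data are handled. The search exploits the pairwise
decomposition (a linear ordering problem): exhaustive for small event sets,
insertion-move local search from a mean-posterior initialisation otherwise.

**3. Staging.** A subject at stage k has passed the first k events; the
stage likelihood is L(k) = Π_{pos<k} p · Π_{pos≥k} (1−p) over observed
events, and disease severity is the likelihood-weighted mean stage on
[0, 1]. Uncertainty in the cascade itself is quantified by refitting on
bootstrap resamples (positional-variance diagrams), and staging is
validated by 10-fold cross-validation.

Because the real cohort is available only on request, the package ships a
synthetic-cohort generator (`ftdebm.synthetic_data`) that plants a known
cascade with staged abnormality, left-before-right asymmetry, confounder
effects and the study's modality-wise missingness pattern, so the whole
pipeline is testable end to end.

## Worked example

```bash
ftdebm simulate --out results/cohort --seed 7
ftdebm run --cohort results/cohort/cohort.csv \
           --config results/cohort/config.yaml \
           --out results/run --variant nonimaging --variant multimodal
```

or, as a scripted analysis, `python analysis/01_simulate_cohort.py` followed
by `analysis/02_fit_cascade.py` and `analysis/03_validate_staging.py`, which
print:

```
nonimaging: 6 events, normalised Kendall error vs truth = 0.067 (11.9 s)
  earliest five: language -> nfl -> attention_processing_speed -> executive_functioning -> social_cognition
multimodal: 22 events, normalised Kendall error vs truth = 0.165 (32.6 s)
  earliest five: language -> nfl -> temporal_gm_left -> insula_gm_left -> anterior_thalamic_radiation_fa_left

nonimaging: AUC 0.998, sensitivity 1.000, specificity 0.982 at severity threshold 0.625 (125 held-out subjects)
multimodal: AUC 0.998, sensitivity 1.000, specificity 0.964 at severity threshold 0.343 (112 held-out subjects)
```

Reading: on this simulated cohort the pipeline recovers the planted
cascade's early events (language and NfL first) exactly; the normalised
Kendall error counts the fraction of discordant event pairs against the
planted ordering (0 = identical, 0.5 = random, 1 = reversed). Held-out
severities separate symptomatic from presymptomatic carriers almost
perfectly; the sensitivity/specificity pair is evaluated at the
Youden-optimal severity cutoff. `results/run/` additionally contains the
ordering JSONs, per-subject staging CSVs, positional-variance TSVs
(bootstrap uncertainty of every event's position) and mixture diagnostics.

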