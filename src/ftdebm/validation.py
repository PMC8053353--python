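"""Model validation: bootstrap positional variance, cross-validated staging,
symptomatic/presymptomatic classification, clinical correlations, and the
differential phenotype cascades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cascade import (
    EventOrdering,
    assign_event_centers,
    compute_subject_posteriors,
    estimate_central_ordering,
)
from .data_model import (
    IMAGING_MODALITIES,
    AnalysisConfig,
    CohortError,
    CohortTable,
)
from .mixture import MixtureError, fit_phenotype_shared_gmm
from .modeling import (
    FittedModel,
    build_model,
    control_stats,
    fit_mixtures,
    select_variant_biomarkers,
)
from .preprocess import apply_preprocess, preprocess_cohort
from .staging import SeverityEstimate, estimate_severity, stage_cohort


class ValidationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Bootstrap positional variance
# --------------------------------------------------------------------------

@dataclass
class PositionalVariance:
    """counts[i, j] = number of bootstrap repetitions placing the i-th
    biomarker of the reference ordering at cascade position j."""

    counts: np.ndarray
    n_boot: int
    n_dropped: int
    reference_order: EventOrdering

    def to_frame(self) -> pd.DataFrame:
        names = self.reference_order.ordered_names()
        return pd.DataFrame(self.counts, index=names,
                            columns=[f"pos_{j}" for j in range(len(names))])

    def positional_spread(self) -> np.ndarray:
        """Count-weighted SD of each biomarker's position across repetitions."""
        m = self.counts.shape[0]
        pos = np.arange(m)
        tot = self.counts.sum(axis=1)
        mean = (self.counts * pos).sum(axis=1) / np.maximum(tot, 1)
        var = (self.counts * (pos[None, :] - mean[:, None]) ** 2).sum(axis=1) \
            / np.maximum(tot, 1)
        return np.sqrt(var)


def _stratified_resample(groups: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for g in np.unique(groups):
        members = np.flatnonzero(groups == g)
        idx.append(rng.choice(members, size=len(members), replace=True))
    return np.concatenate(idx)


def bootstrap_positional_variance(pre: CohortTable, reference: EventOrdering,
                                  variant: str = "multimodal",
                                  config: Optional[AnalysisConfig] = None
                                  ) -> PositionalVariance:
    """Re-estimate the cascade on bootstrap resamples of the (preprocessed)
    cohort, stratified by diagnostic group, and count biomarker positions.

    A repetition that fails to converge is retried once with a jittered
    resample; a second failure drops the repetition.
    """
    config = config or AnalysisConfig()
    m = pre.n_biomarkers
    ref_pos = reference.order  # counts row i <-> biomarker reference.order[i]
    counts = np.zeros((m, m), dtype=int)
    groups = pre.groups
    dropped = 0
    for b in range(config.n_bootstrap):
        seed = config.bootstrap_seed_base + b
        ok = False
        for attempt in range(2):
            rng = np.random.default_rng(seed if attempt == 0 else seed + 10_000_019)
            idx = _stratified_resample(groups, rng)
            boot = CohortTable(
                subjects=[_renamed(pre.subjects[i], f"{pre.subjects[i].subject_id}#{j}")
                          for j, i in enumerate(idx)],
                biomarkers=list(pre.biomarkers),
                values=pre.values[idx].copy(),
                observed=pre.observed[idx].copy(),
            )
            try:
                fits = fit_mixtures(boot, variant,
                                    config.mixture_maxiter, config.mixture_tol)
                sp = compute_subject_posteriors(boot, fits)
                carriers = boot.group_mask("presymptomatic", "symptomatic")
                csp = [s for s, c in zip(sp, carriers) if c]
                ordering = estimate_central_ordering(
                    csp, names=boot.biomarker_names,
                    exact=None, exact_max=config.exact_ordering_max)
            except (MixtureError, CohortError):
                continue
            pos_of = ordering.position_of()
            for row, bm in enumerate(ref_pos):
                counts[row, pos_of[bm]] += 1
            ok = True
            break
        if not ok:
            dropped += 1
    return PositionalVariance(counts=counts, n_boot=config.n_bootstrap,
                              n_dropped=dropped, reference_order=reference)


def _renamed(subject, new_id):
    from dataclasses import replace
    return replace(subject, subject_id=new_id)


# --------------------------------------------------------------------------
# Cross-validated staging
# --------------------------------------------------------------------------

def exclude_imaging_free_symptomatic(cohort: CohortTable) -> CohortTable:
    """Drop symptomatic subjects with no observed imaging biomarker (used for
    validating the multimodal model only)."""
    img_cols = [k for k, b in enumerate(cohort.biomarkers)
                if b.modality in IMAGING_MODALITIES]
    if not img_cols:
        return cohort
    has_img = cohort.observed[:, img_cols].any(axis=1)
    keep = has_img | (cohort.groups != "symptomatic")
    return cohort.subset_subjects(keep)


def crossval_severity(raw: CohortTable, variant: str = "multimodal",
                      config: Optional[AnalysisConfig] = None
                      ) -> list[SeverityEstimate]:
    """Held-out severities: the model (preprocessing, mixtures, ordering) is
    built on each training fold and applied to the held-out fold, so every
    subject is staged exactly once by a model that never saw it."""
    config = config or AnalysisConfig()
    cohort = select_variant_biomarkers(raw, variant)
    if variant in ("multimodal", "multimodal-nosiamese"):
        cohort = exclude_imaging_free_symptomatic(cohort)
    groups = cohort.groups
    if not np.any(groups == "noncarrier"):
        raise ValidationError("stratification impossible: no non-carriers")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.cv_seed)
    estimates: list[SeverityEstimate] = []
    for train_idx, test_idx in skf.split(np.zeros(len(groups)), groups):
        train_mask = np.zeros(len(groups), dtype=bool)
        train_mask[train_idx] = True
        if not np.any(groups[train_idx] == "noncarrier"):
            raise ValidationError("fold without non-carriers")
        train = cohort.subset_subjects(train_mask)
        model, _, _ = build_model(train, variant, config)
        test = cohort.subset_subjects(~train_mask)
        test_pre = apply_preprocess(test, model.preprocess)
        sp = compute_subject_posteriors(test_pre, model.fits)
        for s in sp:
            if s.observed.any():
                estimates.append(
                    estimate_severity(s, model.ordering, config.severity_mode))
    return estimates


# --------------------------------------------------------------------------
# Classification and clinical correlation
# --------------------------------------------------------------------------

def classify_groups(severities: np.ndarray, is_symptomatic: np.ndarray
                    ) -> tuple[float, float, float]:
    """Severity cutoff maximising Youden's J; returns (sensitivity,
    specificity, threshold). Sensitivity counts symptomatic >= threshold,
    specificity presymptomatic < threshold; J-ties break toward the larger
    threshold (higher specificity)."""
    severities = np.asarray(severities, dtype=float)
    is_symptomatic = np.asarray(is_symptomatic, dtype=bool)
    if not is_symptomatic.any() or is_symptomatic.all():
        raise ValidationError("both groups must be non-empty")
    sym = severities[is_symptomatic]
    pre = severities[~is_symptomatic]
    cuts = np.unique(severities)
    cuts = np.concatenate([cuts, [cuts.max() + 1.0]])
    best = None
    for t in cuts:
        sens = float(np.mean(sym >= t))
        spec = float(np.mean(pre < t))
        j = sens + spec - 1.0
        if best is None or j >= best[0] - 1e-12:
            if best is None or j > best[0] + 1e-12 or t > best[3]:
                best = (j, sens, spec, float(t))
    _, sens, spec, thr = best
    return sens, spec, thr


def correlate_clinical(severities: np.ndarray, clinical: np.ndarray
                       ) -> tuple[float, float]:
    """Pearson correlation on complete pairs."""
    s = np.asarray(severities, dtype=float)
    c = np.asarray(clinical, dtype=float)
    ok = np.isfinite(s) & np.isfinite(c)
    if ok.sum() < 3:
        raise ValidationError(f"need >= 3 complete pairs, got {int(ok.sum())}")
    if np.std(c[ok]) == 0 or np.std(s[ok]) == 0:
        raise ValidationError("zero variance in correlation input")
    r, p = stats.pearsonr(s[ok], c[ok])
    return float(r), float(p)


def validation_metrics(cohort: CohortTable, estimates: list[SeverityEstimate]
                       ) -> dict:
    """Sensitivity/specificity of the symptomatic-vs-presymptomatic split and
    per-phenotype clinical correlations of held-out severities."""
    by_id = {e.subject_id: e.severity for e in estimates}
    rows = [(s, by_id[s.subject_id]) for s in cohort.subjects
            if s.subject_id in by_id and s.group != "noncarrier"]
    sev = np.array([v for _, v in rows])
    is_sym = np.array([s.group == "symptomatic" for s, _ in rows])
    sens, spec, thr = classify_groups(sev, is_sym)
    out = {"sensitivity": sens, "specificity": spec, "threshold": thr,
           "correlations": {}}
    for pheno in ("bvFTD", "nfvPPA"):
        sel = [(s, v) for s, v in rows if s.phenotype == pheno]
        for attr, key in (("years_since_onset", "years_since_onset"),
                          ("functional_score", "functional_score")):
            pairs = [(v, getattr(s, attr)) for s, v in sel
                     if getattr(s, attr) is not None]
            if len(pairs) >= 3:
                try:
                    r, p = correlate_clinical(*map(np.array, zip(*pairs)))
                    out["correlations"][f"{pheno}:{key}"] = {"r": r, "p": p}
                except ValidationError:
                    pass
    return out


# --------------------------------------------------------------------------
# Differential phenotype analysis
# --------------------------------------------------------------------------

def phenotype_cascades(raw: CohortTable, variant: str = "multimodal",
                       config: Optional[AnalysisConfig] = None,
                       min_n: int = 5, run_bootstrap: bool = True) -> dict:
    """Per-phenotype cascades among symptomatic carriers.

    Normal and abnormal Gaussians are shared across phenotypes (fit on all
    symptomatic carriers pooled); only the mixing fractions are re-estimated
    per phenotype. Presymptomatic subjects are excluded. Phenotypes below
    ``min_n`` subjects are skipped with a warning entry.
    """
    config = config or AnalysisConfig()
    cohort = select_variant_biomarkers(raw, variant)
    pre, _ = preprocess_cohort(cohort)
    sym_mask = pre.group_mask("symptomatic")
    phenos = pre.phenotypes
    counts = {ph: int(((phenos == ph) & sym_mask).sum())
              for ph in np.unique(phenos[sym_mask]) if ph != "none"}
    usable = [ph for ph, n in counts.items() if n >= min_n]
    skipped = {ph: n for ph, n in counts.items() if n < min_n}
    if len(usable) < 2:
        raise ValidationError(
            f"need >= 2 phenotypes with >= {min_n} subjects, have {counts}")

    # phenotype-shared mixtures: Gaussians pooled over usable phenotypes
    fits: dict = {}
    for k, b in enumerate(pre.biomarkers):
        mu_n, sd_n = control_stats(pre, k)
        by_ph = {}
        for ph in usable:
            mask = sym_mask & (phenos == ph) & pre.observed[:, k]
            by_ph[ph] = pre.values[mask, k]
        fits[b.name] = fit_phenotype_shared_gmm(by_ph, mu_n, sd_n,
                                                config.mixture_maxiter,
                                                config.mixture_tol)

    ctx = {s.subject_id: s.phenotype for s in pre.subjects}
    results: dict = {"skipped": skipped, "per_phenotype": {}}
    for ph in usable:
        mask = sym_mask & (phenos == ph)
        sub = pre.subset_subjects(mask)
        sp = compute_subject_posteriors(sub, fits, context_by_subject=ctx)
        sp = [s for s in sp if s.observed.any()]
        ordering = estimate_central_ordering(
            sp, names=pre.biomarker_names,
            exact=None, exact_max=config.exact_ordering_max)
        ordering = assign_event_centers(ordering, sp, config.center_mode)
        entry = {"ordering": ordering, "n": counts[ph]}
        if run_bootstrap:
            entry["positional_variance"] = _phenotype_bootstrap(
                sub, fits, ctx, ordering, config)
        results["per_phenotype"][ph] = entry
    return results


def _phenotype_bootstrap(sub: CohortTable, fits: dict, ctx: dict,
                         reference: EventOrdering,
                         config: AnalysisConfig) -> PositionalVariance:
    """Bootstrap the ordering within one phenotype (mixtures held fixed; the
    per-phenotype sample is too small to refit them stably per repetition)."""
    m = sub.n_biomarkers
    counts = np.zeros((m, m), dtype=int)
    sp_all = compute_subject_posteriors(sub, fits, context_by_subject=ctx)
    sp_all = [s for s in sp_all if s.observed.any()]
    dropped = 0
    for b in range(config.n_bootstrap):
        rng = np.random.default_rng(config.bootstrap_seed_base + b)
        idx = rng.choice(len(sp_all), size=len(sp_all), replace=True)
        try:
            ordering = estimate_central_ordering(
                [sp_all[i] for i in idx], names=sub.biomarker_names,
                exact=None, exact_max=config.exact_ordering_max)
        except CohortError:
            dropped += 1
            continue
        pos_of = ordering.position_of()
        for row, bm in enumerate(reference.order):
            counts[row, pos_of[bm]] += 1
    return PositionalVariance(counts=counts, n_boot=config.n_bootstrap,
                              n_dropped=dropped, reference_order=reference)
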