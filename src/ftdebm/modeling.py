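"""Fit a full event-based model on a (preprocessed) cohort.

Variants:

* ``nonimaging`` — fluid + cognitive biomarkers, standard controls-fixed GMM;
* ``multimodal`` — all biomarkers, Siamese GMM for left/right pairs;
* ``multimodal-nosiamese`` — all biomarkers, every fit independent (the
  ablation of the pairwise coupling).

The normal component of every mixture is fixed at the non-carrier mean and
SD of the preprocessed values; mixtures are fit on mutation carriers
(presymptomatic + symptomatic). The consensus ordering is estimated from
carrier posteriors only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cascade import (
    EventOrdering,
    SubjectPosteriors,
    assign_event_centers,
    compute_subject_posteriors,
    estimate_central_ordering,
)
from .data_model import (
    NON_IMAGING_MODALITIES,
    AnalysisConfig,
    CohortError,
    CohortTable,
)
from .mixture import MixtureError, MixtureFit, fit_fixed_normal_gmm, fit_siamese_gmm
from .preprocess import PreprocessModel, apply_preprocess, preprocess_cohort

VARIANTS = ("nonimaging", "multimodal", "multimodal-nosiamese")


@dataclass
class FittedModel:
    variant: str
    preprocess: PreprocessModel
    fits: dict  # biomarker name -> MixtureFit
    ordering: EventOrdering
    biomarker_names: list


def select_variant_biomarkers(cohort: CohortTable, variant: str) -> CohortTable:
    if variant == "nonimaging":
        names = [b.name for b in cohort.biomarkers
                 if b.modality in NON_IMAGING_MODALITIES]
        return cohort.subset_biomarkers(names)
    if variant in ("multimodal", "multimodal-nosiamese"):
        return cohort
    raise CohortError(f"unknown model variant {variant!r}")


def control_stats(cohort: CohortTable, k: int) -> tuple[float, float]:
    mask = cohort.group_mask("noncarrier") & cohort.observed[:, k]
    if mask.sum() < 2:
        raise MixtureError(
            f"biomarker {cohort.biomarkers[k].name}: <2 non-carrier observations")
    v = cohort.values[mask, k]
    return float(v.mean()), float(v.std(ddof=1))


def fit_mixtures(pre: CohortTable, variant: str = "multimodal",
                 maxiter: int = 500, tol: float = 1e-6) -> dict:
    """Fit per-biomarker mixtures on carriers; Siamese for pairs when the
    variant uses them. Returns name -> MixtureFit."""
    carriers = pre.group_mask("presymptomatic", "symptomatic")
    sym = pre.group_mask("symptomatic")
    use_siamese = variant == "multimodal"
    fits: dict[str, MixtureFit] = {}
    done: set[str] = set()
    for k, b in enumerate(pre.biomarkers):
        if b.name in done:
            continue
        partner = None
        if use_siamese and b.pair_id is not None:
            for k2, b2 in enumerate(pre.biomarkers):
                if b2.pair_id == b.pair_id and b2.name != b.name:
                    partner = (k2, b2)
        mu_n, sd_n = control_stats(pre, k)
        if partner is None:
            obs = pre.observed[:, k] & carriers
            x = pre.values[obs, k]
            sobs = pre.observed[:, k] & sym
            smean = float(pre.values[sobs, k].mean()) if sobs.sum() else None
            fit = fit_fixed_normal_gmm(x, mu_n, sd_n, maxiter, tol,
                                       symptomatic_mean=smean)
            fits[b.name] = fit
            done.add(b.name)
        else:
            k2, b2 = partner
            left_k, right_k = (k, k2) if b.hemisphere == "left" else (k2, k)
            left_b = pre.biomarkers[left_k]
            right_b = pre.biomarkers[right_k]
            mu_l, sd_l = control_stats(pre, left_k)
            mu_r, sd_r = control_stats(pre, right_k)
            xl = pre.values[pre.observed[:, left_k] & carriers, left_k]
            xr = pre.values[pre.observed[:, right_k] & carriers, right_k]
            sobs = (pre.observed[:, left_k] | pre.observed[:, right_k]) & sym
            pooled_sym = np.concatenate([
                pre.values[pre.observed[:, left_k] & sym, left_k],
                pre.values[pre.observed[:, right_k] & sym, right_k]])
            smean = float(pooled_sym.mean()) if pooled_sym.size else None
            fit = fit_siamese_gmm(xl, xr, mu_l, sd_l, mu_r, sd_r,
                                  maxiter, tol, symptomatic_mean=smean)
            fits[left_b.name] = fit
            fits[right_b.name] = fit
            done.update((left_b.name, right_b.name))
    return fits


def build_model(raw: CohortTable, variant: str = "multimodal",
                config: Optional[AnalysisConfig] = None,
                preprocessed: Optional[tuple] = None) -> tuple[FittedModel, CohortTable, list]:
    """Preprocess, fit mixtures, and estimate the consensus ordering.

    Returns (model, preprocessed cohort, carrier SubjectPosteriors).
    ``preprocessed`` may carry an existing (cohort, PreprocessModel) pair to
    skip refitting the preprocessing (bootstrap refits reuse it).
    """
    config = config or AnalysisConfig()
    sub = select_variant_biomarkers(raw, variant)
    if preprocessed is None:
        pre, pmodel = preprocess_cohort(sub)
    else:
        pre, pmodel = preprocessed
    fits = fit_mixtures(pre, variant, config.mixture_maxiter, config.mixture_tol)
    all_sp = compute_subject_posteriors(pre, fits)
    carriers = pre.group_mask("presymptomatic", "symptomatic")
    carrier_sp = [sp for sp, c in zip(all_sp, carriers) if c]
    ordering = estimate_central_ordering(
        carrier_sp, names=pre.biomarker_names,
        exact=None, exact_max=config.exact_ordering_max)
    ordering = assign_event_centers(ordering, carrier_sp, config.center_mode)
    model = FittedModel(variant=variant, preprocess=pmodel, fits=fits,
                        ordering=ordering, biomarker_names=pre.biomarker_names)
    return model, pre, carrier_sp


def posteriors_for(model: FittedModel, raw: CohortTable,
                   already_preprocessed: bool = False) -> list[SubjectPosteriors]:
    """Posteriors for (new) subjects under a fitted model."""
    sub = raw if already_preprocessed else select_variant_biomarkers(raw, model.variant)
    pre = sub if already_preprocessed else apply_preprocess(sub, model.preprocess)
    return compute_subject_posteriors(pre, model.fits)
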