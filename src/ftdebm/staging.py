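"""Per-subject disease severity along the fitted cascade timeline.

A subject at stage k has experienced the first k events of the cascade. The
stage likelihood over k = 0..M multiplies, for observed events only, the
abnormality posterior of events at positions < k and the complement for
positions >= k:

    L(k) = prod_{pos < k, obs} p  *  prod_{pos >= k, obs} (1 - p)

Severity is k*/M with k* the maximum-likelihood stage (smallest k on ties);
an expectation-based variant sum_k k L(k) / (M sum_k L(k)) is available.
Posteriors are clipped away from 0/1 so a single extreme posterior cannot
annihilate the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cascade import EventOrdering, SubjectPosteriors
from .data_model import CohortTable

_CLIP = 1e-6


class StagingError(ValueError):
    pass


@dataclass
class SeverityEstimate:
    subject_id: str
    severity: float
    n_observed: int
    loglik_profile: Optional[np.ndarray] = None  # log L(k), k = 0..M


def estimate_severity(sp: SubjectPosteriors, ordering: EventOrdering,
                      mode: str = "argmax") -> SeverityEstimate:
    m = ordering.n_events
    obs_in_order = sp.observed[ordering.order]
    p = np.clip(sp.probs[ordering.order], _CLIP, 1.0 - _CLIP)
    n_obs = int(obs_in_order.sum())
    if n_obs == 0:
        raise StagingError(f"subject {sp.subject_id} observes no biomarker")

    logp = np.where(obs_in_order, np.log(p), 0.0)
    logq = np.where(obs_in_order, np.log1p(-p), 0.0)
    # log L(k) = sum_{i<k} logp[i] + sum_{i>=k} logq[i], via cumulative sums
    cp = np.concatenate([[0.0], np.cumsum(logp)])
    cq = np.concatenate([[0.0], np.cumsum(logq)])
    profile = cp + (cq[m] - cq)  # length M+1

    if mode == "argmax":
        k_star = int(np.argmax(profile))  # argmax returns smallest index on ties
        severity = k_star / m
    elif mode == "expectation":
        w = np.exp(profile - profile.max())
        severity = float(np.sum(np.arange(m + 1) * w) / (m * w.sum()))
    else:
        raise StagingError(f"unknown severity mode {mode!r}")
    return SeverityEstimate(sp.subject_id, float(severity), n_obs, profile)


def stage_cohort(all_sp: list[SubjectPosteriors], ordering: EventOrdering,
                 mode: str = "argmax") -> list[SeverityEstimate]:
    return [estimate_severity(sp, ordering, mode) for sp in all_sp]


def staging_table(cohort: CohortTable,
                  estimates: list[SeverityEstimate]) -> pd.DataFrame:
    """Per-subject staging export: id, group, phenotype, severity, n_observed."""
    by_id = {e.subject_id: e for e in estimates}
    rows = []
    for s in cohort.subjects:
        e = by_id.get(s.subject_id)
        if e is None:
            continue
        rows.append({
            "subject_id": s.subject_id, "group": s.group,
            "phenotype": s.phenotype, "severity": e.severity,
            "n_observed": e.n_observed,
        })
    return pd.DataFrame(rows)
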