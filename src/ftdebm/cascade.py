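"""Consensus event ordering from per-subject abnormality posteriors.

Each subject induces a (partial) ordering of their observed biomarkers by
descending abnormality posterior. The central cascade is the permutation
minimising the summed probabilistic Kendall tau distance to all
subject-specific cascades. The distance charges every observed discordant
pair (u before v in the candidate but p_v > p_u for the subject) its
probability gap p_v - p_u; on binary posteriors it reduces exactly to the
classic Kendall discordance count. Pairs involving unobserved biomarkers
contribute nothing, which is how missing data are handled.

Because the total distance decomposes over ordered pairs, the consensus
search is a linear ordering problem on a pairwise cost matrix
W[u, v] = sum_j max(0, p_jv - p_ju): the cost of placing u before v, summed
over subjects observing both. The heuristic initialises by descending mean
posterior and refines with insertion-move local search (a superset of
adjacent transpositions); for small event sets an exhaustive search over all
permutations is available and used by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .data_model import CohortError, CohortTable
from .mixture import MixtureFit, posterior_abnormality


@dataclass
class SubjectPosteriors:
    subject_id: str
    probs: np.ndarray  # per-biomarker abnormality probability
    observed: np.ndarray  # per-biomarker bool

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.probs.shape != self.observed.shape:
            raise CohortError("probs/observed shape mismatch")
        obs = self.probs[self.observed]
        if obs.size and (obs.min() < 0 or obs.max() > 1):
            raise CohortError("posterior outside [0, 1]")


@dataclass
class EventOrdering:
    """A permutation of biomarker indices; position 0 is the earliest event."""

    order: np.ndarray  # permutation of 0..M-1
    names: Optional[list[str]] = None
    centers: Optional[np.ndarray] = None  # per-event position in [0,1], sorted
    unobserved_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=int)
        m = len(self.order)
        if sorted(self.order.tolist()) != list(range(m)):
            raise CohortError("order is not a permutation")
        if self.centers is not None:
            self.centers = np.asarray(self.centers, dtype=float)
            if self.centers.shape != (m,):
                raise CohortError("centers length mismatch")
            if np.any(np.diff(self.centers) < -1e-12):
                raise CohortError("centers must be non-decreasing along the order")

    @property
    def n_events(self) -> int:
        return len(self.order)

    def position_of(self) -> np.ndarray:
        """position_of()[k] = cascade position of biomarker k."""
        pos = np.empty(self.n_events, dtype=int)
        pos[self.order] = np.arange(self.n_events)
        return pos

    def ordered_names(self) -> list[str]:
        if self.names is None:
            raise CohortError("ordering carries no biomarker names")
        return [self.names[k] for k in self.order]


def compute_subject_posteriors(cohort: CohortTable, fits: dict,
                               context_by_subject=None) -> list[SubjectPosteriors]:
    """Abnormality posteriors for every subject.

    ``fits`` maps biomarker name -> MixtureFit. The mixing context per
    biomarker is chosen by hemisphere for Siamese fits; phenotype models pass
    ``context_by_subject`` (subject_id -> context label) instead.
    """
    out = []
    for k, b in enumerate(cohort.biomarkers):
        if b.name not in fits:
            raise CohortError(f"no mixture fit for biomarker {b.name!r}")
    probs = np.zeros((cohort.n_subjects, cohort.n_biomarkers))
    observed = cohort.observed.copy()
    for k, b in enumerate(cohort.biomarkers):
        fit: MixtureFit = fits[b.name]
        obs = observed[:, k]
        if not obs.any():
            continue
        if context_by_subject is not None:
            for i in np.flatnonzero(obs):
                ctx = context_by_subject[cohort.subjects[i].subject_id]
                if fit.mixing.get(ctx) is None:
                    observed[i, k] = False
                    continue
                probs[i, k] = posterior_abnormality(
                    cohort.values[i, k], fit, ctx)
        else:
            if "all" in fit.mixing:
                ctx = "all"
            elif b.hemisphere in fit.mixing:
                ctx = b.hemisphere
            else:
                raise CohortError(
                    f"cannot resolve mixing context for {b.name} "
                    f"(available: {sorted(fit.mixing)})")
            probs[obs, k] = posterior_abnormality(cohort.values[obs, k], fit, ctx)
    for i, s in enumerate(cohort.subjects):
        out.append(SubjectPosteriors(s.subject_id, probs[i], observed[i]))
    return out


def subject_ordering(sp: SubjectPosteriors) -> np.ndarray:
    """Observed biomarkers sorted by descending posterior; ties broken by the
    global biomarker index (configuration order)."""
    idx = np.flatnonzero(sp.observed)
    if idx.size == 0:
        raise CohortError(f"subject {sp.subject_id} observes no biomarker")
    # stable sort on (-p, index): mergesort keeps index order within ties
    return idx[np.argsort(-sp.probs[idx], kind="stable")]


def prob_kendall_tau(candidate: EventOrdering | Sequence[int],
                     sp: SubjectPosteriors) -> float:
    """Probabilistic Kendall tau distance between a candidate cascade and one
    subject's posteriors; unobserved biomarkers contribute zero."""
    order = candidate.order if isinstance(candidate, EventOrdering) else \
        np.asarray(candidate, dtype=int)
    p = sp.probs[order]
    o = sp.observed[order]
    p = p[o]
    if p.size < 2:
        return 0.0
    diff = p[None, :] - p[:, None]  # diff[i, j] = p_j - p_i
    return float(np.triu(np.clip(diff, 0.0, None), k=1).sum())


def pairwise_costs(all_sp: list[SubjectPosteriors], m: int) -> np.ndarray:
    """W[u, v] = total cost of placing u before v across subjects."""
    W = np.zeros((m, m))
    for sp in all_sp:
        obs = sp.observed
        p = sp.probs
        idx = np.flatnonzero(obs)
        if idx.size < 2:
            continue
        pv = p[idx]
        gap = np.clip(pv[None, :] - pv[:, None], 0.0, None)
        W[np.ix_(idx, idx)] += gap
    np.fill_diagonal(W, 0.0)
    return W


def total_distance(order: Sequence[int], W: np.ndarray) -> float:
    order = np.asarray(order, dtype=int)
    sub = W[np.ix_(order, order)]
    return float(np.triu(sub, k=1).sum())


def _insertion_local_search(order: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Best-improvement insertion moves until no move reduces the total cost.

    Insertion moves include adjacent transpositions, so the result is a local
    minimum under adjacent swaps as the consensus contract requires.
    """
    order = list(order)
    m = len(order)
    improved = True
    while improved:
        improved = False
        for i in range(m):
            u = order[i]
            rest = order[:i] + order[i + 1:]
            # delta of inserting u at position j in rest, relative to removal
            # cost(before set) = sum W[u, w] for w after u, W[w, u] for w before
            best_j, best_delta = None, -1e-12
            base = sum(W[w, u] for w in rest[:i]) + sum(W[u, w] for w in rest[i:])
            prefix = 0.0
            for j in range(m):
                cost_j = prefix + sum(W[u, w] for w in rest[j:])
                delta = base - cost_j
                if delta > best_delta:
                    best_delta, best_j = delta, j
                if j < m - 1:
                    prefix += W[rest[j], u]
            if best_j is not None and best_j != i and best_delta > 1e-12:
                rest.insert(best_j, u)
                order = rest
                improved = True
    return np.array(order, dtype=int)


def estimate_central_ordering(all_sp: list[SubjectPosteriors],
                              names: Optional[list[str]] = None,
                              exact: Optional[bool] = None,
                              exact_max: int = 8) -> EventOrdering:
    """Consensus ordering minimising the summed probabilistic Kendall tau.

    ``exact=None`` auto-selects exhaustive search for <= ``exact_max`` events;
    ``exact=False`` forces the heuristic (mean-posterior initialisation plus
    insertion local search). Deterministic given inputs.
    """
    if len(all_sp) < 2:
        raise CohortError("need >= 2 subjects to estimate a consensus ordering")
    m = len(all_sp[0].probs)
    W = pairwise_costs(all_sp, m)

    obs_counts = np.sum([sp.observed for sp in all_sp], axis=0)
    unobserved = np.flatnonzero(obs_counts == 0)

    if exact is None:
        exact = m <= exact_max
    if exact and m > 10:
        raise CohortError(f"exhaustive search over {m}! permutations refused")

    if exact:
        best_order, best_cost = None, np.inf
        for perm in permutations(range(m)):
            c = total_distance(perm, W)
            if c < best_cost - 1e-15:
                best_cost, best_order = c, perm
        order = np.array(best_order, dtype=int)
    else:
        with np.errstate(invalid="ignore"):
            sums = np.sum([np.where(sp.observed, sp.probs, 0.0)
                           for sp in all_sp], axis=0)
            mean_post = np.where(obs_counts > 0, sums / np.maximum(obs_counts, 1), 0.0)
        init = np.argsort(-mean_post, kind="stable")
        order = _insertion_local_search(init, W)

    un_names = [names[k] for k in unobserved] if names is not None else \
        [int(k) for k in unobserved]
    return EventOrdering(order=order, names=names,
                         unobserved_events=list(un_names))


def assign_event_centers(ordering: EventOrdering,
                         all_sp: list[SubjectPosteriors],
                         mode: str = "uniform") -> EventOrdering:
    """Attach event-centre positions on [0, 1] to a fitted ordering.

    ``uniform``: c_k = (k + 0.5)/M. ``weighted``: posterior-weighted mean
    normalised rank of each event across subjects, monotonised along the
    ordering by pool-adjacent-violators.
    """
    m = ordering.n_events
    if mode == "uniform":
        centers = (np.arange(m) + 0.5) / m
    elif mode == "weighted":
        num = np.zeros(m)
        den = np.zeros(m)
        for sp in all_sp:
            idx = subject_ordering(sp) if sp.observed.any() else None
            if idx is None or idx.size == 0:
                continue
            ranks = (np.arange(idx.size) + 0.5) / idx.size
            w = sp.probs[idx]
            num[idx] += w * ranks
            den[idx] += w
        raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        along = raw[ordering.order]
        iso = IsotonicRegression(y_min=0.0, y_max=1.0, increasing=True)
        centers = iso.fit_transform(np.arange(m), along)
    else:
        raise CohortError(f"unknown center mode {mode!r}")
    return EventOrdering(order=ordering.order.copy(), names=ordering.names,
                         centers=np.asarray(centers, dtype=float),
                         unobserved_events=list(ordering.unobserved_events))
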