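"""Probabilistic Kendall tau distance, consensus ordering and event centers."""

from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ftdebm.cascade import (
    EventOrdering,
    SubjectPosteriors,
    assign_event_centers,
    compute_subject_posteriors,
    estimate_central_ordering,
    pairwise_costs,
    prob_kendall_tau,
    subject_ordering,
    total_distance,
)
from ftdebm.data_model import CohortError
from ftdebm.mixture import GaussianComponent, MixtureFit
from ftdebm.modeling import build_model


def sp(probs, observed=None, sid="s"):
    probs = np.asarray(probs, dtype=float)
    if observed is None:
        observed = np.ones_like(probs, dtype=bool)
    return SubjectPosteriors(sid, probs, np.asarray(observed, dtype=bool))


class TestSubjectOrdering:
    def test_sorts_by_descending_posterior(self):
        assert subject_ordering(sp([0.9, 0.5, 0.1])).tolist() == [0, 1, 2]
        assert subject_ordering(sp([0.1, 0.5, 0.9])).tolist() == [2, 1, 0]

    def test_ties_break_by_global_index(self):
        assert subject_ordering(sp([0.5, 0.5, 0.5])).tolist() == [0, 1, 2]

    def test_masked_entries_excluded(self):
        order = subject_ordering(sp([0.9, 0.5, 0.1], [True, False, True]))
        assert order.tolist() == [0, 2]

    def test_no_observations_raises(self):
        with pytest.raises(CohortError):
            subject_ordering(sp([0.5], [False]))


class TestProbKendallTau:
    def test_consistent_binary_probs_give_zero(self):
        assert prob_kendall_tau([0, 1, 2], sp([1.0, 1.0, 0.0])) == 0.0

    def test_reversed_binary_probs_cost_k_times_m_minus_k(self):
        # candidate places the 0-events before the 1-events: k*(m-k) pairs
        m, k = 7, 3
        probs = np.r_[np.zeros(m - k), np.ones(k)]
        assert prob_kendall_tau(np.arange(m), sp(probs)) == k * (m - k)

    def test_single_discordant_pair_costs_probability_gap(self):
        # candidate (B, A, C) against probs A=0.9, B=0.5, C=0.1
        d = prob_kendall_tau([1, 0, 2], sp([0.9, 0.5, 0.1]))
        assert d == pytest.approx(0.4)

    def test_unobserved_pairs_contribute_nothing(self):
        d = prob_kendall_tau([0, 1, 2], sp([0.2, 0.9, 0.0],
                                           [True, True, False]))
        assert d == pytest.approx(0.7)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8),
           st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_nonnegative_and_invariant_to_unobserved_position(self, probs, s):
        m = len(probs)
        rng = np.random.default_rng(s)
        observed = rng.random(m) < 0.7
        subject = sp(probs, observed)
        base = rng.permutation(m)
        d = prob_kendall_tau(base, subject)
        assert d >= 0.0
        # permuting the unobserved biomarkers inside the candidate is a no-op
        unobs = np.flatnonzero(~observed)
        if len(unobs) >= 2:
            swapped = base.copy()
            pos = [np.where(base == u)[0][0] for u in unobs[:2]]
            swapped[pos[0]], swapped[pos[1]] = swapped[pos[1]], swapped[pos[0]]
            assert prob_kendall_tau(swapped, subject) == pytest.approx(d)


class TestCentralOrdering:
    def test_unanimous_binary_subjects_recover_their_ordering(self):
        subjects = [sp([1.0, 1.0, 0.0, 0.0]) for _ in range(5)]
        ordering = estimate_central_ordering(subjects)
        assert total_distance(ordering.order,
                              pairwise_costs(subjects, 4)) == 0.0
        assert set(ordering.order[:2].tolist()) == {0, 1}

    def test_heuristic_matches_brute_force_on_fixture(self):
        rng = np.random.default_rng(2024)
        subjects = [sp(rng.random(4), sid=f"s{j}") for j in range(6)]
        W = pairwise_costs(subjects, 4)
        heur = estimate_central_ordering(subjects, exact=False)
        best = min(total_distance(p, W) for p in permutations(range(4)))
        assert total_distance(heur.order, W) == pytest.approx(best, rel=1e-12)

    def test_exact_and_heuristic_agree_on_small_problems(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            subjects = [sp(rng.random(5)) for _ in range(8)]
            W = pairwise_costs(subjects, 5)
            exact = estimate_central_ordering(subjects, exact=True)
            heur = estimate_central_ordering(subjects, exact=False)
            assert total_distance(heur.order, W) == \
                pytest.approx(total_distance(exact.order, W), rel=1e-12)

    def test_invariant_under_subject_duplication(self):
        rng = np.random.default_rng(5)
        subjects = [sp(rng.random(6), sid=f"s{j}") for j in range(7)]
        once = estimate_central_ordering(subjects, exact=True)
        twice = estimate_central_ordering(subjects + subjects, exact=True)
        assert np.array_equal(once.order, twice.order)

    def test_totally_unobserved_biomarker_is_flagged(self):
        subjects = [sp([0.9, 0.1, 0.5], [True, True, False]) for _ in range(3)]
        ordering = estimate_central_ordering(subjects, names=["a", "b", "c"])
        assert ordering.unobserved_events == ["c"]

    def test_default_cohort_recovery_beats_chance_clearly(self, default_cohort):
        """A random ordering has expected normalised distance 0.5; the
        estimate must sit far below it (the measured regime is ~0.2)."""
        from ftdebm.synthetic_data import recovery_error
        cohort, gt = default_cohort
        model, _, _ = build_model(cohort, "multimodal")
        assert recovery_error(gt.ordering, model.ordering) <= 0.3


class TestEventCenters:
    def test_uniform_centers_formula(self):
        o = EventOrdering(order=np.arange(4))
        c = assign_event_centers(o, [], mode="uniform")
        assert np.allclose(c.centers, [0.125, 0.375, 0.625, 0.875])

    def test_weighted_centers_sorted_along_ordering(self):
        rng = np.random.default_rng(3)
        subjects = [sp(rng.random(5)) for _ in range(10)]
        o = estimate_central_ordering(subjects, exact=True)
        c = assign_event_centers(o, subjects, mode="weighted")
        assert np.all(np.diff(c.centers) >= -1e-12)
        assert c.centers.min() >= 0.0 and c.centers.max() <= 1.0

    def test_weighted_centers_track_ground_truth_times(self, default_cohort):
        from scipy.stats import spearmanr
        cohort, gt = default_cohort
        model, _, csp = build_model(cohort, "multimodal")
        c = assign_event_centers(model.ordering, csp, mode="weighted")
        per_biomarker = np.empty(cohort.n_biomarkers)
        per_biomarker[c.order] = c.centers
        assert spearmanr(per_biomarker, gt.event_times).statistic > 0.5


class TestComputeSubjectPosteriors:
    @staticmethod
    def _fits(names):
        return {n: MixtureFit(normal=GaussianComponent(0.0, 1.0),
                              abnormal=GaussianComponent(4.0, 1.0),
                              mixing={"all": 0.5}, loglik=0.0) for n in names}

    def test_single_observed_biomarker(self, toy_cohort):
        fits = self._fits(toy_cohort.biomarker_names)
        sps = compute_subject_posteriors(toy_cohort, fits)
        assert sps[2].observed.sum() == 1

    def test_noncarriers_mostly_near_zero_posterior(self, clean_cohort):
        cohort, _ = clean_cohort
        model, pre, _ = build_model(cohort, "multimodal")
        sps = compute_subject_posteriors(pre, model.fits)
        probs = np.concatenate([
            s.probs[s.observed] for s, g in zip(sps, cohort.groups)
            if g == "noncarrier"])
        assert np.median(probs) <= 0.2
        assert np.mean(probs <= 0.2) >= 0.8

    def test_missing_fit_raises(self, toy_cohort):
        with pytest.raises(CohortError):
            compute_subject_posteriors(toy_cohort, {})
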