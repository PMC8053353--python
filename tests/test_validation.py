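"""Bootstrap positional variance, cross-validated staging, classification,
clinical correlation, and the differential phenotype cascades."""

import numpy as np
import pytest

from ftdebm.data_model import AnalysisConfig
from ftdebm.modeling import build_model
from ftdebm.synthetic_data import (
    DEFAULT_BASE_EVENT_TIMES,
    GeneratorConfig,
    generate_cohort,
    recovery_error,
)
from ftdebm.validation import (
    ValidationError,
    bootstrap_positional_variance,
    classify_groups,
    correlate_clinical,
    crossval_severity,
    exclude_imaging_free_symptomatic,
    phenotype_cascades,
)

FULL = {m: {g: 1.0 for g in ("symptomatic", "presymptomatic", "noncarrier")}
        for m in ("fluid", "cognitive", "grey_matter", "white_matter")}


class TestBootstrap:
    def test_single_repetition_is_permutation_matrix(self, default_cohort):
        cohort, _ = default_cohort
        cfg = AnalysisConfig(n_bootstrap=1)
        model, pre, _ = build_model(cohort, "nonimaging", cfg)
        pv = bootstrap_positional_variance(pre, model.ordering, "nonimaging", cfg)
        assert pv.counts.shape == (6, 6)
        assert (pv.counts.sum(axis=0) == 1).all()
        assert (pv.counts.sum(axis=1) == 1).all()

    def test_row_and_column_sums_equal_successful_reps(self, default_cohort):
        cohort, _ = default_cohort
        cfg = AnalysisConfig(n_bootstrap=8)
        model, pre, _ = build_model(cohort, "multimodal", cfg)
        pv = bootstrap_positional_variance(pre, model.ordering, "multimodal", cfg)
        n_ok = cfg.n_bootstrap - pv.n_dropped
        assert (pv.counts.sum(axis=0) == n_ok).all()
        assert (pv.counts.sum(axis=1) == n_ok).all()

    def test_strong_signal_keeps_modal_positions(self):
        cohort, _ = generate_cohort(GeneratorConfig(
            seed=5, effect_size=4.0, availability=FULL, confounder_scale=0.0,
            n_presymptomatic=70, n_symptomatic=45))
        cfg = AnalysisConfig(n_bootstrap=10)
        model, pre, _ = build_model(cohort, "nonimaging", cfg)
        pv = bootstrap_positional_variance(pre, model.ordering, "nonimaging", cfg)
        modal = pv.counts.argmax(axis=1)
        match = np.mean(modal == np.arange(pv.counts.shape[0]))
        assert match >= 0.8

    def test_pure_noise_less_stable_than_signal(self):
        """A null cohort's positional-variance diagram is markedly more
        diffuse than a signal cohort's (a single null cohort can still show
        cohort-specific pseudo-signal, so the check is comparative)."""
        cfg = AnalysisConfig(n_bootstrap=10)

        def mean_spread(effect, seed):
            cohort, _ = generate_cohort(GeneratorConfig(
                seed=seed, effect_size=effect, availability=FULL,
                confounder_scale=0.0))
            model, pre, _ = build_model(cohort, "nonimaging", cfg)
            pv = bootstrap_positional_variance(pre, model.ordering,
                                               "nonimaging", cfg)
            return pv.positional_spread().mean()

        null = np.mean([mean_spread(0.0, s) for s in (6, 7)])
        signal = np.mean([mean_spread(4.0, s) for s in (6, 7)])
        assert null > signal


class TestCrossval:
    def test_leave_one_out_bookkeeping(self):
        cohort, _ = generate_cohort(GeneratorConfig(
            seed=2, n_noncarrier=12, n_presymptomatic=12, n_symptomatic=12,
            availability=FULL))
        cfg = AnalysisConfig(cv_folds=3, n_bootstrap=1)
        est = crossval_severity(cohort, "nonimaging", cfg)
        # every subject staged exactly once
        ids = [e.subject_id for e in est]
        assert len(ids) == len(set(ids)) == 36

    def test_imaging_free_symptomatic_excluded(self, default_cohort):
        cohort, _ = default_cohort
        kept = exclude_imaging_free_symptomatic(cohort)
        img = [k for k, b in enumerate(cohort.biomarkers)
               if b.modality in ("grey_matter", "white_matter")]
        dropped = (~cohort.observed[:, img].any(axis=1)) & \
            (cohort.groups == "symptomatic")
        assert kept.n_subjects == cohort.n_subjects - dropped.sum()

    def test_heldout_severities_separate_groups(self, default_cohort):
        from sklearn.metrics import roc_auc_score
        cohort, _ = default_cohort
        est = crossval_severity(cohort, "multimodal", AnalysisConfig())
        by = {e.subject_id: e.severity for e in est}
        sev, lab = [], []
        for s in cohort.subjects:
            if s.group != "noncarrier" and s.subject_id in by:
                sev.append(by[s.subject_id])
                lab.append(s.group == "symptomatic")
        assert roc_auc_score(lab, sev) >= 0.95


class TestClassifyGroups:
    def test_perfect_separation(self):
        sens, spec, _ = classify_groups(
            np.array([0.8, 0.9, 0.1, 0.2]), np.array([1, 1, 0, 0], bool))
        assert sens == 1.0 and spec == 1.0

    def test_degenerate_identical_severities(self):
        sens, spec, _ = classify_groups(
            np.full(6, 0.5), np.array([1, 1, 1, 0, 0, 0], bool))
        assert sens + spec == pytest.approx(1.0)

    def test_youden_maximising_cutoff_enumeration(self):
        sev = np.array([0.9, 0.7, 0.3, 0.4, 0.2, 0.1])
        lab = np.array([1, 1, 1, 0, 0, 0], bool)
        sens, spec, thr = classify_groups(sev, lab)
        assert sens == pytest.approx(2 / 3)
        assert spec == pytest.approx(1.0)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        sev = rng.random(30)
        lab = rng.random(30) < 0.5
        lab[0], lab[1] = True, False
        a = classify_groups(sev, lab)
        b = classify_groups(np.exp(3 * sev), lab)
        assert a[0] == b[0] and a[1] == b[1]

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            classify_groups(np.array([0.1, 0.2]), np.array([1, 1], bool))


class TestCorrelateClinical:
    def test_exactly_linear_gives_r_one(self):
        y = np.arange(5.0)
        r, p = correlate_clinical(y, 2 * y + 1)
        assert r == pytest.approx(1.0)

    def test_constant_clinical_rejected(self):
        with pytest.raises(ValidationError):
            correlate_clinical(np.arange(5.0), np.full(5, 3.0))

    def test_hand_computed_fixture(self):
        sev = np.array([0.1, 0.3, 0.2, 0.8, 0.5, 0.9, 0.4])
        yrs = np.array([0.5, 1.0, 2.0, 4.0, 2.5, 6.0, 1.5])
        r, _ = correlate_clinical(sev, yrs)
        a, b = sev - sev.mean(), yrs - yrs.mean()
        expected = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
        assert r == pytest.approx(expected, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            correlate_clinical(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def _phenotype_config(seed, reversed_second=True):
    full = dict(DEFAULT_BASE_EVENT_TIMES)
    for k, v in list(full.items()):
        if k.endswith("_left"):
            full[k[:-5] + "_right"] = round(v + 0.15, 3)
    overrides = {"nfvPPA": {k: round(1.03 - v, 3) for k, v in full.items()}} \
        if reversed_second else {}
    return GeneratorConfig(
        seed=seed, n_symptomatic=80, effect_size=4.0, availability=FULL,
        confounder_scale=0.0,
        phenotype_fractions={"bvFTD": 0.5, "nfvPPA": 0.5},
        phenotype_event_times=overrides)


class TestPhenotypeCascades:
    def test_reversed_phenotypes_yield_far_apart_orderings(self):
        cohort, gt = generate_cohort(_phenotype_config(seed=0))
        res = phenotype_cascades(cohort, "multimodal", AnalysisConfig(),
                                 run_bootstrap=False)
        oA = res["per_phenotype"]["bvFTD"]["ordering"]
        oB = res["per_phenotype"]["nfvPPA"]["ordering"]
        # planted orderings are exactly reversed (distance 1); estimates from
        # 40 symptomatic subjects per phenotype must stay far apart
        assert recovery_error(gt.ordering,
                              gt.phenotype_orderings["nfvPPA"]) == 1.0
        assert recovery_error(oA, oB) >= 0.6
        # and each estimate is closer to its own truth than to the other's
        assert recovery_error(gt.ordering, oA) < \
            recovery_error(gt.phenotype_orderings["nfvPPA"], oA)
        assert recovery_error(gt.phenotype_orderings["nfvPPA"], oB) < \
            recovery_error(gt.ordering, oB)

    def test_small_phenotype_skipped_with_warning(self):
        gc = GeneratorConfig(
            seed=3, availability=FULL,
            phenotype_fractions={"bvFTD": 0.46, "nfvPPA": 0.46, "CBS": 0.08})
        cohort, _ = generate_cohort(gc)
        n_cbs = int((cohort.phenotypes == "CBS").sum())
        assert 0 < n_cbs < 5  # the seed-3 draw leaves CBS below the minimum
        res = phenotype_cascades(cohort, "nonimaging",
                                 AnalysisConfig(n_bootstrap=1))
        assert res["skipped"] == {"CBS": n_cbs}
        assert set(res["per_phenotype"]) == {"bvFTD", "nfvPPA"}

    def test_presymptomatic_subjects_are_excluded(self):
        cohort, _ = generate_cohort(_phenotype_config(seed=1,
                                                      reversed_second=False))
        res = phenotype_cascades(cohort, "nonimaging",
                                 AnalysisConfig(n_bootstrap=2))
        n_sym = int((cohort.groups == "symptomatic").sum())
        assert sum(e["n"] for e in res["per_phenotype"].values()) \
            + sum(res["skipped"].values()) == n_sym
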