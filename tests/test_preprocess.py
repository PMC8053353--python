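"""Log decision, control-referenced z-scoring, orientation and residualisation."""

import numpy as np
import pytest

from ftdebm.data_model import BiomarkerSpec, CohortTable, SubjectRecord
from ftdebm.preprocess import (
    PreprocessError,
    decide_and_apply_log,
    preprocess_cohort,
    residualize_confounders,
    zscore_to_controls,
)


def spec(log="auto"):
    return BiomarkerSpec("nfl", "fluid", "increase", log_transform=log)


class TestLogDecision:
    def test_lognormal_values_trigger_log(self):
        rng = np.random.default_rng(0)
        v = np.exp(rng.normal(0, 1, 200))
        out, flag = decide_and_apply_log(v, spec())
        assert flag
        assert np.allclose(out, np.log(v))

    def test_normal_values_left_alone(self):
        rng = np.random.default_rng(1)
        v = rng.normal(50, 5, 200)
        out, flag = decide_and_apply_log(v, spec())
        assert not flag
        assert np.array_equal(out, v)

    def test_never_is_identity(self):
        v = np.exp(np.random.default_rng(2).normal(0, 2, 100))
        out, flag = decide_and_apply_log(v, spec("never"))
        assert not flag and np.array_equal(out, v)

    def test_always_on_nonpositive_raises(self):
        with pytest.raises(PreprocessError):
            decide_and_apply_log(np.array([-1.0, 2.0, 3.0] * 5), spec("always"))


def _cohort_with_groups(values, groups, specs, covs=None):
    subjects = [
        SubjectRecord(f"s{i}", g, covariates=covs[i] if covs else {})
        for i, g in enumerate(groups)
    ]
    values = np.asarray(values, dtype=float)
    return CohortTable(subjects, specs, values, np.isfinite(values))


class TestZScore:
    def test_controls_have_mean_zero_sd_one(self, default_cohort):
        cohort, _ = default_cohort
        z, model = zscore_to_controls(cohort)
        ctrl = z.group_mask("noncarrier")
        for k in range(z.n_biomarkers):
            obs = z.observed[:, k] & ctrl
            assert abs(z.values[obs, k].mean()) < 1e-12
            assert abs(z.values[obs, k].std(ddof=1) - 1.0) < 1e-12

    def test_orientation_sign_convention(self):
        # a decreasing biomarker 2 control-SD below control mean -> z = +2
        specs = [BiomarkerSpec("mmse", "cognitive", "decrease"),
                 BiomarkerSpec("nfl", "fluid", "increase")]
        vals = [[10.0, 1.0], [12.0, 3.0], [11.0, 2.0],  # controls
                [11.0 - 2.0 * 1.0, 2.0 + 3.0 * 1.0]]  # carrier
        cohort = _cohort_with_groups(
            vals, ["noncarrier"] * 3 + ["symptomatic"], specs)
        z, _ = zscore_to_controls(cohort)
        assert z.values[3, 0] == pytest.approx(2.0)   # decrease, 2 SD below
        assert z.values[3, 1] == pytest.approx(3.0)   # increase, 3 SD above

    def test_symptomatic_mean_above_controls_after_orientation(
            self, default_cohort):
        cohort, _ = default_cohort
        z, _ = zscore_to_controls(cohort)
        sym = z.group_mask("symptomatic")
        ctrl = z.group_mask("noncarrier")
        for k in range(z.n_biomarkers):
            s = z.values[z.observed[:, k] & sym, k]
            c = z.values[z.observed[:, k] & ctrl, k]
            assert s.mean() >= c.mean()

    def test_too_few_controls_raises(self):
        specs = [BiomarkerSpec("nfl", "fluid", "increase")]
        cohort = _cohort_with_groups(
            [[1.0], [2.0], [3.0]],
            ["noncarrier", "presymptomatic", "symptomatic"], specs)
        with pytest.raises(PreprocessError, match="nfl"):
            zscore_to_controls(cohort)


class TestResidualise:
    @staticmethod
    def _age_cohort(slope=0.1, n=80, seed=3):
        rng = np.random.default_rng(seed)
        specs = [BiomarkerSpec("nfl", "fluid", "increase",
                               confounders=("age",))]
        groups = ["noncarrier"] * 20 + ["presymptomatic"] * (n - 20)
        age = rng.uniform(30, 70, n)
        vals = slope * (age - 50.0) + rng.normal(0, 1, n)
        covs = [{"age": float(a)} for a in age]
        return _cohort_with_groups(vals[:, None], groups, specs, covs), age

    def test_age_slope_removed(self):
        cohort, age = self._age_cohort()
        z, model = zscore_to_controls(cohort)
        res = residualize_confounders(z, model)
        presym = res.group_mask("presymptomatic")
        slope = np.polyfit(age[presym], res.values[presym, 0], 1)[0]
        se = res.values[presym, 0].std() / (age[presym].std()
                                            * np.sqrt(presym.sum()))
        assert abs(slope) < 2 * se

    def test_idempotent(self):
        cohort, _ = self._age_cohort()
        z, model = zscore_to_controls(cohort)
        once = residualize_confounders(z, model)
        twice = residualize_confounders(once, model)
        assert np.allclose(once.values[once.observed],
                           twice.values[twice.observed], atol=1e-8)

    def test_constant_covariates_rejected_as_rank_deficient(self):
        specs = [BiomarkerSpec("nfl", "fluid", "increase",
                               confounders=("age",))]
        groups = ["noncarrier"] * 3 + ["presymptomatic"] * 10
        covs = [{"age": 50.0}] * 13
        vals = np.arange(13.0)[:, None]
        cohort = _cohort_with_groups(vals, groups, specs, covs)
        z, model = zscore_to_controls(cohort)
        with pytest.raises(PreprocessError, match="rank-deficient"):
            residualize_confounders(z, model)

    def test_insufficient_presymptomatic_raises(self):
        specs = [BiomarkerSpec("nfl", "fluid", "increase",
                               confounders=("age",))]
        groups = ["noncarrier"] * 3 + ["presymptomatic"] * 2
        covs = [{"age": float(40 + i)} for i in range(5)]
        cohort = _cohort_with_groups(np.arange(5.0)[:, None], groups, specs, covs)
        z, model = zscore_to_controls(cohort)
        with pytest.raises(PreprocessError, match="presymptomatic"):
            residualize_confounders(z, model)


def test_full_chain_runs_on_default_cohort(default_cohort):
    cohort, _ = default_cohort
    pre, model = preprocess_cohort(cohort)
    assert pre.values.shape == cohort.values.shape
    assert np.array_equal(pre.observed, cohort.observed)
    # coefficients stored only for declared confounders
    for b in cohort.biomarkers:
        fitted = model.per_biomarker[b.name].coefficients
        declared = set(b.confounders)
        for col in fitted:
            base = col.split("[")[0]
            assert base in declared
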