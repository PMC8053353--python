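"""Raw biomarker values -> confound-corrected, consistently oriented z-scores.

Pipeline order: optional log transform (automatic for skewed biomarkers) ->
z-score against the non-carrier mean and SD -> orient so the abnormal
direction is positive for every biomarker -> regress out declared confounders
with coefficients fitted on presymptomatic carriers only (most non-carriers
come from a single centre, so they are unsuitable for estimating site and
covariate effects).

Residualisation removes only the covariate effects: the design matrix is
centred at the presymptomatic covariate means, so the presymptomatic
intercept is retained and group means stay comparable to the
control-referenced zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_model import BiomarkerSpec, CohortError, CohortTable

SHAPIRO_ALPHA = 0.05


class PreprocessError(ValueError):
    pass


@dataclass
class BiomarkerPreprocess:
    log_applied: bool = False
    log_shift: float = 0.0
    control_mean: float = 0.0
    control_sd: float = 1.0
    orientation_sign: int = 1
    coefficients: dict = field(default_factory=dict)  # design-column -> beta
    design_means: dict = field(default_factory=dict)  # design-column -> presym mean


@dataclass
class PreprocessModel:
    """Fitted per-biomarker transforms, reapplicable to new subjects."""

    per_biomarker: dict  # name -> BiomarkerPreprocess
    protocol_levels: list  # reference level first

    def to_dict(self) -> dict:
        return {
            "protocol_levels": self.protocol_levels,
            "per_biomarker": {
                name: {
                    "log_applied": p.log_applied,
                    "log_shift": p.log_shift,
                    "control_mean": p.control_mean,
                    "control_sd": p.control_sd,
                    "orientation_sign": p.orientation_sign,
                    "coefficients": p.coefficients,
                    "design_means": p.design_means,
                }
                for name, p in self.per_biomarker.items()
            },
        }


def decide_and_apply_log(values: np.ndarray, spec: BiomarkerSpec,
                         shift: float = 0.0) -> tuple[np.ndarray, bool]:
    """Apply a natural-log transform when warranted.

    ``auto``: log iff Shapiro-Wilk rejects normality at alpha=0.05 and all
    (shifted) values are positive. ``always``/``never`` force the decision.
    """
    values = np.asarray(values, dtype=float)
    mode = spec.log_transform
    if mode == "never":
        return values, False
    shifted = values + shift
    positive = bool(np.all(shifted > 0))
    if mode == "always":
        if not positive:
            raise PreprocessError(
                f"log transform requested for {spec.name} but values are not "
                f"positive (configure a shift)"
            )
        return np.log(shifted), True
    # auto
    if len(values) >= 3:
        _, p = stats.shapiro(values)
    else:
        p = 1.0
    if p < SHAPIRO_ALPHA and positive:
        return np.log(shifted), True
    return values, False


def _design_columns(spec: BiomarkerSpec, protocol_levels: list[str]) -> list[str]:
    cols: list[str] = []
    for c in spec.confounders:
        if c == "protocol":
            cols.extend(f"protocol[{lev}]" for lev in protocol_levels[1:])
        else:
            cols.append(c)
    return cols


def _design_matrix(cohort: CohortTable, spec: BiomarkerSpec,
                   protocol_levels: list[str]) -> tuple[np.ndarray, list[str]]:
    cols = _design_columns(spec, protocol_levels)
    X = np.zeros((cohort.n_subjects, len(cols)))
    for j, col in enumerate(cols):
        if col.startswith("protocol["):
            lev = col[len("protocol["):-1]
            X[:, j] = (cohort.covariate("protocol") == lev).astype(float)
        else:
            X[:, j] = cohort.covariate(col).astype(float)
    return X, cols


def zscore_to_controls(cohort: CohortTable) -> tuple[CohortTable, PreprocessModel]:
    """Log-transform where configured, z-score against non-carriers, and orient
    so the abnormal direction is positive for every biomarker."""
    ctrl = cohort.group_mask("noncarrier")
    values = cohort.values.copy()
    per: dict[str, BiomarkerPreprocess] = {}

    uses_protocol = any("protocol" in b.confounders for b in cohort.biomarkers)
    protocol_levels: list[str] = []
    if uses_protocol:
        protocol_levels = sorted(set(cohort.covariate("protocol")))

    for k, b in enumerate(cohort.biomarkers):
        obs = cohort.observed[:, k]
        transformed, logged = decide_and_apply_log(values[obs, k], b)
        values[obs, k] = transformed
        cobs = obs & ctrl
        if cobs.sum() < 2:
            raise PreprocessError(
                f"biomarker {b.name}: need >=2 non-carrier observations, "
                f"got {int(cobs.sum())}"
            )
        mu = float(values[cobs, k].mean())
        sd = float(values[cobs, k].std(ddof=1))
        if sd <= 0:
            raise PreprocessError(f"biomarker {b.name}: zero control SD")
        sign = b.orientation_sign
        values[obs, k] = sign * (values[obs, k] - mu) / sd
        per[b.name] = BiomarkerPreprocess(
            log_applied=logged, control_mean=mu, control_sd=sd,
            orientation_sign=sign,
        )

    out = CohortTable(list(cohort.subjects), list(cohort.biomarkers),
                      values, cohort.observed.copy())
    return out, PreprocessModel(per_biomarker=per, protocol_levels=protocol_levels)


def residualize_confounders(cohort: CohortTable,
                            model: PreprocessModel) -> CohortTable:
    """Regress declared confounders out of each (z-scored) biomarker.

    Coefficients are estimated by OLS on presymptomatic subjects only and
    applied to every subject, with the design centred at presymptomatic
    covariate means.
    """
    presym = cohort.group_mask("presymptomatic")
    values = cohort.values.copy()
    for k, b in enumerate(cohort.biomarkers):
        if not b.confounders:
            continue
        X, cols = _design_matrix(cohort, b, model.protocol_levels)
        obs = cohort.observed[:, k]
        fit_mask = obs & presym
        if fit_mask.sum() < len(cols) + 2:
            raise PreprocessError(
                f"biomarker {b.name}: only {int(fit_mask.sum())} presymptomatic "
                f"observations for {len(cols)} coefficients"
            )
        # Categorical dummies can be unidentifiable on the presymptomatic
        # subset (a level absent, or the reference level absent so the
        # remaining dummies hit the intercept). Such dummies are pruned and
        # their effect folded into the reference; a degenerate design among
        # the remaining (numeric) covariates is an error.
        def _is_droppable(c: str) -> bool:
            return c.startswith("protocol[") or c == "sex"

        keep = [j for j, c in enumerate(cols)
                if X[fit_mask, j].std() > 0 or not _is_droppable(c)]
        means = X[fit_mask].mean(axis=0)

        def _design(idx):
            return sm.add_constant((X - means)[np.ix_(fit_mask, idx)],
                                   has_constant="add")

        while len(keep) and \
                np.linalg.matrix_rank(_design(keep)) < len(keep) + 1:
            drop = next((j for j in reversed(keep) if _is_droppable(cols[j])),
                        None)
            if drop is None:
                break
            keep.remove(drop)
        design = _design(keep)
        if np.linalg.matrix_rank(design) < len(keep) + 1:
            raise PreprocessError(
                f"biomarker {b.name}: rank-deficient confounder design "
                f"(columns {[cols[j] for j in keep]})"
            )
        cols_used = [cols[j] for j in keep]
        Xc = (X - means)[:, keep]
        res = sm.OLS(values[fit_mask, k], design).fit()
        beta = res.params[1:]  # drop intercept: only covariate effects removed
        values[obs, k] = values[obs, k] - Xc[obs] @ beta
        pp = model.per_biomarker[b.name]
        full_beta = {c: 0.0 for c in cols}
        full_beta.update(dict(zip(cols_used, map(float, beta))))
        pp.coefficients = full_beta
        pp.design_means = dict(zip(cols, map(float, means)))
    return CohortTable(list(cohort.subjects), list(cohort.biomarkers),
                       values, cohort.observed.copy())


def preprocess_cohort(cohort: CohortTable) -> tuple[CohortTable, PreprocessModel]:
    """Full chain: log -> z-score vs non-carriers -> orient -> residualise."""
    z, model = zscore_to_controls(cohort)
    return residualize_confounders(z, model), model


def apply_preprocess(cohort: CohortTable, model: PreprocessModel) -> CohortTable:
    """Apply an already-fitted preprocessing model to (possibly new) subjects."""
    values = cohort.values.copy()
    for k, b in enumerate(cohort.biomarkers):
        pp = model.per_biomarker[b.name]
        obs = cohort.observed[:, k]
        v = values[obs, k]
        if pp.log_applied:
            v = np.log(v + pp.log_shift)
        v = pp.orientation_sign * (v - pp.control_mean) / pp.control_sd
        values[obs, k] = v
        if pp.coefficients:
            X, cols = _design_matrix(cohort, b, model.protocol_levels)
            beta = np.array([pp.coefficients[c] for c in cols])
            means = np.array([pp.design_means[c] for c in cols])
            values[obs, k] = values[obs, k] - (X[obs] - means) @ beta
    return CohortTable(list(cohort.subjects), list(cohort.biomarkers),
                       values, cohort.observed.copy())
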