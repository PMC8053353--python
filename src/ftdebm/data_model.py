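"""Core data model for event-based modelling of a cross-sectional biomarker cohort.

The cohort is a subjects x biomarkers value matrix with an explicit
observed-mask, plus per-subject metadata (mutation-carrier group, clinical
phenotype, covariates). Biomarkers carry the metadata the pipeline needs:
modality, direction of abnormal change, optional left/right pairing, and the
covariates declared as confounders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MODALITIES = ("fluid", "cognitive", "grey_matter", "white_matter")
DIRECTIONS = ("increase", "decrease")
GROUPS = ("noncarrier", "presymptomatic", "symptomatic")
PHENOTYPES = ("bvFTD", "nfvPPA", "CBS", "none")
HEMISPHERES = ("left", "right", "none")

#: covariates each modality may declare as confounders
ALLOWED_CONFOUNDERS = {
    "fluid": {"age", "sex"},
    "cognitive": {"age", "sex", "education"},
    "grey_matter": {"age", "sex", "tiv", "protocol"},
    "white_matter": {"age", "sex", "tiv", "protocol"},
}

NON_IMAGING_MODALITIES = ("fluid", "cognitive")
IMAGING_MODALITIES = ("grey_matter", "white_matter")


class CohortError(ValueError):
    """Raised on malformed cohort tables or configuration."""


@dataclass(frozen=True)
class BiomarkerSpec:
    """Metadata for one biomarker column.

    direction is the direction of *abnormal* change on the measured scale
    (NfL increases with degeneration, grey-matter volume decreases).
    pair_id links the left/right homologues of a lateralised region; exactly
    two specs may share a pair_id, one per hemisphere.
    """

    name: str
    modality: str
    direction: str
    pair_id: Optional[str] = None
    hemisphere: str = "none"
    confounders: tuple[str, ...] = ()
    log_transform: str = "never"  # auto | always | never

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise CohortError(f"unknown modality {self.modality!r} for {self.name}")
        if self.direction not in DIRECTIONS:
            raise CohortError(f"unknown direction {self.direction!r} for {self.name}")
        if self.hemisphere not in HEMISPHERES:
            raise CohortError(f"unknown hemisphere {self.hemisphere!r} for {self.name}")
        if self.log_transform not in ("auto", "always", "never"):
            raise CohortError(f"bad log_transform {self.log_transform!r} for {self.name}")
        if self.pair_id is not None and self.hemisphere == "none":
            raise CohortError(f"paired biomarker {self.name} needs a hemisphere")
        bad = set(self.confounders) - ALLOWED_CONFOUNDERS[self.modality]
        if bad:
            raise CohortError(
                f"confounder(s) {sorted(bad)} not allowed for {self.modality} "
                f"biomarker {self.name}"
            )

    @property
    def orientation_sign(self) -> int:
        """+1 if abnormal values are high on the measured scale, else -1."""
        return 1 if self.direction == "increase" else -1


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    phenotype: str = "none"
    covariates: dict = field(default_factory=dict)
    years_since_onset: Optional[float] = None
    functional_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(f"unknown group {self.group!r} for {self.subject_id}")
        if self.phenotype not in PHENOTYPES:
            raise CohortError(f"unknown phenotype {self.phenotype!r} for {self.subject_id}")
        if self.phenotype != "none" and self.group != "symptomatic":
            raise CohortError(
                f"{self.subject_id}: phenotype set but group is {self.group}"
            )
        if self.group != "symptomatic" and (
            self.years_since_onset is not None or self.functional_score is not None
        ):
            raise CohortError(
                f"{self.subject_id}: onset/functional data on non-symptomatic subject"
            )


def _check_pairs(biomarkers: list[BiomarkerSpec]) -> None:
    by_pair: dict[str, list[BiomarkerSpec]] = {}
    for bm in biomarkers:
        if bm.pair_id is not None:
            by_pair.setdefault(bm.pair_id, []).append(bm)
    for pid, members in by_pair.items():
        if len(members) != 2:
            raise CohortError(
                f"pair {pid!r} has {len(members)} member(s); exactly 2 required"
            )
        hemis = {m.hemisphere for m in members}
        if hemis != {"left", "right"}:
            raise CohortError(f"pair {pid!r} must have one left and one right member")


@dataclass
class CohortTable:
    """Subjects x biomarkers matrix with missingness mask and metadata."""

    subjects: list[SubjectRecord]
    biomarkers: list[BiomarkerSpec]
    values: np.ndarray  # (n_subjects, n_biomarkers) float
    observed: np.ndarray  # same shape, bool

    def __post_init__(self) -> None:
        n, m = len(self.subjects), len(self.biomarkers)
        self.values = np.asarray(self.values, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.values.shape != (n, m) or self.observed.shape != (n, m):
            raise CohortError(
                f"value/mask shape {self.values.shape}/{self.observed.shape} "
                f"does not match {n} subjects x {m} biomarkers"
            )
        if not np.all(np.isfinite(self.values[self.observed])):
            raise CohortError("non-finite value in an observed cell")
        names = [b.name for b in self.biomarkers]
        if len(set(names)) != len(names):
            raise CohortError("duplicate biomarker names")
        sids = [s.subject_id for s in self.subjects]
        if len(set(sids)) != len(sids):
            raise CohortError("duplicate subject ids")
        _check_pairs(self.biomarkers)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_biomarkers(self) -> int:
        return len(self.biomarkers)

    @property
    def biomarker_names(self) -> list[str]:
        return [b.name for b in self.biomarkers]

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def phenotypes(self) -> np.ndarray:
        return np.array([s.phenotype for s in self.subjects])

    def group_mask(self, *groups: str) -> np.ndarray:
        return np.isin(self.groups, groups)

    def biomarker_index(self, name: str) -> int:
        try:
            return self.biomarker_names.index(name)
        except ValueError:
            raise CohortError(f"unknown biomarker {name!r}") from None

    def covariate(self, name: str) -> np.ndarray:
        vals = [s.covariates.get(name) for s in self.subjects]
        if any(v is None for v in vals):
            missing = [s.subject_id for s, v in zip(self.subjects, vals) if v is None]
            raise CohortError(f"covariate {name!r} missing for subjects {missing[:5]}")
        return np.asarray(vals)

    def subset_biomarkers(self, names: list[str]) -> "CohortTable":
        idx = [self.biomarker_index(n) for n in names]
        bms = [self.biomarkers[i] for i in idx]
        # drop pairings whose partner is not retained
        kept = {b.name for b in bms}
        pruned = []
        for b in bms:
            partner_in = any(
                o.pair_id == b.pair_id and o.name != b.name for o in bms
            ) if b.pair_id else False
            if b.pair_id and not partner_in:
                pruned.append(
                    BiomarkerSpec(b.name, b.modality, b.direction, None, "none",
                                  b.confounders, b.log_transform)
                )
            else:
                pruned.append(b)
        del kept
        return CohortTable(
            subjects=list(self.subjects),
            biomarkers=pruned,
            values=self.values[:, idx].copy(),
            observed=self.observed[:, idx].copy(),
        )

    def subset_subjects(self, mask: np.ndarray) -> "CohortTable":
        mask = np.asarray(mask, dtype=bool)
        return CohortTable(
            subjects=[s for s, keep in zip(self.subjects, mask) if keep],
            biomarkers=list(self.biomarkers),
            values=self.values[mask].copy(),
            observed=self.observed[mask].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Flat per-subject table (metadata + biomarker values, NaN = unobserved)."""
        rows = []
        for i, s in enumerate(self.subjects):
            row: dict = {
                "subject_id": s.subject_id,
                "group": s.group,
                "phenotype": s.phenotype,
                **s.covariates,
                "years_since_onset": s.years_since_onset,
                "functional_score": s.functional_score,
            }
            for k, b in enumerate(self.biomarkers):
                row[b.name] = self.values[i, k] if self.observed[i, k] else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class AnalysisConfig:
    """Settings for a full analysis run."""

    n_bootstrap: int = 100
    bootstrap_seed_base: int = 0
    cv_folds: int = 10
    cv_seed: int = 42
    severity_mode: str = "expectation"  # expectation | argmax
    center_mode: str = "uniform"  # uniform | weighted
    exact_ordering_max: int = 8  # exhaustive consensus search up to this many events
    mixture_maxiter: int = 500
    mixture_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1:
            raise CohortError("n_bootstrap must be >= 1")
        if self.cv_folds < 2:
            raise CohortError("cv_folds must be >= 2")
        if self.severity_mode not in ("argmax", "expectation"):
            raise CohortError(f"bad severity_mode {self.severity_mode!r}")
        if self.center_mode not in ("uniform", "weighted"):
            raise CohortError(f"bad center_mode {self.center_mode!r}")


# --------------------------------------------------------------------------
# Default biomarker battery: serum NfL, MMSE, four cognitive domains, and
# left/right grey-matter regions and white-matter tracts.
# --------------------------------------------------------------------------

_GM_REGIONS = ("insula", "frontal", "parietal", "temporal")
_WM_TRACTS = (
    "anterior_thalamic_radiation",
    "superior_longitudinal_fasciculus",
    "uncinate_fasciculus",
    "forceps_minor",
)


def default_biomarkers(pair_forceps_minor: bool = True) -> list[BiomarkerSpec]:
    """The default 22-biomarker battery.

    The forceps minor is a midline tract recorded as separate left/right
    columns; its pairing can be disabled while keeping both columns.
    """
    specs: list[BiomarkerSpec] = [
        BiomarkerSpec("nfl", "fluid", "increase", confounders=("age", "sex")),
        BiomarkerSpec("mmse", "cognitive", "decrease",
                      confounders=("age", "sex", "education")),
    ]
    for dom in ("attention_processing_speed", "executive_functioning",
                "language", "social_cognition"):
        specs.append(
            BiomarkerSpec(dom, "cognitive", "decrease",
                          confounders=("age", "sex", "education"))
        )
    imaging_conf = ("age", "sex", "tiv", "protocol")
    for region in _GM_REGIONS:
        for hemi in ("left", "right"):
            specs.append(
                BiomarkerSpec(f"{region}_gm_{hemi}", "grey_matter", "decrease",
                              pair_id=f"{region}_gm", hemisphere=hemi,
                              confounders=imaging_conf)
            )
    for tract in _WM_TRACTS:
        paired = pair_forceps_minor or tract != "forceps_minor"
        for hemi in ("left", "right"):
            specs.append(
                BiomarkerSpec(f"{tract}_fa_{hemi}", "white_matter", "decrease",
                              pair_id=f"{tract}_fa" if paired else None,
                              hemisphere=hemi if paired else "none",
                              confounders=imaging_conf)
            )
    return specs
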