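"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a three-group genetic-FTD cohort: 35 symptomatic and
56 presymptomatic mutation carriers plus 35 healthy non-carriers. Each
subject carries a latent disease stage s in [0, 1] (non-carriers s = 0;
presymptomatic low; symptomatic high). Each biomarker k has a ground-truth
event time t_k; the subject's biomarker is abnormal with probability
sigmoid((s - t_k)/tau). Values are drawn on the oriented z scale — N(0, 1)
when normal, N(delta, ratio^2) when abnormal — then de-oriented to the
declared abnormal direction, mapped to a raw measurement scale, perturbed by
linear covariate (confounder) effects, and masked with
missing-completely-at-random missingness per modality x group at the study's
reported availability rates (a subject loses a whole modality at once, as
with a missing MRI session).

Right-hemisphere homologues lag their left counterpart by ``asymmetry_lag``,
reproducing the left-before-right atrophy pattern. In phenotype mode each
symptomatic subject is assigned a phenotype and uses that phenotype's event
times, so phenotype-specific cascades can be planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cascade import EventOrdering
from .data_model import (
    BiomarkerSpec,
    CohortError,
    CohortTable,
    SubjectRecord,
    default_biomarkers,
)

#: modality availability per group (fraction observed), matching the study's
#: reported data availability.
DEFAULT_AVAILABILITY = {
    "fluid": {"symptomatic": 0.917, "presymptomatic": 0.6964, "noncarrier": 0.9167},
    "cognitive": {"symptomatic": 0.917, "presymptomatic": 0.9821, "noncarrier": 0.9167},
    "grey_matter": {"symptomatic": 0.444, "presymptomatic": 0.964, "noncarrier": 0.886},
    "white_matter": {"symptomatic": 0.50, "presymptomatic": 0.929, "noncarrier": 0.914},
}

#: ground-truth event times for the left/base biomarkers; right homologues
#: are generated at t + asymmetry_lag. Mirrors the qualitative cascade of the
#: disease: language and NfL first, white matter before grey matter, left
#: before right.
DEFAULT_BASE_EVENT_TIMES = {
    "language": 0.12,
    "nfl": 0.16,
    "anterior_thalamic_radiation_fa_left": 0.20,
    "attention_processing_speed": 0.25,
    "uncinate_fasciculus_fa_left": 0.30,
    "insula_gm_left": 0.34,
    "executive_functioning": 0.40,
    "superior_longitudinal_fasciculus_fa_left": 0.44,
    "temporal_gm_left": 0.52,
    "forceps_minor_fa_left": 0.56,
    "mmse": 0.62,
    "frontal_gm_left": 0.66,
    "social_cognition": 0.72,
    "parietal_gm_left": 0.76,
}

#: raw measurement scale (control mean, control sd) per biomarker family, so
#: generated tables look like real units rather than z-scores.
_RAW_SCALES = {
    "fluid": (20.0, 6.0),
    "cognitive": (0.0, 1.0),
    "grey_matter": (8.0, 1.2),
    "white_matter": (0.45, 0.04),
}

_SITES = ("rotterdam", "brescia", "barcelona")
_SITE_PROBS = (0.6, 0.3, 0.1)
_SITE_SHIFT = {"rotterdam": 0.0, "brescia": 0.2, "barcelona": -0.2}


@dataclass
class GeneratorConfig:
    n_noncarrier: int = 35
    n_presymptomatic: int = 56
    n_symptomatic: int = 35
    effect_size: float = 3.0  # abnormal-mean separation, control-SD units
    abnormal_sd_ratio: float = 1.0
    transition_sharpness: float = 0.05  # tau of the abnormality sigmoid
    asymmetry_lag: float = 0.15  # added to right-hemisphere event times
    base_event_times: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_EVENT_TIMES))
    availability: dict = field(
        default_factory=lambda: {m: dict(g) for m, g in DEFAULT_AVAILABILITY.items()})
    confounder_scale: float = 1.0  # 0 disables confounder effects
    phenotype_fractions: dict = field(
        default_factory=lambda: {"bvFTD": 17 / 35, "nfvPPA": 16 / 35, "CBS": 2 / 35})
    phenotype_event_times: dict = field(default_factory=dict)  # phenotype -> overrides
    presym_stage_range: tuple = (0.0, 0.6)  # Beta(2,5) scaled into this range
    sym_stage_range: tuple = (0.4, 1.0)  # Beta(5,2) scaled into this range
    noncarriers_healthy: bool = True  # draw non-carriers fully normal
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_noncarrier, self.n_presymptomatic, self.n_symptomatic) < 0:
            raise CohortError("group sizes must be >= 0")
        for mod, per_group in self.availability.items():
            for g, r in per_group.items():
                if not 0.0 <= r <= 1.0:
                    raise CohortError(f"availability[{mod}][{g}]={r} outside [0,1]")
        for name, t in self.base_event_times.items():
            if not 0.0 <= t <= 1.0:
                raise CohortError(f"event time for {name} outside [0,1]")


@dataclass
class GroundTruth:
    stages: np.ndarray  # per-subject latent stage
    abnormal: np.ndarray  # subject x biomarker indicator
    event_times: np.ndarray  # per-biomarker t_k (base cascade)
    ordering: EventOrdering  # base ground-truth cascade
    phenotype_orderings: dict = field(default_factory=dict)


def _event_times(specs: list[BiomarkerSpec], base: dict, lag: float) -> np.ndarray:
    times = np.empty(len(specs))
    for k, b in enumerate(specs):
        if b.name in base:
            times[k] = base[b.name]
        elif b.name.endswith("_right"):
            left = b.name[: -len("_right")] + "_left"
            if left not in base:
                raise CohortError(f"no event time for {b.name} (or {left})")
            times[k] = base[left] + lag
        else:
            raise CohortError(f"no event time for biomarker {b.name}")
    if np.any(times > 1.0) or np.any(times < 0.0):
        raise CohortError("event times (with asymmetry lag) must stay in [0,1]")
    return times


def _ordering_from_times(times: np.ndarray, names: list[str]) -> EventOrdering:
    order = np.argsort(times, kind="stable")  # ties: configuration order
    return EventOrdering(order=order, names=names)


def _scaled_beta(rng, a, b, lo, hi, size):
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def generate_cohort(gc: Optional[GeneratorConfig] = None,
                    specs: Optional[list[BiomarkerSpec]] = None
                    ) -> tuple[CohortTable, GroundTruth]:
    """Draw one synthetic cohort; identical config and seed give a
    bit-identical cohort."""
    gc = gc or GeneratorConfig()
    specs = specs or default_biomarkers()
    rng = np.random.default_rng(gc.seed)
    names = [b.name for b in specs]
    m = len(specs)

    times = _event_times(specs, gc.base_event_times, gc.asymmetry_lag)
    pheno_times: dict[str, np.ndarray] = {}
    for ph, overrides in gc.phenotype_event_times.items():
        merged = dict(gc.base_event_times)
        merged.update(overrides)
        pheno_times[ph] = _event_times(specs, merged, gc.asymmetry_lag)

    groups = (["noncarrier"] * gc.n_noncarrier
              + ["presymptomatic"] * gc.n_presymptomatic
              + ["symptomatic"] * gc.n_symptomatic)
    n = len(groups)

    stages = np.zeros(n)
    pres = slice(gc.n_noncarrier, gc.n_noncarrier + gc.n_presymptomatic)
    sym = slice(gc.n_noncarrier + gc.n_presymptomatic, n)
    stages[pres] = _scaled_beta(rng, 2, 5, *gc.presym_stage_range,
                                gc.n_presymptomatic)
    stages[sym] = _scaled_beta(rng, 5, 2, *gc.sym_stage_range, gc.n_symptomatic)

    # phenotype assignment for symptomatic subjects
    phenos = np.array(["none"] * n, dtype=object)
    ph_names = list(gc.phenotype_fractions)
    if ph_names and gc.n_symptomatic:
        p = np.array([gc.phenotype_fractions[k] for k in ph_names], dtype=float)
        p = p / p.sum()
        phenos[sym] = rng.choice(ph_names, size=gc.n_symptomatic, p=p)

    # covariates
    age = np.clip(rng.normal(55, 12, n), 25, 85)
    age[sym.start:] = np.clip(rng.normal(62, 7, gc.n_symptomatic), 35, 90)
    sex = rng.integers(0, 2, n).astype(float)
    education = np.clip(rng.normal(13, 3, n), 5, 22)
    tiv = np.clip(rng.normal(1.4, 0.15, n), 1.0, 1.9)
    site = rng.choice(_SITES, size=n, p=_SITE_PROBS)

    # abnormality indicators and oriented-z values
    tau = gc.transition_sharpness
    t_by_subject = np.tile(times, (n, 1))
    for i in range(n):
        if phenos[i] in pheno_times:
            t_by_subject[i] = pheno_times[phenos[i]]
    with np.errstate(over="ignore"):
        p_abn = 1.0 / (1.0 + np.exp(-(stages[:, None] - t_by_subject) / tau))
    if gc.noncarriers_healthy:
        # the emulated cohort's non-carriers are healthy by definition; do not
        # let the sigmoid's tail plant abnormal values in the control group
        p_abn[np.array(groups) == "noncarrier"] = 0.0
    abnormal = rng.random((n, m)) < p_abn
    z = rng.normal(0.0, 1.0, (n, m))
    z[abnormal] = rng.normal(gc.effect_size, gc.abnormal_sd_ratio,
                             int(abnormal.sum()))

    # confounder effects on the z scale (modest; exercised by preprocessing)
    conf = np.zeros((n, m))
    if gc.confounder_scale:
        cs = gc.confounder_scale
        site_shift = np.array([_SITE_SHIFT[s] for s in site])
        for k, b in enumerate(specs):
            eff = np.zeros(n)
            if "age" in b.confounders:
                eff += 0.008 * (age - 55.0)
            if "sex" in b.confounders:
                eff += 0.2 * (sex - 0.5)
            if "education" in b.confounders:
                eff += -0.02 * (education - 13.0)
            if "tiv" in b.confounders:
                eff += 0.5 * (tiv - 1.4)
            if "protocol" in b.confounders:
                eff += site_shift
            conf[:, k] = cs * eff
    z_conf = z + conf

    # de-orient and map to a raw measurement scale
    values = np.empty((n, m))
    for k, b in enumerate(specs):
        mu_raw, sd_raw = _RAW_SCALES[b.modality]
        values[:, k] = mu_raw + sd_raw * b.orientation_sign * z_conf[:, k]

    # modality-level missingness (MCAR within modality x group)
    observed = np.ones((n, m), dtype=bool)
    modalities = sorted({b.modality for b in specs})
    for mod in modalities:
        cols = [k for k, b in enumerate(specs) if b.modality == mod]
        rates = gc.availability.get(mod, {})
        for i, g in enumerate(groups):
            avail = rates.get(g, 1.0)
            if rng.random() >= avail:
                observed[i, cols] = False
    values[~observed] = np.nan

    # subject records; symptomatic get years-since-onset and a functional
    # score increasing with stage
    subjects = []
    for i in range(n):
        yso = fs = None
        if groups[i] == "symptomatic":
            yso = float(np.clip((stages[i] - 0.4) * 8 + rng.normal(0, 0.5),
                                0.0, None))
            fs = float(np.clip(stages[i] * 16 - 4 + rng.normal(0, 1.0),
                               0.0, None))
        subjects.append(SubjectRecord(
            subject_id=f"S{i:03d}", group=groups[i], phenotype=str(phenos[i]),
            covariates={"age": float(age[i]), "sex": float(sex[i]),
                        "education": float(education[i]), "tiv": float(tiv[i]),
                        "protocol": str(site[i])},
            years_since_onset=yso, functional_score=fs,
        ))

    cohort = CohortTable(subjects, list(specs), values, observed)
    gt = GroundTruth(
        stages=stages, abnormal=abnormal, event_times=times,
        ordering=_ordering_from_times(times, names),
        phenotype_orderings={ph: _ordering_from_times(t, names)
                             for ph, t in pheno_times.items()},
    )
    return cohort, gt


def recovery_error(true_ordering: EventOrdering,
                   estimated: EventOrdering) -> float:
    """Normalised Kendall distance between two orderings: discordant pairs
    over M(M-1)/2. 0 = identical, 1 = fully reversed."""
    if true_ordering.n_events != estimated.n_events:
        raise CohortError("orderings cover different biomarker sets")
    m = true_ordering.n_events
    if m < 2:
        return 0.0
    pos_true = true_ordering.position_of()
    pos_est = estimated.position_of()
    if true_ordering.names is not None and estimated.names is not None:
        if set(true_ordering.names) != set(estimated.names):
            raise CohortError("orderings cover different biomarker sets")
        if true_ordering.names != estimated.names:
            # re-index the estimated positions into the true ordering's space
            est_idx = {nm: k for k, nm in enumerate(estimated.names)}
            pos_est = np.array([pos_est[est_idx[nm]]
                                for nm in true_ordering.names])
    disc = 0
    for u in range(m):
        for v in range(u + 1, m):
            if (pos_true[u] - pos_true[v]) * (pos_est[u] - pos_est[v]) < 0:
                disc += 1
    return disc / (m * (m - 1) / 2)


def left_before_right_fraction(specs: list[BiomarkerSpec],
                               ordering: EventOrdering) -> float:
    """Fraction of left/right pairs whose left member precedes the right."""
    pos = ordering.position_of()
    names = {b.name: k for k, b in enumerate(specs)}
    ok = tot = 0
    seen = set()
    for b in specs:
        if b.pair_id is None or b.pair_id in seen:
            continue
        seen.add(b.pair_id)
        pair = [x for x in specs if x.pair_id == b.pair_id]
        left = next(x for x in pair if x.hemisphere == "left")
        right = next(x for x in pair if x.hemisphere == "right")
        tot += 1
        if pos[names[left.name]] < pos[names[right.name]]:
            ok += 1
    return ok / tot if tot else float("nan")
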