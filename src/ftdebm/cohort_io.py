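"""Reading, writing and validation of cohort tables and analysis configuration.

Interchange format: a comma-separated table with a header row, one row per
subject, UTF-8; empty cells or ``NA`` denote missing values. Metadata columns
(``subject_id``, ``group``, ``phenotype``, covariates, ``years_since_onset``,
``functional_score``) sit alongside one numeric column per biomarker. The
analysis configuration is a YAML document naming the biomarkers, their
abnormality directions, pairings and confounders.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    AnalysisConfig,
    BiomarkerSpec,
    CohortError,
    CohortTable,
    SubjectRecord,
    default_biomarkers,
)

NA_STRINGS = ("", "NA", "NaN", "nan")

METADATA_COLUMNS = ("subject_id", "group", "phenotype",
                    "years_since_onset", "functional_score")
NUMERIC_COVARIATES = ("age", "education", "tiv")
CATEGORICAL_COVARIATES = ("sex", "protocol")
COVARIATE_COLUMNS = NUMERIC_COVARIATES + CATEGORICAL_COVARIATES


def biomarker_from_dict(d: dict) -> BiomarkerSpec:
    return BiomarkerSpec(
        name=d["name"],
        modality=d["modality"],
        direction=d["direction"],
        pair_id=d.get("pair_id"),
        hemisphere=d.get("hemisphere", "none"),
        confounders=tuple(d.get("confounders", ())),
        log_transform=d.get("log_transform", "never"),
    )


def biomarker_to_dict(b: BiomarkerSpec) -> dict:
    return {
        "name": b.name,
        "modality": b.modality,
        "direction": b.direction,
        "pair_id": b.pair_id,
        "hemisphere": b.hemisphere,
        "confounders": list(b.confounders),
        "log_transform": b.log_transform,
    }


def default_config_dict() -> dict:
    return {
        "biomarkers": [biomarker_to_dict(b) for b in default_biomarkers()],
        "analysis": {},
    }


def load_config(config_path: str | Path) -> tuple[list[BiomarkerSpec], AnalysisConfig]:
    with open(config_path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "biomarkers" not in raw:
        raise CohortError(f"config {config_path} must define a 'biomarkers' list")
    specs = [biomarker_from_dict(d) for d in raw["biomarkers"]]
    cfg = AnalysisConfig(**raw.get("analysis", {}))
    return specs, cfg


def write_config(config_path: str | Path,
                 biomarkers: list[BiomarkerSpec],
                 analysis: Optional[AnalysisConfig] = None) -> None:
    doc: dict = {"biomarkers": [biomarker_to_dict(b) for b in biomarkers]}
    if analysis is not None:
        doc["analysis"] = {
            "n_bootstrap": analysis.n_bootstrap,
            "bootstrap_seed_base": analysis.bootstrap_seed_base,
            "cv_folds": analysis.cv_folds,
            "cv_seed": analysis.cv_seed,
            "severity_mode": analysis.severity_mode,
            "center_mode": analysis.center_mode,
        }
    with open(config_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _parse_float(cell, row: int, col: str) -> float:
    try:
        return float(cell)
    except (TypeError, ValueError):
        raise CohortError(
            f"non-numeric value {cell!r} in column {col!r}, row {row}"
        ) from None


def read_cohort(table_path: str | Path,
                config_path: str | Path) -> tuple[CohortTable, AnalysisConfig]:
    """Read and validate a cohort CSV against a YAML configuration."""
    specs, cfg = load_config(config_path)
    df = pd.read_csv(table_path, dtype=str, keep_default_na=False)

    for col in ("subject_id", "group"):
        if col not in df.columns:
            raise CohortError(f"mandatory column {col!r} missing from {table_path}")
    for b in specs:
        if b.name not in df.columns:
            raise CohortError(f"biomarker column {b.name!r} missing from {table_path}")

    def cell(row, col):
        v = row[col] if col in df.columns else ""
        return None if str(v).strip() in NA_STRINGS else str(v).strip()

    subjects: list[SubjectRecord] = []
    n, m = len(df), len(specs)
    values = np.full((n, m), np.nan)
    observed = np.zeros((n, m), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        covs: dict = {}
        for c in NUMERIC_COVARIATES:
            v = cell(row, c)
            if v is not None:
                covs[c] = _parse_float(v, i, c)
        for c in CATEGORICAL_COVARIATES:
            v = cell(row, c)
            if v is not None:
                covs[c] = float(v) if c == "sex" else v
        yso = cell(row, "years_since_onset")
        fs = cell(row, "functional_score")
        subjects.append(SubjectRecord(
            subject_id=cell(row, "subject_id"),
            group=cell(row, "group"),
            phenotype=cell(row, "phenotype") or "none",
            covariates=covs,
            years_since_onset=_parse_float(yso, i, "years_since_onset") if yso else None,
            functional_score=_parse_float(fs, i, "functional_score") if fs else None,
        ))
        for k, b in enumerate(specs):
            v = cell(row, b.name)
            if v is not None:
                values[i, k] = _parse_float(v, i, b.name)
                observed[i, k] = True

    return CohortTable(subjects, specs, values, observed), cfg


def write_cohort(cohort: CohortTable, table_path: str | Path,
                 float_format: str | None = None) -> None:
    """Write the cohort back to CSV (empty cell = unobserved).

    The default float format is full repr precision, so a write/read
    round-trip reproduces values exactly.
    """
    df = cohort.to_frame()
    df.to_csv(table_path, index=False, float_format=float_format, na_rep="")


# --------------------------------------------------------------------------
# Validation report
# --------------------------------------------------------------------------

def validate_cohort(cohort: CohortTable) -> dict:
    """Report per-biomarker availability by group, all-missing modalities and
    pairing consistency. Purely diagnostic; never mutates the cohort."""
    report: dict = {"errors": [], "warnings": []}
    groups = cohort.groups
    if not np.any(groups == "noncarrier"):
        report["errors"].append("no reference group")

    avail: dict[str, dict[str, float]] = {}
    for k, b in enumerate(cohort.biomarkers):
        avail[b.name] = {}
        for g in ("noncarrier", "presymptomatic", "symptomatic"):
            gm = groups == g
            avail[b.name][g] = (
                float(cohort.observed[gm, k].mean()) if gm.any() else float("nan")
            )
    report["availability"] = avail

    modalities = sorted({b.modality for b in cohort.biomarkers})
    all_missing: dict[str, list[str]] = {mod: [] for mod in modalities}
    for mod in modalities:
        cols = [k for k, b in enumerate(cohort.biomarkers) if b.modality == mod]
        miss = ~cohort.observed[:, cols].any(axis=1)
        all_missing[mod] = [s.subject_id for s, m in zip(cohort.subjects, miss) if m]
    report["subjects_all_missing_by_modality"] = all_missing

    no_obs = ~cohort.observed.any(axis=1)
    if no_obs.any():
        report["warnings"].append(
            "subjects with zero observed biomarkers: "
            + ", ".join(s.subject_id for s, m in zip(cohort.subjects, no_obs) if m)
        )
    report["pairs_ok"] = True  # CohortTable construction enforces pairing
    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
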