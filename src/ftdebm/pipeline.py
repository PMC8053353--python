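"""End-to-end analysis run: preprocess -> mixtures -> cascade -> staging ->
validation (+ optional phenotype cascades), with result artifacts and a run
manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .cohort_io import read_cohort, write_report
from .data_model import AnalysisConfig, CohortTable
from .modeling import VARIANTS, build_model
from .staging import stage_cohort, staging_table
from .validation import (
    ValidationError,
    bootstrap_positional_variance,
    crossval_severity,
    phenotype_cascades,
    validation_metrics,
)

log = logging.getLogger("ftdebm")


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ordering_to_dict(ordering) -> dict:
    return {
        "events": ordering.ordered_names(),
        "centers": None if ordering.centers is None else
        [float(c) for c in ordering.centers],
        "unobserved_events": list(ordering.unobserved_events),
    }


def run_full_analysis(cohort_path: str | Path, config_path: str | Path,
                      out_dir: str | Path,
                      variants: tuple = ("nonimaging", "multimodal"),
                      run_phenotypes: bool = False) -> dict:
    """Run the requested model variants and write all artifacts to out_dir.

    Identical inputs and configuration produce byte-identical artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, config = read_cohort(cohort_path, config_path)
    manifest: dict = {
        "version": __version__,
        "input_digest": _digest(cohort_path),
        "config_digest": _digest(config_path),
        "seeds": {"bootstrap_seed_base": config.bootstrap_seed_base,
                  "cv_seed": config.cv_seed},
        "variants": list(variants),
        "started_unix": int(time.time()),
        "stages": {},
    }
    try:
        for variant in variants:
            if variant not in VARIANTS:
                raise ValidationError(f"unknown variant {variant!r}")
            _run_variant(cohort, config, variant, out, manifest,
                         run_phenotypes)
    except Exception as exc:  # mark partial results before re-raising
        (out / "PARTIAL").write_text(
            f"run aborted in stage {manifest.get('current_stage')}: {exc}\n")
        raise
    manifest["finished_unix"] = int(time.time())
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _run_variant(cohort: CohortTable, config: AnalysisConfig, variant: str,
                 out: Path, manifest: dict, run_phenotypes: bool) -> None:
    t0 = time.time()
    manifest["current_stage"] = f"{variant}:model"
    model, pre, carrier_sp = build_model(cohort, variant, config)
    log.info("%s: consensus ordering estimated (%d events)", variant,
             model.ordering.n_events)
    with open(out / f"ordering_{variant}.json", "w") as fh:
        json.dump(ordering_to_dict(model.ordering), fh, indent=2)

    manifest["current_stage"] = f"{variant}:mixtures"
    with open(out / f"mixtures_{variant}.json", "w") as fh:
        json.dump({name: fit.to_dict() for name, fit in model.fits.items()},
                  fh, indent=2)
    _export_mixture_diagnostics(pre, model, out / f"gmm_diagnostics_{variant}.json")

    manifest["current_stage"] = f"{variant}:staging"
    from .cascade import compute_subject_posteriors
    all_sp = compute_subject_posteriors(pre, model.fits)
    all_sp = [sp for sp in all_sp if sp.observed.any()]
    estimates = stage_cohort(all_sp, model.ordering, config.severity_mode)
    staging_table(pre, estimates).to_csv(out / f"staging_{variant}.csv",
                                         index=False)

    manifest["current_stage"] = f"{variant}:bootstrap"
    pv = bootstrap_positional_variance(pre, model.ordering, variant, config)
    pv.to_frame().to_csv(out / f"positional_variance_{variant}.tsv", sep="\t")

    manifest["current_stage"] = f"{variant}:crossval"
    cv_estimates = crossval_severity(cohort, variant, config)
    metrics = validation_metrics(cohort, cv_estimates)
    metrics["n_staged_heldout"] = len(cv_estimates)
    metrics["bootstrap_dropped"] = pv.n_dropped
    with open(out / f"metrics_{variant}.json", "w") as fh:
        json.dump(metrics, fh, indent=2)

    if run_phenotypes:
        manifest["current_stage"] = f"{variant}:phenotypes"
        try:
            res = phenotype_cascades(cohort, variant, config)
        except ValidationError as exc:
            log.warning("%s: phenotype analysis skipped (%s)", variant, exc)
        else:
            doc = {"skipped": res["skipped"], "per_phenotype": {}}
            for ph, entry in res["per_phenotype"].items():
                doc["per_phenotype"][ph] = {
                    "n": entry["n"],
                    "ordering": ordering_to_dict(entry["ordering"]),
                }
                if "positional_variance" in entry:
                    entry["positional_variance"].to_frame().to_csv(
                        out / f"positional_variance_{variant}_{ph}.tsv", sep="\t")
            with open(out / f"phenotype_cascades_{variant}.json", "w") as fh:
                json.dump(doc, fh, indent=2)

    manifest["stages"][variant] = {"seconds": round(time.time() - t0, 2)}


def _export_mixture_diagnostics(pre: CohortTable, model, path: Path,
                                n_bins: int = 20) -> None:
    """Per-biomarker histogram (by group) plus fitted mixture parameters —
    machine-readable content for normal/abnormal distribution plots."""
    doc: dict = {}
    groups = pre.groups
    for k, b in enumerate(pre.biomarkers):
        obs = pre.observed[:, k]
        v = pre.values[obs, k]
        if v.size == 0:
            continue
        edges = np.histogram_bin_edges(v, bins=n_bins)
        hist = {}
        for g in ("noncarrier", "presymptomatic", "symptomatic"):
            gv = pre.values[obs & (groups == g), k]
            hist[g] = np.histogram(gv, bins=edges)[0].tolist()
        fit = model.fits[b.name]
        doc[b.name] = {
            "bin_edges": edges.tolist(),
            "counts_by_group": hist,
            "fit": fit.to_dict(),
        }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def validate_cohort_file(cohort_path: str | Path, config_path: str | Path,
                         out_path: Optional[str | Path] = None) -> dict:
    from .cohort_io import validate_cohort
    cohort, _ = read_cohort(cohort_path, config_path)
    report = validate_cohort(cohort)
    if out_path is not None:
        write_report(report, out_path)
    return report
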