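"""Cross-validated disease-severity validation on the simulated cohort.

Reports how well held-out (10-fold) severities delineate symptomatic from
presymptomatic carriers (AUC, Youden sensitivity/specificity) and how they
correlate with the simulated clinical measures (years since onset and the
functional score) in the symptomatic phenotypes.

Run analysis/01_simulate_cohort.py first. Output: results/staging_validation.json
"""

import json
from pathlib import Path

import numpy as np
from sklearn.metrics import roc_auc_score

from ftdebm.cohort_io import read_cohort
from ftdebm.validation import crossval_severity, validation_metrics

ROOT = Path(__file__).resolve().parents[1] / "results"
COHORT = ROOT / "cohort"


def main() -> None:
    cohort, config = read_cohort(COHORT / "cohort.csv", COHORT / "config.yaml")
    doc = {}
    for variant in ("nonimaging", "multimodal"):
        est = crossval_severity(cohort, variant, config)
        metrics = validation_metrics(cohort, est)
        by = {e.subject_id: e.severity for e in est}
        sev, lab = [], []
        for s in cohort.subjects:
            if s.group != "noncarrier" and s.subject_id in by:
                sev.append(by[s.subject_id])
                lab.append(s.group == "symptomatic")
        metrics["auc"] = float(roc_auc_score(lab, sev))
        metrics["n_staged_heldout"] = len(est)
        doc[variant] = metrics
        print(f"{variant}: AUC {metrics['auc']:.3f}, "
              f"sensitivity {metrics['sensitivity']:.3f}, "
              f"specificity {metrics['specificity']:.3f} "
              f"at severity threshold {metrics['threshold']:.3f} "
              f"({metrics['n_staged_heldout']} held-out subjects)")
        for key, val in metrics["correlations"].items():
            print(f"  {key}: r = {val['r']:+.2f} (p = {val['p']:.3g})")
    with open(ROOT / "staging_validation.json", "w") as fh:
        json.dump(doc, fh, indent=2)


if __name__ == "__main__":
    main()
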