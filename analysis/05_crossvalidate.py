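"""Repeated stratified 10-fold cross-validation of the selected model.

Standardisation and coefficients are re-learned inside every training fold;
each repetition's AUC pools the out-of-fold predictions. Writes cv_auc.csv,
per-dataset ROC point CSVs and cv_report.json under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ibrad.pipeline import RunConfig, run_crossval  # noqa: E402

BASE = os.path.join(os.path.dirname(__file__), "..")
REPETITIONS = 300  # full protocol; ~1 min at this problem size


def main() -> None:
    results = os.path.join(BASE, "results")
    cfg = RunConfig(out_dir=results, seed=1, cv_k=10, cv_repetitions=REPETITIONS)
    report_path = run_crossval(
        cfg, os.path.join(BASE, "scratch", "features", "features.csv"), os.path.join(results, "model.json")
    )
    report = json.load(open(report_path))
    lo, hi = report["cv_auc_ci"]
    print(f"10-fold x {report['repetitions']} CV: mean AUC {report['mean_cv_auc']:.3f} "
          f"[{lo:.3f}, {hi:.3f}] (2.5-97.5 pct over repetitions)")
    print("Note: feature selection preceded this CV (the protocol cross-validates")
    print("a chosen model, not the search); compare the fresh-cohort check in 06.")


if __name__ == "__main__":
    main()
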