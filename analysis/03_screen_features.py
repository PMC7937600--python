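"""Two-cohort univariate screening of the extracted feature table.

Standardises per cohort, gates each feature through Shapiro-Wilk into a
t or Wilcoxon-Mann-Whitney test of responders vs non-responders, adjusts
with Benjamini-Hochberg within each cohort, and prints the screening top
of each cohort (the candidates that seed the model in 04).
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ibrad.cohort_stats import screen_cohort, zscore  # noqa: E402
from ibrad.pipeline import load_feature_table  # noqa: E402

BASE = os.path.join(os.path.dirname(__file__), "..")


def main() -> None:
    table = load_feature_table(os.path.join(BASE, "scratch", "features", "features.csv"))
    std = zscore(table, scope="per_cohort")
    rows = []
    for cohort in std.cohorts:
        results = screen_cohort(std, cohort, alpha=0.05)
        rows += [r.__dict__ for r in results]
        top = sorted(results, key=lambda r: r.p_adj)[:5]
        n_sig = sum(r.significant for r in results)
        print(f"\n{cohort}: {len(results)} features tested, {n_sig} significant (BH < 0.05)")
        for r in top:
            print(f"  {r.feature:45s} {r.test_used:3s} p={r.p_raw:.2e} p_adj={r.p_adj:.3f}")
    out = os.path.join(BASE, "results", "univariate.csv")
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
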