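"""Build the seeded logistic model: cohort seeds + third feature + AIC stop.

Combines the most significant feature of each cohort, adds the candidate
that maximises training AUC, and keeps extending greedily while the AIC
drops. Writes model.json and univariate.csv under results/.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from ibrad.pipeline import RunConfig, run_select_and_fit  # noqa: E402

BASE = os.path.join(os.path.dirname(__file__), "..")


def main() -> None:
    cfg = RunConfig(out_dir=os.path.join(BASE, "results"), seed=1)
    model_path, _ = run_select_and_fit(cfg, os.path.join(BASE, "scratch", "features", "features.csv"))
    model = json.load(open(model_path))
    print(f"model: {model_path}")
    print(f"features ({len(model['features'])}):")
    for f, b in zip(model["features"], model["coefficients"]):
        print(f"  {f:45s} beta = {b:+.3f}")
    print(f"intercept = {model['intercept']:+.3f}")
    print(f"AIC = {model['aic']:.2f}, training AUC = {model['train_auc']:.3f}")


if __name__ == "__main__":
    main()
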