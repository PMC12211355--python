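"""Build the longitudinal inverse-probability weights for the cohort.

Runs the full weighting pipeline with stepwise propensity selection:
missingness screening, imputation, per-subsample registration- and
participation-stage models, weight chaining, convex combination by effective
case numbers, dispersion/effectiveness diagnostics, and covariate balance.
"""

import json
from pathlib import Path

import pandas as pd

from panelreact import pipeline as pl

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    cohort_path = OUT / "cohort_baseline.csv"
    if not cohort_path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    records = pd.read_csv(cohort_path)
    run = pl.run_weighting(records, selection="stepwise")

    print("weight diagnostics (participation stage, combined):")
    print(f"{'':>22}{'min':>9}{'median':>9}{'max':>9}{'CV %':>9}{'eff %':>9}")
    for label, diag in run.diagnostics.items():
        d = diag.as_dict()
        print(f"{label:>22}{d['min']:>9.3f}{d['median']:>9.3f}{d['max']:>9.3f}"
              f"{d['cv_pct']:>9.2f}{d['effectiveness_pct']:>9.2f}")
    print(f"\nsubsample mixing proportions: {run.lambdas}")
    print("\nselected propensity terms:")
    for key, spec in run.specs.items():
        print(f"  {key}: {spec.main_effects} + {spec.interactions}")
    print("\nbalance (max |weighted - reference| per parameter, pp):")
    for param, disc in run.balance.max_discrepancy.items():
        print(f"  {param}: {disc:.2f}")

    run.weights_participation.reset_index(names="row").to_csv(OUT / "weights_participation.csv", index=False)
    run.balance.table.round(2).to_csv(OUT / "balance.csv", index=False)
    with open(OUT / "weighting_summary.json", "w") as fh:
        json.dump(
            {
                "diagnostics": {k: v.as_dict() for k, v in run.diagnostics.items()},
                "lambdas": run.lambdas,
                "max_discrepancy": run.balance.max_discrepancy,
            },
            fh,
            indent=2,
        )
    print(f"\nwrote weights, balance table and summary under {OUT}")


if __name__ == "__main__":
    main()
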