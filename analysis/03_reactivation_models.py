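"""Fit the age-stratified re-activation models on the simulated cohort.

Fits registration and participation logistic models for both age strata and
prints odds-ratio tables; the fitted sex, SES and mental-health effects can
be read against the generating values the cohort was simulated with.
"""

import json
from pathlib import Path

import pandas as pd

from panelreact import models as md

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    cohort_path = OUT / "cohort_baseline.csv"
    if not cohort_path.exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    records = pd.read_csv(cohort_path)

    results = {}
    for age_group in ("under_11", "from_11"):
        for outcome in ("registration", "participation"):
            spec = md.ModelSpec(outcome, age_group)
            frame, dropped = md.build_model_frame(records, spec)
            table = md.fit_logistic(frame, spec)
            print(f"\n=== {outcome} | age group {age_group} "
                  f"(n = {table.n_obs:,}, dropped {dropped:,} incomplete) ===")
            print(table)
            for w in table.warnings:
                print(f"  warning: {w}")
            results[f"{outcome}/{age_group}"] = {
                "n_obs": table.n_obs,
                "terms": table.table.round(4).reset_index(names="term").to_dict("records"),
            }
    with open(OUT / "reactivation_models.json", "w") as fh:
        json.dump(results, fh, indent=2)
    print(f"\nwrote {OUT / 'reactivation_models.json'}")


if __name__ == "__main__":
    main()
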