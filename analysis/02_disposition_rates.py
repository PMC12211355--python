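"""Tabulate final disposition codes and compute the outcome rates.

Two parts: (1) the reference study's printed registration-process counts,
whose rate arithmetic is reproduced exactly; (2) the simulated cohort from
step 01, tabulated with the same machinery.
"""

import json
from pathlib import Path

import pandas as pd

from panelreact import dispositions as dp

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"

REFERENCE_COUNTS = {
    "registered": 4451,
    "refusal": 60,
    "restricted_access": 32,
    "nothing_returned": 6479,
    "unclear_address": 696,
    "deceased": 4,
    "moved_abroad": 15,
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = dp.DispositionTable(REFERENCE_COUNTS)
    simple = dp.recruitment_rate(table, "simple")
    aapor = dp.recruitment_rate(table, "aapor_e1")
    print("reference registration process:")
    print(f"  invited {table.total:,}, registered {table.counts['registered']:,}")
    print(f"  recruitment rate (simple):   {simple.rate}%  ({simple.numerator:,}/{simple.denominator:,})")
    print(f"  recruitment rate (AAPOR-E1): {aapor.rate}%  ({aapor.numerator:,}/{aapor.denominator:,})")
    print(f"  consent rate: {dp.consent_rate(11815, 12975).rate}%   completion rate: {dp.completion_rate(3063, 4451).rate}%")
    print(f"  eligible invitees: {dp.eligible_invitees(11815, {'restricted_access': 17, 'deceased': 8, 'moved_abroad': 37, 'other_sample': 16}):,}")

    cohort_path = OUT / "cohort_baseline.csv"
    if cohort_path.exists():
        records = pd.read_csv(cohort_path)
        sim_table = dp.tabulate_dispositions(records)
        sim_rate = dp.recruitment_rate(sim_table, "simple")
        print("\nsimulated cohort:")
        print(sim_table.to_frame().to_string(index=False))
        print(f"  recruitment rate (simple): {sim_rate.rate}%")
        payload = {
            "reference": {"counts": table.counts, "recruitment_simple_pct": simple.rate},
            "simulated": {"counts": sim_table.counts, "recruitment_simple_pct": sim_rate.rate},
        }
        with open(OUT / "disposition_rates.json", "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        print("\n(run analysis/01_simulate_cohort.py first for the simulated table)")


if __name__ == "__main__":
    main()
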