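"""Generate the synthetic baseline cohort used by the downstream analyses.

Draws a two-subsample cohort (longitudinal cohort + cross-section) at the
default study conditions, attaches raked cross-sectional weights, simulates
selective registration and participation, injects item-missingness, assigns
final disposition codes, and writes the cohort CSV with a config sidecar.
"""

from pathlib import Path

from panelreact.synthetic import CohortConfig, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = CohortConfig()
    frame = simulate_cohort(cfg)
    write_cohort(frame, OUT / "cohort_baseline.csv", cfg)

    print(f"generated {len(frame):,} invitees (cohort {cfg.n_cohort:,}, cross-section {cfg.n_cross:,})")
    print(f"registration rate: {frame['registered'].mean() * 100:.1f}%")
    reg = frame.loc[frame["registered"] == 1]
    print(f"participation rate among registrants: {reg['participated'].mean() * 100:.1f}%")
    print("\ncomposition:")
    for var in ("sex", "parents_birth", "edu_casmin"):
        shares = frame[var].value_counts(normalize=True).mul(100).round(1)
        print(f"  {var}: {shares.to_dict()}")
    print("\ndisposition counts:")
    print(frame["disposition"].value_counts().to_string())
    print(f"\nwrote {OUT / 'cohort_baseline.csv'}")


if __name__ == "__main__":
    main()
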