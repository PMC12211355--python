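import numpy as np
import pandas as pd
import pytest

from panelreact import synthetic as syn


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A fully simulated 1,000-person cohort, fixed seed."""
    cfg = syn.CohortConfig(n_cohort=300, n_cross=700, seed=11)
    return syn.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    """10,000 records for distribution-level checks."""
    cfg = syn.CohortConfig(n_cohort=4000, n_cross=6000, seed=23)
    return syn.simulate_cohort(cfg)


def make_selection_frame(seed: int, true_log_or: float, n: int = 5000) -> pd.DataFrame:
    """One binary candidate with a known effect plus five noise candidates."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"x_true": rng.integers(0, 2, n).astype(float)})
    for i in range(5):
        df[f"noise{i}"] = rng.normal(size=n)
    df["age_w2"] = rng.integers(11, 18, n).astype(float)
    df["sex"] = rng.choice(["male", "female"], n)
    eta = true_log_or * df["x_true"].to_numpy() - 0.5
    df["y"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return df
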