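"""Age-stratified logistic selection models for panel re-activation.

Two outcomes are modelled on the invited baseline sample: registration on
the panel platform, and participation in the follow-up survey. Because some
baseline instruments exist only from age 11, separate models are fitted for
invitees under 11 and for those 11 and older; the older model additionally
carries the psychosocial scales, cohort membership and a cohort-by-age
interaction. Results are reported as odds ratios with Wald 95% confidence
intervals. These are unweighted selection analyses, separate from the
weighting pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateOutcomeError, SchemaError, ValidationError

__all__ = ["ModelSpec", "ORTable", "build_model_frame", "fit_logistic", "compare_or_tables"]

Z95 = stats.norm.ppf(0.975)

_BASE_VARS = [
    "general_health",
    "mh_problem_score",
    "age_w2",
    "sex",
    "ses_occupation",
    "ses_education",
    "ses_income",
    "parents_birth",
]
_FROM11_EXTRA = ["social_support", "self_efficacy", "subsample"]

_DEFAULT_REFERENCES = {
    "general_health": "excellent_very_good",
    "sex": "male",
    "parents_birth": "both_germany",
    "subsample": "cross_section",
}


@dataclass
class ModelSpec:
    """What to model: outcome, age stratum, and predictor coding."""

    outcome: str  # "registration" | "participation"
    age_group: str  # "under_11" | "from_11"
    references: dict = field(default_factory=lambda: dict(_DEFAULT_REFERENCES))
    #: participation coded on the full invitee frame (1 iff registered and
    #: participated) by default; True restricts the frame to registrants
    conditional_participation: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in ("registration", "participation"):
            raise ValidationError(f"unknown outcome {self.outcome!r}")
        if self.age_group not in ("under_11", "from_11"):
            raise ValidationError(f"unknown age group {self.age_group!r}")

    @property
    def variables(self) -> list[str]:
        if self.age_group == "under_11":
            return list(_BASE_VARS)
        return _BASE_VARS + _FROM11_EXTRA

    @property
    def categorical(self) -> list[str]:
        return [v for v in self.variables if v in self.references]


@dataclass
class ORTable:
    """Odds ratios with Wald CIs, in published table order."""

    table: pd.DataFrame  # index: term; columns: or_, ci_low, ci_high, p
    n_obs: int
    warnings: list = field(default_factory=list)
    fitted: pd.Series | None = None  # per-row fitted probabilities

    def __str__(self) -> str:  # aligned text rendering
        lines = [f"{'term':<42}{'OR':>8}{'95% CI':>18}{'p':>9}"]
        for term, row in self.table.iterrows():
            ci = f"{row.ci_low:.2f}-{row.ci_high:.2f}"
            p = "<.001" if row.p < 0.001 else f"{row.p:.3f}"
            lines.append(f"{term:<42}{row.or_:>8.2f}{ci:>18}{p:>9}")
        lines.append(f"Observations: {self.n_obs:,}")
        return "\n".join(lines)


def build_model_frame(records: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    """Complete-case analysis frame for one age stratum, plus rows dropped.

    The participation outcome is coded 1 iff the person both registered and
    participated, on the same frame as the registration model (so both models
    share an observation count), unless the spec asks for the
    conditional-on-registration coding.
    """
    needed = spec.variables + ["registered", "participated"]
    for var in needed:
        if var not in records.columns:
            raise SchemaError(f"required variable {var!r} absent from input")

    mask = records["age_w2"] < 11 if spec.age_group == "under_11" else records["age_w2"] >= 11
    sub = records.loc[mask].copy()
    if spec.outcome == "participation" and spec.conditional_participation:
        sub = sub.loc[sub["registered"].fillna(0).astype(int) == 1]

    before = len(sub)
    complete = sub.dropna(subset=spec.variables + ["registered"])
    dropped = before - len(complete)

    frame = complete.copy()
    reg = frame["registered"].astype(int)
    if spec.outcome == "registration":
        frame["_y"] = reg
    else:
        part = frame["participated"].fillna(0).astype(int)
        frame["_y"] = ((reg == 1) & (part == 1)).astype(int)
    return frame, dropped


def _design(frame: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Design matrix with treatment coding against the spec's references."""
    cols: dict[str, np.ndarray] = {}
    for var in spec.variables:
        if var == "subsample":
            continue  # handled with its interaction below
        if var in spec.references:
            ref = spec.references[var]
            levels = [l for l in pd.unique(frame[var]) if l != ref]
            for level in sorted(map(str, levels)):
                cols[f"{var}[{level}]"] = (frame[var].astype(str) == level).to_numpy(float)
        else:
            cols[var] = frame[var].to_numpy(float)
    if spec.age_group == "from_11":
        ref = spec.references.get("subsample", "cross_section")
        cohort = (frame["subsample"].astype(str) != ref).to_numpy(float)
        cols["cohort"] = cohort
        cols["cohort:age_w2"] = cohort * frame["age_w2"].to_numpy(float)
    X = pd.DataFrame(cols, index=frame.index)
    X.insert(0, "const", 1.0)
    return X


def fit_logistic(frame: pd.DataFrame, spec: ModelSpec) -> ORTable:
    """Maximum-likelihood logistic fit; OR = exp(beta), Wald 95% CI and p."""
    if len(frame) == 0:
        raise DegenerateOutcomeError("empty analysis frame")
    y = frame["_y"].to_numpy(int)
    if y.min() == y.max():
        raise DegenerateOutcomeError(f"outcome is single-class (all {y[0]})")
    X = _design(frame, spec)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)

    beta = res.params.drop("const")
    se = res.bse.drop("const")
    table = pd.DataFrame(
        {
            "or_": np.exp(beta),
            "ci_low": np.exp(beta - Z95 * se),
            "ci_high": np.exp(beta + Z95 * se),
            "p": 2 * stats.norm.sf(np.abs(beta / se)),
        }
    )
    warns = [
        f"possible separation for term {t!r} (|log-odds| {abs(b):.1f}, SE {s:.1f})"
        for t, b, s in zip(beta.index, beta, se)
        if abs(b) > 10 or s > 100
    ]
    fitted = pd.Series(np.asarray(res.predict(X)), index=frame.index)
    return ORTable(table=table, n_obs=len(frame), warnings=warns, fitted=fitted)


def compare_or_tables(fitted: ORTable, reference: ORTable) -> pd.DataFrame:
    """Per-term check of a fitted table against a reference table.

    ``inside_ci`` uses the reference's closed CI; ``sign_agreement`` compares
    each OR's direction relative to 1.
    """
    ft, rt = fitted.table, reference.table
    if set(ft.index) != set(rt.index):
        raise SchemaError(
            f"term mismatch: {sorted(set(ft.index) ^ set(rt.index))}"
        )
    rt = rt.loc[ft.index]
    inside = (ft["or_"] >= rt["ci_low"]) & (ft["or_"] <= rt["ci_high"])
    same_sign = np.sign(np.log(ft["or_"])) == np.sign(np.log(rt["or_"]))
    return pd.DataFrame({"inside_ci": inside, "sign_agreement": same_sign})
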