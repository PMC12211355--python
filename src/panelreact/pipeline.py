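"""End-to-end weighting pipeline over a baseline cohort.

Chains the two re-activation stages per subsample — registration weighted
from the cross-sectional base weight, participation weighted from the
registration-stage longitudinal weight — then merges the subsamples by
effective case numbers and reports dispersion/effectiveness diagnostics and
covariate balance against the baseline composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import weighting as wt
from .errors import ValidationError

__all__ = ["WeightingRun", "prepare_weighting_frame", "run_weighting"]

DEFAULT_CANDIDATES = [
    "age_w2",
    "sex",
    "ses_occupation",
    "ses_education",
    "ses_income",
    "edu_casmin",
    "parents_birth",
    "general_health",
    "mh_problem_score",
]
DEFAULT_CATEGORICAL = {
    "sex": "male",
    "edu_casmin": "basic",
    "parents_birth": "both_germany",
    "general_health": "excellent_very_good",
}
BALANCE_PARAMETERS = ["sex", "age_group", "edu_casmin", "parents_birth", "general_health"]


@dataclass
class WeightingRun:
    """Everything one pipeline pass produced."""

    weights_registration: pd.DataFrame
    weights_participation: pd.DataFrame
    lambdas: dict
    diagnostics: dict  # label -> WeightDiagnostics
    balance: wt.BalanceReport | None
    specs: dict = field(default_factory=dict)
    logs: dict = field(default_factory=dict)


def prepare_weighting_frame(
    records: pd.DataFrame,
    candidates: list[str] | None = None,
    categorical: dict | None = None,
    threshold: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Screen candidates for item-missingness and impute the admitted ones."""
    candidates = candidates or list(DEFAULT_CANDIDATES)
    categorical = categorical if categorical is not None else dict(DEFAULT_CATEGORICAL)
    structural = {
        v: records["age_w2"] < 11
        for v in ("social_support", "self_efficacy")
        if v in candidates and "age_w2" in records.columns
    }
    admitted, rejected = wt.screen_missingness(records, candidates, threshold, structural)
    completed, impute_log = wt.impute_simple(
        records, admitted, categorical=list(categorical), structural=structural
    )
    log = {"admitted": admitted, "rejected": rejected, "imputed": impute_log}
    return completed, log


def _stage_weights(frame, outcome, base, candidates, categorical, selection, floor, stepwise_kwargs):
    if selection == "stepwise":
        spec = wt.stepwise_select(
            frame, outcome, base, candidates, categorical=categorical, **stepwise_kwargs
        )
    elif selection == "full":
        spec = wt.PropensitySpec(
            outcome=outcome,
            main_effects=list(candidates),
            categorical={v: r for v, r in categorical.items() if v in candidates},
        )
    else:
        raise ValidationError(f"unknown selection mode {selection!r}")
    theta, floor_log = wt.estimate_propensity(frame, spec, base, floor=floor)
    respondents = frame[outcome].astype(float) == 1
    weights = wt.compute_weights(theta, pd.Series(base, index=frame.index), outcome, respondents)
    return weights, spec, floor_log


def run_weighting(
    records: pd.DataFrame,
    candidates: list[str] | None = None,
    categorical: dict | None = None,
    selection: str = "full",
    floor: float = 0.01,
    balance_parameters: list[str] | None = None,
    **stepwise_kwargs,
) -> WeightingRun:
    """Two-stage, two-subsample longitudinal weighting of one cohort.

    ``selection`` chooses the propensity model per stage and subsample:
    ``"full"`` keeps every admitted candidate as a main effect, ``"stepwise"``
    runs the semi-automatic selection loop.
    """
    candidates = candidates or list(DEFAULT_CANDIDATES)
    categorical = categorical if categorical is not None else dict(DEFAULT_CATEGORICAL)
    completed, prep_log = prepare_weighting_frame(records, candidates, categorical)
    admitted = [c for c in prep_log["admitted"]]

    reg_parts, part_parts, specs, logs = {}, {}, {}, {"prepare": prep_log}
    for sub in ("cohort", "cross_section"):
        sub_frame = completed.loc[completed["subsample"] == sub].copy()
        if len(sub_frame) == 0:
            continue
        sub_frame["registered"] = sub_frame["registered"].fillna(0).astype(int)
        sub_frame["participated"] = sub_frame["participated"].fillna(0).astype(int)
        base = sub_frame["w_qs"].to_numpy(float)

        w_reg, spec_reg, log_reg = _stage_weights(
            sub_frame, "registered", base, admitted, categorical, selection, floor, stepwise_kwargs
        )
        reg_parts[sub] = w_reg
        specs[f"registration/{sub}"] = spec_reg
        logs[f"registration/{sub}"] = log_reg

        # participation stage: among registrants, base = registration wLS
        reg_frame = sub_frame.loc[w_reg.index]
        w_part, spec_part, log_part = _stage_weights(
            reg_frame,
            "participated",
            w_reg["wls"].to_numpy(float),
            admitted,
            categorical,
            selection,
            floor,
            stepwise_kwargs,
        )
        part_parts[sub] = w_part
        specs[f"participation/{sub}"] = spec_part
        logs[f"participation/{sub}"] = log_part

    if not part_parts:
        raise ValidationError("no subsample produced any weights")

    if len(reg_parts) == 2:
        reg_combined, lam_reg = wt.combine_subsamples(reg_parts["cohort"], reg_parts["cross_section"])
        part_combined, lam_part = wt.combine_subsamples(part_parts["cohort"], part_parts["cross_section"])
        lambdas = {"registration": lam_reg, "participation": lam_part}
    else:
        (reg_combined,) = reg_parts.values()
        (part_combined,) = part_parts.values()
        reg_combined = reg_combined.assign(wls_combined=reg_combined["wls"] / reg_combined["wls"].mean())
        part_combined = part_combined.assign(wls_combined=part_combined["wls"] / part_combined["wls"].mean())
        lambdas = {"registration": {"single": 1.0}, "participation": {"single": 1.0}}

    participants = completed.loc[part_combined.index]
    diagnostics = {
        "unweighted": wt.weight_diagnostics([1.0] * len(part_combined)),
        "base_weight": wt.weight_diagnostics(participants["w_qs"]),
        "longitudinal_weight": wt.weight_diagnostics(part_combined["wls_combined"]),
    }
    params = balance_parameters or [p for p in BALANCE_PARAMETERS if p in records.columns]
    balance = wt.balance_report(
        completed,
        participants,
        part_combined["wls_combined"].to_numpy(float),
        params,
        baseline_weights=completed["w_qs"].to_numpy(float),
    )
    return WeightingRun(
        weights_registration=reg_combined,
        weights_participation=part_combined,
        lambdas=lambdas,
        diagnostics=diagnostics,
        balance=balance,
        specs=specs,
        logs=logs,
    )
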