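"""Synthetic baseline cohort with selective two-stage re-participation.

Emulates the structure of a child/adolescent health survey whose former
participants are later invited into an online panel: two subsamples (a
longitudinal cohort and a cross-sectional sample), baseline covariates with
realistic marginal distributions, a calibration weight, and a two-stage
re-activation outcome (panel registration, then survey participation) driven
by configurable log-odds so that downstream selection models and
inverse-probability weights can be validated against known truth.

Covariate marginals default to the published composition of the baseline
sample (e.g. 49.5% male, 82.7% with both parents born in Germany); the
generating effects for registration and participation default to the published
odds ratios of the age-11+ re-activation models (e.g. female OR 2.61 for
registration) with intercepts calibrated to the observed marginal rates
(37.9% registration; 68.8% participation among registrants).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from ._raking import rake
from .errors import ConfigurationError

__all__ = [
    "CohortConfig",
    "default_population_margins",
    "generate_baseline",
    "assign_cross_sectional_weights",
    "simulate_reactivation",
    "inject_missingness",
    "assign_dispositions",
    "simulate_cohort",
    "write_cohort",
]

AGE_BANDS = ("6-9", "10-13", "14-17", "18+")
_AGE_RANGES = {"6-9": (6, 9), "10-13": (10, 13), "14-17": (14, 17), "18+": (18, 19)}

SEX_LEVELS = ("male", "female")
PARENTS_LEVELS = ("both_germany", "one_abroad", "both_abroad")
HEALTH_LEVELS = ("excellent_very_good", "good", "moderate_to_very_poor")
EDU_LEVELS = ("basic", "intermediate", "higher")

#: disposition codes usable for invitees who did not register
NONRESPONSE_CODES = (
    "refusal",
    "restricted_access",
    "nothing_returned",
    "unclear_address",
    "deceased",
    "moved_abroad",
    "other_sample",
)


def _log(x: float) -> float:
    return math.log(x)


@dataclass
class CohortConfig:
    """Parameters governing one synthetic baseline cohort.

    The defaults are the study conditions: marginal covariate shares follow
    the baseline sample's published unweighted composition, generating
    effects follow the published re-activation odds ratios, and the marginal
    registration / participation targets are the published rates.
    """

    n_cohort: int = 4400
    n_cross: int = 7400
    seed: int = 20240229

    # marginal covariate distributions
    age_band_probs: dict = field(
        default_factory=lambda: {"6-9": 0.150, "10-13": 0.427, "14-17": 0.410, "18+": 0.013}
    )
    sex_probs: dict = field(default_factory=lambda: {"male": 0.495, "female": 0.505})
    parents_birth_probs: dict = field(
        default_factory=lambda: {"both_germany": 0.827, "one_abroad": 0.082, "both_abroad": 0.091}
    )
    general_health_probs: dict = field(
        default_factory=lambda: {
            "excellent_very_good": 0.570,
            "good": 0.389,
            "moderate_to_very_poor": 0.041,
        }
    )
    edu_casmin_probs: dict = field(
        default_factory=lambda: {"basic": 0.102, "intermediate": 0.542, "higher": 0.356}
    )
    # score distributions (mean, sd); SES subscores live on 1-7, SDQ on 0-40,
    # social support on 3-15, self-efficacy on 10-40
    mh_mean: float = 8.0
    mh_sd: float = 5.0
    ses_mean: float = 3.5
    ses_sd: float = 1.4
    ses_edu_by_casmin: dict = field(
        default_factory=lambda: {"basic": 2.3, "intermediate": 3.5, "higher": 5.2}
    )
    social_support_mean: float = 12.0
    social_support_sd: float = 2.5
    self_efficacy_mean: float = 29.0
    self_efficacy_sd: float = 5.0

    # generating log-odds for the two re-activation stages
    registration_target: float = 0.379
    participation_target: float = 0.688
    registration_effects: dict = field(
        default_factory=lambda: {
            "female": _log(2.61),
            "mh_problem_score": _log(0.98),
            "social_support": _log(0.99),
            "self_efficacy": 0.0,
            "age_w2": _log(0.97),
            "ses_occupation": _log(1.08),
            "ses_education": _log(1.13),
            "ses_income": _log(0.99),
            "health_good": _log(0.97),
            "health_moderate_to_very_poor": _log(0.86),
            "parents_one_abroad": _log(0.69),
            "parents_both_abroad": _log(0.73),
            "cohort": _log(0.68),
            "cohort_x_age": _log(1.05),
        }
    )
    participation_effects: dict = field(
        default_factory=lambda: {
            "female": _log(2.85),
            "mh_problem_score": _log(0.98),
            "social_support": _log(0.99),
            "self_efficacy": 0.0,
            "age_w2": _log(0.97),
            "ses_occupation": _log(1.06),
            "ses_education": _log(1.13),
            "ses_income": _log(1.02),
            "health_good": _log(0.93),
            "health_moderate_to_very_poor": _log(0.83),
            "parents_one_abroad": _log(0.69),
            "parents_both_abroad": _log(0.75),
            "cohort": _log(0.84),
            "cohort_x_age": _log(1.03),
        }
    )

    # item-missingness (MCAR) rates per variable; all below the 5% screen
    item_missing_rates: dict = field(
        default_factory=lambda: {
            "ses_occupation": 0.02,
            "ses_education": 0.02,
            "ses_income": 0.03,
            "mh_problem_score": 0.02,
            "general_health": 0.01,
            "parents_birth": 0.01,
            "social_support": 0.03,
            "self_efficacy": 0.03,
        }
    )
    #: optional MAR mechanism: variable whose value shifts missingness odds
    mar_driver: str | None = None
    mar_log_odds: float = 0.0

    # mixture over non-response codes, defaults proportional to the published
    # registration-stage disposition counts (60/32/6479/696/4/15 of 7,286)
    disposition_probs: dict = field(
        default_factory=lambda: {
            "refusal": 60 / 7286,
            "restricted_access": 32 / 7286,
            "nothing_returned": 6479 / 7286,
            "unclear_address": 696 / 7286,
            "deceased": 4 / 7286,
            "moved_abroad": 15 / 7286,
            "other_sample": 0.0,
        }
    )

    def __post_init__(self) -> None:
        if self.n_cohort < 0 or self.n_cross < 0:
            raise ConfigurationError("n_cohort and n_cross must be non-negative")
        for name in (
            "age_band_probs",
            "sex_probs",
            "parents_birth_probs",
            "general_health_probs",
            "edu_casmin_probs",
            "disposition_probs",
        ):
            probs = getattr(self, name)
            total = float(sum(probs.values()))
            if any(p < 0 for p in probs.values()):
                raise ConfigurationError(f"{name} contains a negative probability")
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} sums to {total!r}, expected 1")
        for var, rate in self.item_missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness rate for {var!r} is {rate}, outside [0, 1]")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def default_population_margins() -> dict:
    """Population margins the cross-sectional weight calibrates to.

    Deliberately offset from the sample composition so the base weight has
    realistic (modest) dispersion.
    """
    return {
        "sex": {"male": 0.487, "female": 0.513},
        "age_group": {"6-9": 0.170, "10-13": 0.405, "14-17": 0.400, "18+": 0.025},
        "edu_casmin": {"basic": 0.140, "intermediate": 0.555, "higher": 0.305},
    }


def _rng(config: CohortConfig, stream: int) -> np.random.Generator:
    # one seed governs everything; sub-streams are derived per operation
    return np.random.default_rng([config.seed, stream])


def _draw_cat(rng, levels, probs, n):
    p = np.array([probs.get(l, 0.0) for l in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def generate_baseline(config: CohortConfig) -> pd.DataFrame:
    """Draw ``n_cohort + n_cross`` baseline records with covariates only.

    Covariates are drawn independently per variable (the published reference
    gives marginals only), except that the family-education CASMIN level and
    the numeric SES-education subscore are linked, and cohort members exclude
    the youngest age band (the cohort contained no members that young at
    baseline). Outcome columns are present but unset.
    """
    rng = _rng(config, 0)
    n = config.n_cohort + config.n_cross
    subsample = np.array(["cohort"] * config.n_cohort + ["cross_section"] * config.n_cross)

    # ages: cohort members never fall in the youngest band
    bands_cross = list(config.age_band_probs)
    cohort_probs = {b: p for b, p in config.age_band_probs.items() if b != "6-9"}
    band = np.empty(n, dtype=object)
    if config.n_cohort:
        band[: config.n_cohort] = _draw_cat(rng, list(cohort_probs), cohort_probs, config.n_cohort)
    if config.n_cross:
        band[config.n_cohort :] = _draw_cat(rng, bands_cross, config.age_band_probs, config.n_cross)
    age = np.empty(n, dtype=int)
    for b, (lo, hi) in _AGE_RANGES.items():
        mask = band == b
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    sex = _draw_cat(rng, SEX_LEVELS, config.sex_probs, n)
    parents = _draw_cat(rng, PARENTS_LEVELS, config.parents_birth_probs, n)
    health = _draw_cat(rng, HEALTH_LEVELS, config.general_health_probs, n)
    edu = _draw_cat(rng, EDU_LEVELS, config.edu_casmin_probs, n)

    mh = np.clip(np.rint(rng.normal(config.mh_mean, config.mh_sd, n)), 0, 40)
    ses_occ = np.clip(rng.normal(config.ses_mean, config.ses_sd, n), 1, 7).round(1)
    ses_inc = np.clip(rng.normal(config.ses_mean, config.ses_sd, n), 1, 7).round(1)
    edu_means = np.array([config.ses_edu_by_casmin[e] for e in edu])
    ses_edu = np.clip(rng.normal(edu_means, 0.8), 1, 7).round(1)

    # psychosocial scales exist only from age 11 (filtered missing below)
    ss = np.clip(rng.normal(config.social_support_mean, config.social_support_sd, n), 3, 15).round(1)
    se = np.clip(rng.normal(config.self_efficacy_mean, config.self_efficacy_sd, n), 10, 40).round(1)
    under11 = age < 11
    ss[under11] = np.nan
    se[under11] = np.nan

    frame = pd.DataFrame(
        {
            "person_id": [f"P{i:06d}" for i in range(n)],
            "subsample": subsample,
            "age_w2": age,
            "age_group": band,
            "sex": sex,
            "ses_occupation": ses_occ,
            "ses_education": ses_edu,
            "ses_income": ses_inc,
            "edu_casmin": edu,
            "parents_birth": parents,
            "general_health": health,
            "mh_problem_score": mh,
            "social_support": ss,
            "self_efficacy": se,
        }
    )
    frame["w_qs"] = np.nan
    frame["registered"] = pd.array([pd.NA] * n, dtype="Int64")
    frame["participated"] = pd.array([pd.NA] * n, dtype="Int64")
    frame["disposition"] = pd.array([pd.NA] * n, dtype="string")
    return frame


def assign_cross_sectional_weights(
    records: pd.DataFrame, population_margins: Mapping[str, Mapping[str, float]] | None = None
) -> pd.DataFrame:
    """Attach the cross-sectional calibration weight ``w_qs`` by raking.

    The weight adjusts the baseline sample to the population margins on age
    group, sex and parental education; mean weight is normalized to 1.
    """
    margins = population_margins if population_margins is not None else default_population_margins()
    out = records.copy()
    out["w_qs"] = rake(records, margins)
    return out


def _linear_predictor(frame: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    """Generating log-odds contribution per person (no intercept).

    Psychosocial scales contribute only where defined (age 11+); missing
    structural values contribute zero.
    """
    eta = np.zeros(len(frame))
    eta += effects.get("female", 0.0) * (frame["sex"] == "female").to_numpy()
    eta += effects.get("mh_problem_score", 0.0) * frame["mh_problem_score"].to_numpy(dtype=float)
    eta += effects.get("age_w2", 0.0) * frame["age_w2"].to_numpy(dtype=float)
    eta += effects.get("ses_occupation", 0.0) * frame["ses_occupation"].to_numpy(dtype=float)
    eta += effects.get("ses_education", 0.0) * frame["ses_education"].to_numpy(dtype=float)
    eta += effects.get("ses_income", 0.0) * frame["ses_income"].to_numpy(dtype=float)
    eta += effects.get("health_good", 0.0) * (frame["general_health"] == "good").to_numpy()
    eta += effects.get("health_moderate_to_very_poor", 0.0) * (
        frame["general_health"] == "moderate_to_very_poor"
    ).to_numpy()
    eta += effects.get("parents_one_abroad", 0.0) * (frame["parents_birth"] == "one_abroad").to_numpy()
    eta += effects.get("parents_both_abroad", 0.0) * (frame["parents_birth"] == "both_abroad").to_numpy()
    cohort = (frame["subsample"] == "cohort").to_numpy()
    eta += effects.get("cohort", 0.0) * cohort
    eta += effects.get("cohort_x_age", 0.0) * cohort * frame["age_w2"].to_numpy(dtype=float)
    for col in ("social_support", "self_efficacy"):
        beta = effects.get(col, 0.0)
        vals = frame[col].to_numpy(dtype=float)
        eta += beta * np.where(np.isnan(vals), 0.0, vals)
    return eta


def _calibrate_intercept(eta: np.ndarray, target: float) -> float:
    """Deterministic intercept such that mean(expit(a + eta)) == target."""
    if target == 0.0:
        return -np.inf
    if target == 1.0:
        return np.inf
    if not 0.0 < target < 1.0:
        raise ConfigurationError(f"marginal target {target} must lie in [0, 1]")

    def gap(a: float) -> float:
        return float(expit(a + eta).mean() - target)

    return brentq(gap, -60.0, 60.0, xtol=1e-12)


def simulate_reactivation(records: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Draw registration and (conditional) participation outcomes.

    Registration is Bernoulli on the configured generating log-odds;
    participation is drawn only among registrants, with its own effects.
    Intercepts are calibrated by root-finding so the marginal registration
    rate and the participation rate among registrants hit the configured
    targets in expectation.
    """
    rng = _rng(config, 1)
    out = records.copy()
    eta_reg = _linear_predictor(out, config.registration_effects)
    a_reg = _calibrate_intercept(eta_reg, config.registration_target)
    p_reg = expit(a_reg + eta_reg)
    registered = (rng.random(len(out)) < p_reg).astype(int)

    participated = np.zeros(len(out), dtype=int)
    reg_mask = registered == 1
    if reg_mask.any():
        eta_part = _linear_predictor(out, config.participation_effects)
        a_part = _calibrate_intercept(eta_part[reg_mask], config.participation_target)
        p_part = expit(a_part + eta_part)
        participated[reg_mask] = (rng.random(int(reg_mask.sum())) < p_part[reg_mask]).astype(int)

    out["registered"] = pd.array(registered, dtype="Int64")
    out["participated"] = pd.array(participated, dtype="Int64")
    return out


def inject_missingness(records: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Blank a configured fraction of each eligible variable's values.

    Item-missingness is MCAR by default; if ``mar_driver`` is set, the
    per-row missingness log-odds shift with that (standardized) covariate.
    Structural missings — the psychosocial scales below age 11 — are left
    untouched; only observed values can become item-missing.
    """
    rng = _rng(config, 2)
    out = records.copy()
    n = len(out)
    if config.mar_driver is not None:
        driver = out[config.mar_driver].to_numpy(dtype=float)
        z = (driver - np.nanmean(driver)) / (np.nanstd(driver) or 1.0)
        z = np.where(np.isnan(z), 0.0, z)
    else:
        z = np.zeros(n)

    for var, rate in config.item_missing_rates.items():
        if var not in out.columns or rate == 0:
            continue
        if config.mar_driver is None or config.mar_log_odds == 0.0:
            p = np.full(n, rate)
        else:
            # calibrate so the marginal rate is preserved under MAR
            base = _calibrate_intercept(config.mar_log_odds * z, rate)
            p = expit(base + config.mar_log_odds * z)
        hit = rng.random(n) < p
        col = out[var]
        observed = col.notna().to_numpy()
        out.loc[hit & observed, var] = np.nan
    return out


def assign_dispositions(records: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Give every invitee a final disposition code.

    Registrants are coded ``registered``; non-registrants are allocated among
    the non-response codes by the configured mixture, independently of their
    covariates (only code totals are known for the reference study).
    """
    rng = _rng(config, 3)
    out = records.copy()
    reg = out["registered"].fillna(0).to_numpy(dtype=int)
    codes = np.empty(len(out), dtype=object)
    codes[reg == 1] = "registered"
    n_nr = int((reg == 0).sum())
    if n_nr:
        codes[reg == 0] = _draw_cat(rng, NONRESPONSE_CODES, config.disposition_probs, n_nr)
    out["disposition"] = pd.array(codes, dtype="string")
    # ineligible codes cannot have registered or participated
    ineligible = out["disposition"].isin(["deceased", "moved_abroad", "other_sample"])
    out.loc[ineligible, ["registered", "participated"]] = 0
    return out


def simulate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Run the full generation pipeline with one config and one seed."""
    cfg = config or CohortConfig()
    frame = generate_baseline(cfg)
    frame = assign_cross_sectional_weights(frame)
    frame = simulate_reactivation(frame, cfg)
    frame = inject_missingness(frame, cfg)
    frame = assign_dispositions(frame, cfg)
    return frame


def write_cohort(frame: pd.DataFrame, path, config: CohortConfig | None = None) -> None:
    """Write the cohort CSV (empty fields for missing) plus a config sidecar."""
    frame.to_csv(path, index=False, na_rep="")
    if config is not None:
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"seed": config.seed, "config": config.to_dict()}, fh, indent=2)
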