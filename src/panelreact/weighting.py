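"""Longitudinal inverse-probability weights for selective re-participation.

The pipeline mirrors a semi-automatic survey-weighting procedure: candidate
baseline variables are screened for missingness (at most 5% item-missing),
item-missing values are imputed by median/mode, user-missing categories are
merged into the observed category with the closest re-participation rate, a
re-participation propensity model is selected by bidirectional stepwise
search with an interaction-and-plausibility pruning loop, and each
re-participant receives the longitudinal weight

    wLS_i = base_i / theta_i

where ``theta_i`` is the predicted re-participation propensity and ``base``
is the cross-sectional weight at the registration stage, or the
registration-stage longitudinal weight at the participation stage.
Subsamples weighted separately are merged by a convex combination with
proportions given by Kish effective case numbers. Diagnostics report weight
dispersion (min/median/max, CV) and effectiveness, the ratio of Kish
effective sample size to nominal sample size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import EstimationError, SchemaError, ValidationError

__all__ = [
    "PropensitySpec",
    "WeightDiagnostics",
    "BalanceReport",
    "screen_missingness",
    "impute_simple",
    "merge_user_missing",
    "stepwise_select",
    "estimate_propensity",
    "compute_weights",
    "combine_subsamples",
    "weight_diagnostics",
    "kish_n_eff",
    "balance_report",
]

Z95 = stats.norm.ppf(0.975)


# ---------------------------------------------------------------------------
# screening, imputation, recoding
# ---------------------------------------------------------------------------

def screen_missingness(
    frame: pd.DataFrame,
    variables: Sequence[str] | None = None,
    threshold: float = 0.05,
    structural: Mapping[str, pd.Series] | None = None,
) -> tuple[list[str], dict[str, float]]:
    """Admit variables whose item-missing fraction is at most ``threshold``.

    ``structural`` maps a variable to a boolean mask of rows where the value
    is missing by design (e.g. an instrument not administered below a given
    age); such rows count toward neither numerator nor denominator.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold {threshold} outside [0, 1]")
    variables = list(variables) if variables is not None else list(frame.columns)
    structural = structural or {}
    admitted, rejected = [], {}
    for var in variables:
        col = frame[var]
        if var in structural:
            col = col[~structural[var].astype(bool)]
        n = len(col)
        frac = float(col.isna().sum()) / n if n else 0.0
        if frac <= threshold:
            admitted.append(var)
        else:
            rejected[var] = frac
    return admitted, rejected


def _lower_median(values: np.ndarray) -> float:
    ordered = np.sort(values)
    return float(ordered[(len(ordered) - 1) // 2])


def impute_simple(
    frame: pd.DataFrame,
    admitted: Sequence[str],
    categorical: Sequence[str] = (),
    level_order: Mapping[str, Sequence[str]] | None = None,
    structural: Mapping[str, pd.Series] | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Median/mode single imputation of item-missing values.

    Continuous variables get the lower median of observed values (the lower
    of the two central order statistics at even counts — deterministic and
    order-free); categorical variables get the mode, ties broken by the first
    level in ``level_order``. Structurally missing rows are left untouched.
    """
    out = frame.copy()
    structural = structural or {}
    level_order = level_order or {}
    log: dict[str, int] = {}
    for var in admitted:
        col = out[var]
        eligible = col.isna()
        if var in structural:
            eligible &= ~structural[var].astype(bool)
        n_missing = int(eligible.sum())
        if n_missing == 0:
            continue
        observed = col.dropna()
        if observed.empty:
            raise EstimationError(f"cannot impute {var!r}: no observed values")
        if var in categorical:
            counts = observed.value_counts()
            top = counts[counts == counts.max()].index
            order = list(level_order.get(var, sorted(map(str, top))))
            fill = next(l for l in order if l in set(map(str, top)))
        else:
            fill = _lower_median(observed.to_numpy(dtype=float))
        out.loc[eligible, var] = fill
        log[var] = n_missing
    return out, log


def merge_user_missing(
    frame: pd.DataFrame,
    variable: str,
    outcome: str,
    user_missing_level: str = "user_missing",
) -> tuple[pd.DataFrame, dict]:
    """Fold a user-missing category into the observed level with the nearest
    re-participation rate; ties resolve toward the larger level."""
    out = frame.copy()
    col = out[variable].astype(str)
    um_mask = col == user_missing_level
    log: dict = {"variable": variable, "user_missing_level": user_missing_level}
    if not um_mask.any():
        log["action"] = "no user-missing rows; unchanged"
        return out, log
    y = out[outcome].astype(float)
    um_rate = float(y[um_mask].mean())
    levels = [l for l in col[~um_mask].unique()]
    if not levels:
        raise ValidationError(f"{variable!r} has only user-missing values")
    rates = {l: float(y[col == l].mean()) for l in levels}
    sizes = {l: int((col == l).sum()) for l in levels}
    # nearest rate; ties toward the larger level
    best = min(levels, key=lambda l: (abs(rates[l] - um_rate), -sizes[l]))
    out.loc[um_mask, variable] = best
    log.update(
        action="merged",
        merged_into=best,
        user_missing_rate=um_rate,
        level_rates=rates,
        n_merged=int(um_mask.sum()),
    )
    return out, log


# ---------------------------------------------------------------------------
# propensity model selection and estimation
# ---------------------------------------------------------------------------

@dataclass
class PropensitySpec:
    """A selected re-participation propensity model."""

    outcome: str
    main_effects: list[str]
    interactions: list[tuple[str, str]] = field(default_factory=list)
    categorical: dict = field(default_factory=dict)  # var -> reference level
    coefficients: pd.Series | None = None
    base_weight_label: str = "w_qs"
    converged: bool = True
    audit: list = field(default_factory=list)

    @property
    def terms(self) -> list[str]:
        return list(self.main_effects) + [f"{a}:{b}" for a, b in self.interactions]


def _columns_for(frame: pd.DataFrame, var: str, categorical: Mapping[str, str | None]) -> pd.DataFrame:
    if var in categorical:
        ref = categorical[var]
        values = frame[var].astype(str)
        levels = sorted(values.unique())
        if ref is None:
            ref = levels[0]
        return pd.DataFrame(
            {f"{var}[{l}]": (values == l).to_numpy(float) for l in levels if l != str(ref)},
            index=frame.index,
        )
    return pd.DataFrame({var: frame[var].to_numpy(float)}, index=frame.index)


def _design(frame: pd.DataFrame, terms: Iterable[str], categorical: Mapping[str, str | None]) -> pd.DataFrame:
    parts = [pd.DataFrame({"const": np.ones(len(frame))}, index=frame.index)]
    for term in terms:
        if ":" in term:
            a, b = term.split(":", 1)
            left, right = _columns_for(frame, a, categorical), _columns_for(frame, b, categorical)
            inter = {
                f"{lc}:{rc}": left[lc].to_numpy() * right[rc].to_numpy()
                for lc in left.columns
                for rc in right.columns
            }
            parts.append(pd.DataFrame(inter, index=frame.index))
        else:
            parts.append(_columns_for(frame, term, categorical))
    return pd.concat(parts, axis=1)


def _glm_fit(y: np.ndarray, X: pd.DataFrame, w: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
        return model.fit(maxiter=100)


def _term_columns(term: str, X: pd.DataFrame) -> list[str]:
    if ":" in term:
        return [c for c in X.columns if ":" in c and c != "const"
                and c.split(":", 1)[0].split("[")[0] == term.split(":", 1)[0]
                and c.split(":", 1)[1].split("[")[0] == term.split(":", 1)[1]]
    return [c for c in X.columns if c == term or (c.startswith(f"{term}[") and ":" not in c)]


def _bidirectional(frame, y, w, candidates, categorical, audit, max_moves=200):
    """Forward/backward stepwise minimizing AIC over main-effect terms."""
    selected: list[str] = []
    current = _glm_fit(y, _design(frame, selected, categorical), w).aic
    for _ in range(max_moves):
        best_move, best_aic = None, current - 1e-6
        for var in candidates:
            if var in selected:
                continue
            try:
                aic = _glm_fit(y, _design(frame, selected + [var], categorical), w).aic
            except Exception:
                continue
            if aic < best_aic:
                best_move, best_aic = ("add", var), aic
        for var in selected:
            trial = [v for v in selected if v != var]
            try:
                aic = _glm_fit(y, _design(frame, trial, categorical), w).aic
            except Exception:
                continue
            if aic < best_aic:
                best_move, best_aic = ("drop", var), aic
        if best_move is None:
            break
        action, var = best_move
        selected = selected + [var] if action == "add" else [v for v in selected if v != var]
        audit.append({"step": "stepwise", "action": action, "term": var, "aic": best_aic})
        current = best_aic
    return selected


def stepwise_select(
    frame: pd.DataFrame,
    outcome: str,
    base_weights: np.ndarray | pd.Series,
    candidates: Sequence[str],
    categorical: Mapping[str, str | None] | None = None,
    interaction_partners: Sequence[str] = ("age_w2", "sex", "edu_casmin"),
    retention_p: float = 0.05,
    min_cell: int = 25,
    max_abs_logodds: float = 5.0,
    max_se: float = 2.0,
    max_iter: int = 10,
) -> PropensitySpec:
    """Semi-automatic propensity-model selection.

    The loop: (1) bidirectional AIC-stepwise over candidate main effects;
    (2) add interactions of every selected variable with the partner
    variables (age, sex, parental education by default), forcing partner
    main effects into the model; (3) prune any term that is implausible —
    a dummy cell below ``min_cell``, |log-odds| above ``max_abs_logodds``,
    standard error above ``max_se``, or Wald p above ``retention_p``;
    (4) restart the stepwise search with pruned terms banned, until a fixed
    point or ``max_iter``. Fits are weighted by ``base_weights``.
    """
    categorical = dict(categorical or {})
    w = np.asarray(base_weights, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("base weights must be positive")
    y = frame[outcome].to_numpy(dtype=float)
    audit: list = []
    banned: set[str] = set()
    converged = False
    selected: list[str] = []
    inters: list[tuple[str, str]] = []

    for iteration in range(max_iter):
        pool = [c for c in candidates if c not in banned]
        selected = _bidirectional(frame, y, w, pool, categorical, audit)
        inters = []
        for v in selected:
            for p in interaction_partners:
                if p == v or p not in frame.columns or f"{v}:{p}" in banned:
                    continue
                # a selected variable that is itself a partner would pair in
                # both orders; keep one
                if (p, v) in inters or f"{p}:{v}" in banned:
                    continue
                inters.append((v, p))
        # interaction parents must be in the model
        forced = [p for p in interaction_partners if any(q == p for _, q in inters) and p not in selected]
        terms = selected + forced + [f"{a}:{b}" for a, b in inters]
        X = _design(frame, terms, categorical)
        try:
            res = _glm_fit(y, X, w)
            fit_ok = True
        except Exception as exc:  # separation or non-convergence with interactions
            audit.append({"step": "fit_failure", "iteration": iteration, "error": repr(exc)})
            fit_ok = False

        pruned: list[str] = []
        checkable = selected + [f"{a}:{b}" for a, b in inters]
        if not fit_ok:
            pruned = [f"{a}:{b}" for a, b in inters] or list(selected)
        else:
            pvals = 2 * stats.norm.sf(np.abs(res.params / res.bse))
            pvals = pd.Series(pvals, index=res.params.index)
            for term in checkable:
                cols = _term_columns(term, X)
                if not cols:
                    continue
                reasons = []
                for c in cols:
                    x = X[c].to_numpy()
                    if set(np.unique(x)) <= {0.0, 1.0} and 0 < x.sum() < min_cell:
                        reasons.append(f"cell {c} below {min_cell}")
                    if abs(res.params[c]) > max_abs_logodds:
                        reasons.append(f"|log-odds| {abs(res.params[c]):.2f} above cap")
                    if res.bse[c] > max_se:
                        reasons.append(f"SE {res.bse[c]:.2f} above cap")
                if not reasons and float(pvals[cols].min()) > retention_p:
                    reasons.append(f"min Wald p {float(pvals[cols].min()):.3f} above {retention_p}")
                if reasons:
                    pruned.append(term)
                    audit.append(
                        {"step": "prune", "iteration": iteration, "term": term, "reasons": reasons}
                    )
            # interactions are deleted before their (collinear) parents are
            # judged: if any interaction fails, keep mains for the restart
            pruned_inters = [t for t in pruned if ":" in t]
            if pruned_inters:
                pruned = pruned_inters
        if not pruned:
            converged = fit_ok
            break
        banned.update(pruned)
    else:
        audit.append({"step": "non_convergence", "max_iter": max_iter})

    inters = [(a, b) for a, b in inters if f"{a}:{b}" not in banned]
    mains = [t for t in selected if t not in banned]
    forced = [p for p in interaction_partners if any(q == p for _, q in inters) and p not in mains]
    mains = mains + forced
    if not mains and not inters:
        warnings.warn("no candidate survived selection; intercept-only propensity model")
    spec = PropensitySpec(
        outcome=outcome,
        main_effects=mains,
        interactions=inters,
        categorical={v: categorical.get(v) for v in categorical if v in mains},
        converged=converged,
        audit=audit,
    )
    final = _glm_fit(y, _design(frame, spec.terms, categorical), w)
    spec.coefficients = final.params
    return spec


def estimate_propensity(
    frame: pd.DataFrame,
    spec: PropensitySpec,
    base_weights: np.ndarray | pd.Series,
    floor: float = 0.01,
) -> tuple[pd.Series, dict]:
    """Predicted re-participation propensity theta from the weighted fit.

    theta is floored at ``floor`` before any inversion downstream, bounding
    the weight contributed by any single person; floor events are logged.
    """
    w = np.asarray(base_weights, dtype=float)
    if np.any(w <= 0):
        raise ValidationError("base weights must be positive")
    y = frame[spec.outcome].to_numpy(dtype=float)
    X = _design(frame, spec.terms, spec.categorical)
    try:
        res = _glm_fit(y, X, w)
    except Exception as exc:
        raise EstimationError(f"propensity model failed to converge: {exc!r}") from exc
    theta = pd.Series(np.asarray(res.predict(X)), index=frame.index, name="theta")
    floored = int((theta < floor).sum())
    theta = theta.clip(lower=floor)
    return theta, {"n_floored": floored, "floor": floor}


# ---------------------------------------------------------------------------
# weights, combination, diagnostics, balance
# ---------------------------------------------------------------------------

def compute_weights(
    theta: pd.Series,
    base_weights: pd.Series,
    stage: str,
    respondents: pd.Series | None = None,
) -> pd.DataFrame:
    """Longitudinal weights wLS = base / theta for the stage's respondents.

    At the registration stage the base is the cross-sectional weight; at the
    participation stage it is the registration-stage longitudinal weight.
    """
    theta = pd.Series(theta, dtype=float)
    base = pd.Series(base_weights, dtype=float).reindex(theta.index)
    if (theta <= 0).any():
        raise ValidationError("theta must be strictly positive")
    if (theta > 1 + 1e-12).any():
        raise ValidationError("theta must not exceed 1")
    if (base <= 0).any():
        raise ValidationError("base weights must be positive")
    out = pd.DataFrame(
        {"theta": theta, "base_weight": base, "wls": base / theta, "stage": stage},
        index=theta.index,
    )
    if respondents is not None:
        out = out.loc[pd.Series(respondents, dtype=bool).reindex(theta.index).fillna(False)]
    return out


def kish_n_eff(weights: np.ndarray | pd.Series) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2."""
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


@dataclass
class WeightDiagnostics:
    minimum: float
    median: float
    maximum: float
    cv: float  # percent; population SD / mean
    effectiveness: float  # percent; 100 * n_eff / n
    n: int
    n_eff: float

    def as_dict(self) -> dict:
        return {
            "min": self.minimum,
            "median": self.median,
            "max": self.maximum,
            "cv_pct": self.cv,
            "effectiveness_pct": self.effectiveness,
            "n": self.n,
            "n_eff": self.n_eff,
        }


def weight_diagnostics(weights: np.ndarray | pd.Series) -> WeightDiagnostics:
    """Dispersion and effectiveness of a weight vector.

    CV uses the population (divide-by-n) standard deviation so that the
    identity effectiveness = 100 / (1 + (CV/100)^2) is exact.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0:
        raise ValidationError("empty weight vector")
    if np.any(w <= 0):
        raise ValidationError("weights must be positive")
    n_eff = kish_n_eff(w)
    return WeightDiagnostics(
        minimum=float(w.min()),
        median=float(np.median(w)),
        maximum=float(w.max()),
        cv=float(w.std(ddof=0) / w.mean() * 100.0),
        effectiveness=float(100.0 * n_eff / w.size),
        n=int(w.size),
        n_eff=n_eff,
    )


def combine_subsamples(
    weights_a: pd.DataFrame, weights_b: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Convex combination of two separately weighted subsamples.

    Mixing proportions are the subsamples' Kish effective case numbers; each
    subsample's weights are rescaled so its weighted share of the combined
    total equals its proportion, and the combined vector is renormalized to
    mean 1. Using effective rather than nominal case numbers gives the more
    dispersed subsample less mass, raising combined effectiveness.
    """
    if len(weights_a) == 0 or len(weights_b) == 0:
        empty, full = (weights_a, weights_b) if len(weights_a) == 0 else (weights_b, weights_a)
        warnings.warn("one subsample is empty; passthrough with proportion 1")
        out = full.copy()
        out["wls_combined"] = out["wls"] / out["wls"].mean()
        return out, {"a": float(len(weights_a) > 0), "b": float(len(weights_b) > 0)}
    if set(weights_a.index) & set(weights_b.index):
        raise ValidationError("subsamples must be disjoint")
    n_eff = {"a": kish_n_eff(weights_a["wls"]), "b": kish_n_eff(weights_b["wls"])}
    lam = {k: v / sum(n_eff.values()) for k, v in n_eff.items()}
    parts = []
    for key, ws in (("a", weights_a), ("b", weights_b)):
        scaled = ws.copy()
        scaled["wls_combined"] = ws["wls"] * (lam[key] / ws["wls"].sum())
        parts.append(scaled)
    out = pd.concat(parts)
    out["wls_combined"] /= out["wls_combined"].mean()
    return out, lam


@dataclass
class BalanceReport:
    table: pd.DataFrame  # per (parameter, level): percentages with CIs
    max_discrepancy: dict  # parameter -> max |weighted - reference| in pp


def _pct_ci(share: float, n_eff: float) -> tuple[float, float]:
    half = Z95 * np.sqrt(max(share * (1 - share), 0.0) / n_eff) * 100.0
    return share * 100.0 - half, share * 100.0 + half


def balance_report(
    baseline_frame: pd.DataFrame,
    reparticipant_frame: pd.DataFrame,
    weights: np.ndarray | pd.Series,
    parameters: Sequence[str],
    baseline_weights: np.ndarray | pd.Series | None = None,
) -> BalanceReport:
    """Unweighted and weighted composition of re-participants vs. baseline.

    Percentages come with normal-approximation 95% CIs in which the Kish
    effective sample size replaces n. The reference composition is the
    baseline frame (optionally under its own weights).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(reparticipant_frame):
        raise ValidationError("weights must align with the re-participant frame")
    bw = (
        np.ones(len(baseline_frame))
        if baseline_weights is None
        else np.asarray(baseline_weights, dtype=float)
    )
    rows = []
    discrepancy: dict[str, float] = {}
    for param in parameters:
        for frm in (baseline_frame, reparticipant_frame):
            if param not in frm.columns:
                raise SchemaError(f"parameter {param!r} absent from input frame")
        levels = sorted(set(baseline_frame[param].dropna().astype(str)) |
                        set(reparticipant_frame[param].dropna().astype(str)))
        base_vals = baseline_frame[param].astype(str)
        resp_vals = reparticipant_frame[param].astype(str)
        neff_ref = kish_n_eff(bw)
        neff_w = kish_n_eff(w)
        worst = 0.0
        for level in levels:
            ref_share = float(bw[(base_vals == level).to_numpy()].sum() / bw.sum())
            unw_share = float((resp_vals == level).mean())
            w_share = float(w[(resp_vals == level).to_numpy()].sum() / w.sum())
            ref_lo, ref_hi = _pct_ci(ref_share, neff_ref)
            unw_lo, unw_hi = _pct_ci(unw_share, len(reparticipant_frame))
            w_lo, w_hi = _pct_ci(w_share, neff_w)
            worst = max(worst, abs(w_share - ref_share) * 100.0)
            rows.append(
                {
                    "parameter": param,
                    "level": level,
                    "reference_pct": ref_share * 100.0,
                    "reference_ci_low": ref_lo,
                    "reference_ci_high": ref_hi,
                    "unweighted_pct": unw_share * 100.0,
                    "unweighted_ci_low": unw_lo,
                    "unweighted_ci_high": unw_hi,
                    "weighted_pct": w_share * 100.0,
                    "weighted_ci_low": w_lo,
                    "weighted_ci_high": w_hi,
                }
            )
        discrepancy[param] = worst
    return BalanceReport(table=pd.DataFrame(rows), max_discrepancy=discrepancy)
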