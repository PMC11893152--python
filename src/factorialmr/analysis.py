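"""Factorial Mendelian-randomization analysis stages.

Four stages, all sharing one covariate adjustment set (age, sex, assessment
center as one-hot indicators dropping the first, and the first 10 principal
components):

1. instrument-validity lipid associations — linear regression of a measured
   biomarker on the genetically-lower group indicator;
2. per-50-mg/dL hazard ratios — Cox fit on the continuous score in mg/dL,
   reported as exp(-50 * beta) for a 50-mg/dL *decrease* in the genetically
   predicted trait;
3. 2x2 factorial contrasts — one Cox fit with three subgroup indicators
   (reference = higher on both scores);
4. continuous-score interaction test — Cox fit with both standardized
   scores and their product; the Wald p on the product term is the test of
   departure from a multiplicative (log-additive) joint effect.

Composite outcomes (3-/4-point MACE style) are first-event unions of
component outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import CoxFit, fit_cox, fit_linear, wald, Z_95
from .scores import FACTORIAL_GROUPS, FactorialAllocation, dichotomize
from .synthetic import CohortTable, N_PCS

__all__ = [
    "ScaledHR",
    "InteractionResult",
    "FactorialContrast",
    "adjustment_design",
    "biomarker_association",
    "per50_hr",
    "factorial_contrasts",
    "interaction_test",
    "composite_outcome",
]


@dataclass
class ScaledHR:
    """Hazard ratio per 50-mg/dL decrease in the genetically predicted trait."""

    hr_per_50_decrease: float
    ci_low: float
    ci_high: float
    outcome: str
    scale_mg_dl: float = 50.0
    raw_fit: CoxFit = None

    def __post_init__(self):
        if not (self.ci_low <= self.hr_per_50_decrease <= self.ci_high):
            raise ValueError("confidence interval must bracket the point estimate")


@dataclass
class InteractionResult:
    """Product-term interaction test between two genetic score arms."""

    product_coefficient: float
    se: float
    p_interaction: float
    arms: tuple
    outcome: str
    method: str = "continuous"
    raw_fit: CoxFit = None


@dataclass
class FactorialContrast:
    """Per-subgroup hazard ratios versus the both-higher reference group."""

    table: pd.DataFrame  # columns: group, hr, ci_low, ci_high, n, n_events
    outcome: str
    raw_fit: CoxFit = None


def adjustment_design(cohort: CohortTable, intercept: bool = False) -> pd.DataFrame:
    """The shared covariate block: age, sex, center indicators, pc1..pc10."""
    df = cohort.data
    required = ["age", "sex", "center"] + [f"pc{k}" for k in range(1, N_PCS + 1)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise KeyError(f"cohort lacks adjustment covariates: {missing}")
    X = pd.DataFrame(index=df.index)
    if intercept:
        X["intercept"] = 1.0
    X["age"] = df["age"].astype(float)
    X["sex"] = df["sex"].astype(float)
    centers = np.sort(df["center"].unique())
    for c in centers[1:]:  # drop first category
        X[f"center_{c}"] = (df["center"] == c).astype(float)
    for k in range(1, N_PCS + 1):
        X[f"pc{k}"] = df[f"pc{k}"].astype(float)
    return X


def biomarker_association(cohort: CohortTable, scores, biomarker: str) -> dict:
    """Lower-vs-higher genetic group contrast on a measured biomarker (mg/dL).

    Returns the coefficient on the genetically-lower indicator from an
    adjusted linear model; negative = the score's lower half has lower
    measured levels, i.e. genetically proxied lowering works.
    """
    if biomarker not in cohort.data.columns:
        raise KeyError(f"biomarker {biomarker!r} not present in cohort")
    lower = (dichotomize(scores) == "lower").astype(float)
    X = adjustment_design(cohort, intercept=True)
    X.insert(1, "lower_group", lower)
    fit = fit_linear(cohort.data[biomarker].to_numpy(float), X)
    w = fit.wald("lower_group")
    return {
        "biomarker": biomarker,
        "estimate": float(fit.coefficients["lower_group"]),
        "se": float(fit.standard_errors["lower_group"]),
        "ci_low": w.ci_low,
        "ci_high": w.ci_high,
        "p": w.p,
        "n": fit.n,
        "fit": fit,
    }


def per50_hr(cohort: CohortTable, scores, outcome: str, unit: str = "mg/dL") -> ScaledHR:
    """Hazard ratio per 50-mg/dL decrease in the genetically predicted trait.

    Fits the Cox model on the continuous score (mg/dL) plus covariates and
    reports exp(-50 * beta) with interval endpoints exp(-50 * (beta +/- 1.96
    se)) ordered low-to-high.  Scores not measured in mg/dL have no 50-mg/dL
    scale; use per-SD or factorial reporting for those arms.
    """
    if unit != "mg/dL":
        raise ValueError(
            f"per-50-mg/dL scaling requires a mg/dL score, got unit {unit!r}; "
            "report per-SD or per-group instead"
        )
    s = np.asarray(scores, dtype=float).ravel()
    X = adjustment_design(cohort)
    X.insert(0, "score", s)
    time, event = cohort.survival(outcome)
    fit = fit_cox(time, event, X)
    beta = float(fit.coefficients["score"])
    se = float(fit.standard_errors["score"])
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"degenerate score standard error ({se}); cannot scale")
    lo, hi = sorted((np.exp(-50.0 * (beta - Z_95 * se)), np.exp(-50.0 * (beta + Z_95 * se))))
    return ScaledHR(
        hr_per_50_decrease=float(np.exp(-50.0 * beta)),
        ci_low=float(lo),
        ci_high=float(hi),
        outcome=outcome,
        raw_fit=fit,
    )


def factorial_contrasts(cohort: CohortTable, allocation: FactorialAllocation, outcome: str) -> FactorialContrast:
    """Hazard ratios of the three non-reference factorial subgroups.

    One Cox fit with indicators for lowerA_only, lowerB_only and both_lower
    (both_higher omitted as reference) plus the covariate block.
    """
    counts = allocation.counts()
    empty = [g for g in FACTORIAL_GROUPS if counts[g] == 0]
    if empty:
        raise ValueError(f"factorial groups are empty: {empty}")
    X = adjustment_design(cohort)
    for pos, g in enumerate(FACTORIAL_GROUPS[1:]):
        X.insert(pos, g, allocation.indicator(g))
    time, event = cohort.survival(outcome)
    fit = fit_cox(time, event, X)
    rows = [
        {
            "group": "both_higher",
            "hr": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "n": int(counts["both_higher"]),
            "n_events": int(event[allocation.group == "both_higher"].sum()),
        }
    ]
    for g in FACTORIAL_GROUPS[1:]:
        w = fit.wald(g)
        rows.append(
            {
                "group": g,
                "hr": float(np.exp(fit.coefficients[g])),
                "ci_low": float(np.exp(w.ci_low)),
                "ci_high": float(np.exp(w.ci_high)),
                "n": int(counts[g]),
                "n_events": int(event[allocation.group == g].sum()),
            }
        )
    return FactorialContrast(table=pd.DataFrame(rows), outcome=outcome, raw_fit=fit)


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError(f"score {name!r} is constant; interaction test undefined")
    return (x - float(np.mean(x))) / sd


def interaction_test(
    cohort: CohortTable,
    scores_a,
    scores_b,
    outcome: str,
    arms: tuple = ("A", "B"),
    method: str = "continuous",
    standardize: bool = True,
) -> InteractionResult:
    """Test for departure from a multiplicative joint effect of two arms.

    ``method='continuous'`` (default): Cox fit with both scores and their
    product; scores are standardized first (mean 0, SD 1) unless
    ``standardize=False``, which keeps raw trait units.
    ``method='dichotomized'``: the 2x2 analog using median-split lower-group
    indicators and their product — kept for power comparisons; it is the
    less efficient test.
    """
    a = np.asarray(scores_a, dtype=float).ravel()
    b = np.asarray(scores_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("score vectors differ in length")
    if method == "continuous":
        if standardize:
            a = _standardize(a, arms[0])
            b = _standardize(b, arms[1])
        elif np.std(a) == 0 or np.std(b) == 0:
            raise ValueError("scores must be non-constant")
        xa, xb = a, b
    elif method == "dichotomized":
        xa = (dichotomize(a) == "lower").astype(float)
        xb = (dichotomize(b) == "lower").astype(float)
    else:
        raise ValueError(f"unknown interaction method {method!r}")
    X = adjustment_design(cohort)
    X.insert(0, "score_a", xa)
    X.insert(1, "score_b", xb)
    X.insert(2, "product", xa * xb)
    time, event = cohort.survival(outcome)
    fit = fit_cox(time, event, X)
    coef = float(fit.coefficients["product"])
    se = float(fit.standard_errors["product"])
    w = wald(coef, se)
    return InteractionResult(
        product_coefficient=coef,
        se=se,
        p_interaction=w.p,
        arms=tuple(arms),
        outcome=outcome,
        method=method,
        raw_fit=fit,
    )


def composite_outcome(cohort: CohortTable, components: list, name: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """First-event union of component outcomes (MACE-style composite).

    event = any component event; time = earliest component event time if any
    component fires, else the latest censoring time on record (the shared
    administrative horizon for fully censored individuals).
    """
    if len(components) < 2:
        raise ValueError("a composite needs at least 2 component outcomes")
    times, events = [], []
    n = len(cohort)
    for oc in components:
        t, e = cohort.survival(oc)
        if len(t) != n:
            raise ValueError(f"component {oc!r} length mismatch")
        times.append(t)
        events.append(e)
    T = np.column_stack(times)
    E = np.column_stack(events).astype(bool)
    any_event = E.any(axis=1)
    event_time = np.where(E, T, np.inf).min(axis=1)
    censor_time = T.max(axis=1)
    time = np.where(any_event, event_time, censor_time)
    return time, any_event.astype(int)
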