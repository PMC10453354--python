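"""Cohort-adjusted association models for sex differences.

The primary model is a logistic regression of a binary impairment
outcome (PSCI or a single cognitive domain) on sex, with study cohort
entered as fixed-effect indicator covariates:

    logit P(outcome = 1) = b0 + b_sex * I(man) + sum_c b_c * I(cohort c)

Women are the reference group, so exp(b_sex) is the men-vs-women odds
ratio.  No demographic covariates are added because norm-referenced
percentiles are already demographically corrected.  Confidence
intervals and p-values are Wald-based.  Stratified analyses refit the
model within strata (age <65 vs >=65, education below vs at-least high
school, infarct type, or cohort), and effect modification is tested by
a sex-by-stratum product term in the pooled cohort-adjusted model.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .config import AGE_SPLIT_YEARS, EDUCATION_BELOW_HS_CATEGORIES
from .errors import ConvergenceError, SeparationError

__all__ = [
    "LogisticFit",
    "ORResult",
    "StratumResult",
    "fit_logistic_cohort_adjusted",
    "odds_ratio_ci",
    "stratified_or",
    "interaction_test",
    "age_adjusted_difference",
    "add_strata",
]

logger = logging.getLogger(__name__)

_SEPARATION_BOUND = 15.0  # |log-odds| beyond this is treated as separation


@dataclasses.dataclass
class LogisticFit:
    """A fitted logistic model: estimates on the log-odds scale."""

    params: pd.Series
    bse: pd.Series
    cov: pd.DataFrame
    converged: bool
    n_used: int


@dataclasses.dataclass
class ORResult:
    """An odds ratio with Wald 95% CI and two-sided p-value."""

    outcome: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    reference_group: str = "women"

    def __post_init__(self) -> None:
        assert self.ci_low <= self.or_point <= self.ci_high


@dataclasses.dataclass
class StratumResult:
    """A per-stratum odds ratio; interaction p attached at the pair level."""

    stratification: str
    stratum: str
    result: ORResult
    n: int
    interaction_p: float | None = None


def _design(
    outcome: np.ndarray,
    sex: np.ndarray,
    cohort: np.ndarray | None,
    extra: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    y = pd.Series(np.asarray(outcome, dtype=float), name="outcome")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.nunique() < 2:
        raise ValueError("outcome has a single class; model not identifiable")
    man = pd.Series((np.asarray(sex) == "man").astype(float), name="sex_man")
    cols = [man]
    if cohort is not None:
        levels = sorted(pd.unique(np.asarray(cohort, dtype=object)))
        for lev in levels[1:]:  # first cohort alphabetically is the reference
            cols.append(pd.Series((np.asarray(cohort) == lev).astype(float),
                                  name=f"cohort_{lev}"))
    X = pd.concat(cols, axis=1)
    if extra is not None:
        X = pd.concat([X, extra.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, prepend=True)
    return X, y


def fit_logistic_cohort_adjusted(
    outcome,
    sex,
    cohort=None,
    extra_terms: pd.DataFrame | None = None,
) -> LogisticFit:
    """Maximum-likelihood logistic fit of outcome on sex (+ cohort dummies).

    Women are the reference sex and the alphabetically first cohort the
    reference cohort.  Newton/IRLS iterations to gradient tolerance
    1e-8, at most 100 iterations.  Diverging coefficients (|beta| > 15
    on the log-odds scale) raise :class:`SeparationError`.
    """
    X, y = _design(np.asarray(outcome), np.asarray(sex),
                   None if cohort is None else np.asarray(cohort), extra_terms)
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    if np.abs(res.params.to_numpy()).max() > _SEPARATION_BOUND:
        raise SeparationError(
            "diverging coefficient (|beta| > 15): data are separated")
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge in 100 iterations")
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index,
                         columns=res.params.index),
        converged=True,
        n_used=int(len(y)),
    )


def odds_ratio_ci(fit: LogisticFit, term: str = "sex_man",
                  level: float = 0.95, outcome: str = "outcome") -> ORResult:
    """Wald odds ratio, CI and p-value for one model term."""
    if term not in fit.params.index:
        raise KeyError(f"term {term!r} not in fitted model")
    beta = float(fit.params[term])
    se = float(fit.bse[term])
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = 2.0 * stats.norm.sf(abs(beta) / se) if se > 0 else float(beta == 0.0)
    return ORResult(
        outcome=outcome,
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p_value=float(p),
    )


def add_strata(df: pd.DataFrame) -> pd.DataFrame:
    """Derive the stratification variables used in the subgroup analyses.

    Adds ``age65`` (<65 vs >=65), ``education_hs`` (categories 1-2
    below high school vs 3-4) and leaves ``infarct_type`` and
    ``cohort`` as-is when present.
    """
    out = df.copy()
    if "age" in out.columns:
        out["age65"] = np.where(out["age"] < AGE_SPLIT_YEARS, "<65", ">=65")
    if "education4" in out.columns:
        below = out["education4"].isin(EDUCATION_BELOW_HS_CATEGORIES)
        out["education_hs"] = np.where(out["education4"].isna(), None,
                                       np.where(below, "<HS", ">=HS"))
    return out


def stratified_or(
    df: pd.DataFrame, strat_var: str, outcome_col: str = "outcome"
) -> list[StratumResult]:
    """One cohort-adjusted men-vs-women OR per stratum of ``strat_var``.

    Cohort adjustment is dropped when stratifying by cohort itself.
    Strata where the model cannot be fitted (empty, single-class) are
    skipped with a logged warning.
    """
    results: list[StratumResult] = []
    data = df[df[strat_var].notna()]
    for level, sub in data.groupby(strat_var, observed=True, sort=True):
        try:
            fit = fit_logistic_cohort_adjusted(
                sub[outcome_col], sub["sex"],
                None if strat_var == "cohort" else sub["cohort"])
        except (ValueError, SeparationError, ConvergenceError) as exc:
            logger.warning("stratum %s=%r skipped: %s", strat_var, level, exc)
            continue
        results.append(StratumResult(
            stratification=strat_var,
            stratum=str(level),
            result=odds_ratio_ci(fit, outcome=outcome_col),
            n=fit.n_used,
        ))
    return results


def interaction_test(
    df: pd.DataFrame, strat_var: str, outcome_col: str = "outcome"
) -> float:
    """Wald p-value for the sex-by-stratum product term.

    The stratification variable is dichotomized by its sorted levels
    (first level = 0) and entered as a main effect plus its product
    with the sex indicator, in the cohort-adjusted model.
    """
    data = df[df[strat_var].notna()]
    levels = sorted(data[strat_var].astype(str).unique())
    if len(levels) != 2:
        raise ValueError(f"interaction test needs 2 strata, got {levels}")
    ind = (data[strat_var].astype(str) == levels[1]).astype(float)
    man = (data["sex"] == "man").astype(float)
    extra = pd.DataFrame({
        "stratum_ind": ind.to_numpy(),
        "sex_x_stratum": (ind * man).to_numpy(),
    })
    fit = fit_logistic_cohort_adjusted(
        data[outcome_col], data["sex"], data["cohort"], extra_terms=extra)
    beta = float(fit.params["sex_x_stratum"])
    se = float(fit.bse["sex_x_stratum"])
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def age_adjusted_difference(outcome, sex, age) -> tuple[float, float, float]:
    """Age-adjusted women-to-men difference in an impairment proportion.

    Fits the linear model ``outcome ~ I(woman) + age`` by least squares
    and returns the women-minus-men difference in percentage points
    with its t-based 95% CI: ``(difference, ci_low, ci_high)``.
    """
    y = np.asarray(outcome, dtype=float)
    woman = (np.asarray(sex) == "woman").astype(float)
    age = np.asarray(age, dtype=float)
    if np.ptp(age) == 0:
        raise ValueError("age is constant; age adjustment is collinear")
    X = sm.add_constant(pd.DataFrame({"woman": woman, "age": age}))
    res = sm.OLS(y, X).fit()
    diff = 100.0 * float(res.params["woman"])
    tcrit = stats.t.ppf(0.975, df=res.df_resid)
    half = 100.0 * tcrit * float(res.bse["woman"])
    return diff, diff - half, diff + half
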