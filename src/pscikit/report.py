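"""Pipeline orchestration and paper-shaped summary outputs.

``run_pipeline`` chains the stages — simulate (or load), harmonize,
classify, associate, screening meta-analysis — and writes tidy CSV/JSON
results plus a run log that accounts for every excluded patient.
``baseline_table`` builds a Table-1-style by-sex summary with the
conventional group tests (t test for parametric numeric variables,
Mann-Whitney U for nonparametric ones, chi-square for proportions);
which test a variable gets is declared in its spec, not inferred from a
normality test.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib

import numpy as np
import pandas as pd
from scipy import stats

from . import associate, classify, dta
from .config import DOMAINS, RunConfig
from .simulate import GeneratorConfig, generate_study

__all__ = ["baseline_table", "compare_proportions", "run_pipeline"]

logger = logging.getLogger(__name__)


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided chi-square p-value (no continuity correction) for two proportions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group totals must be positive")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], float)
    if table.min() < 0:
        raise ValueError("counts cannot exceed totals or be negative")
    if table.sum(axis=0).min() == 0:  # a margin is empty: no information
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def baseline_table(
    participants: pd.DataFrame,
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Table-1-style summary by sex with per-variable group tests.

    ``variables`` maps column name to its declared type: ``"numeric_t"``
    (mean/SD, t test), ``"numeric_mw"`` (median/IQR, Mann-Whitney U) or
    ``"categorical"`` (percentages, chi-square).  All-missing variables
    are skipped with a warning.
    """
    if variables is None:
        variables = {"age": "numeric_t", "nihss": "numeric_mw",
                     "education4": "categorical"}
    women = participants[participants["sex"] == "woman"]
    men = participants[participants["sex"] == "man"]
    if min(len(women), len(men)) < 2:
        raise ValueError("need at least 2 patients per sex")
    rows = []
    for var, kind in variables.items():
        w = women[var].dropna()
        m = men[var].dropna()
        if w.empty or m.empty:
            logger.warning("variable %r skipped: all missing in one sex", var)
            continue
        if kind == "numeric_t":
            t, p = stats.ttest_ind(w, m, equal_var=True)
            summ_w = f"{w.mean():.1f} ({w.std(ddof=1):.1f})"
            summ_m = f"{m.mean():.1f} ({m.std(ddof=1):.1f})"
            test = "t test"
        elif kind == "numeric_mw":
            _, p = stats.mannwhitneyu(w, m, alternative="two-sided")
            summ_w = f"{w.median():.1f} [{w.quantile(.25):.1f}-{w.quantile(.75):.1f}]"
            summ_m = f"{m.median():.1f} [{m.quantile(.25):.1f}-{m.quantile(.75):.1f}]"
            test = "Mann-Whitney U"
        elif kind == "categorical":
            tab = pd.crosstab(participants[var], participants["sex"])
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
            summ_w = "; ".join(f"{lev}: {100 * (w == lev).mean():.0f}%"
                               for lev in sorted(w.unique()))
            summ_m = "; ".join(f"{lev}: {100 * (m == lev).mean():.0f}%"
                               for lev in sorted(m.unique()))
            test = "chi-square"
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
        rows.append({"variable": var, "women": summ_w, "men": summ_m,
                     "test": test, "p_value": float(p),
                     "n_women": len(w), "n_men": len(m)})
    return pd.DataFrame(rows)


@dataclasses.dataclass
class PipelineResult:
    """In-memory bundle of a full run (everything is also on disk)."""

    participants: pd.DataFrame
    classified: pd.DataFrame
    associations: pd.DataFrame
    dta_results: dict
    exclusions: dict


def _associations(analysis: pd.DataFrame) -> pd.DataFrame:
    """Men-vs-women ORs for PSCI and each domain, plus stratified analyses."""
    rows = []
    outcomes = {"psci": (analysis["psci"] == "present").astype(int)}
    for dom in DOMAINS:
        sub = analysis[analysis[f"impaired_{dom}"].notna()].copy()
        sub["y"] = sub[f"impaired_{dom}"].astype(int)
        # a cohort with no impaired (or no intact) patients separates its
        # own indicator; such cohorts carry no within-cohort information
        # on the sex effect and are dropped from this domain's fit
        per_cohort = sub.groupby("cohort")["y"].nunique()
        keep = per_cohort[per_cohort == 2].index
        dropped = sorted(set(per_cohort.index) - set(keep))
        if dropped:
            logger.info("domain %s: cohorts without outcome variation "
                        "dropped: %s", dom, dropped)
        sub = sub[sub["cohort"].isin(keep)]
        if sub.empty or sub["y"].nunique() < 2:
            continue
        try:
            fit = associate.fit_logistic_cohort_adjusted(
                sub["y"], sub["sex"], sub["cohort"])
            r = associate.odds_ratio_ci(fit, outcome=dom)
            rows.append({"outcome": dom, "stratum": "all", "n": fit.n_used,
                         "or": r.or_point, "ci_low": r.ci_low,
                         "ci_high": r.ci_high, "p_value": r.p_value,
                         "interaction_p": None})
        except Exception as exc:  # noqa: BLE001 - surfaced in the results table
            logger.warning("domain %s association skipped: %s", dom, exc)

    work = analysis.assign(outcome=outcomes["psci"])
    fit = associate.fit_logistic_cohort_adjusted(
        work["outcome"], work["sex"], work["cohort"])
    r = associate.odds_ratio_ci(fit, outcome="psci")
    rows.insert(0, {"outcome": "psci", "stratum": "all", "n": fit.n_used,
                    "or": r.or_point, "ci_low": r.ci_low, "ci_high": r.ci_high,
                    "p_value": r.p_value, "interaction_p": None})

    work = associate.add_strata(work)
    work["infarct_type"] = [
        classify.classify_infarct_type(
            count_of_infarcts=c, supratentorial=s,
            cortical_involvement=ci, volume_ml=v)
        for c, s, ci, v in zip(work["count_of_infarcts"], work["supratentorial"],
                               work["cortical_involvement"], work["volume_ml"])]
    for sv in ("age65", "education_hs", "infarct_type", "cohort"):
        strata = associate.stratified_or(work, sv)
        inter = None
        if sv != "cohort":
            try:
                inter = associate.interaction_test(work, sv)
            except Exception as exc:  # noqa: BLE001
                logger.warning("interaction test for %s failed: %s", sv, exc)
        for s in strata:
            rows.append({"outcome": "psci", "stratum": f"{sv}={s.stratum}",
                         "n": s.n, "or": s.result.or_point,
                         "ci_low": s.result.ci_low, "ci_high": s.result.ci_high,
                         "p_value": s.result.p_value, "interaction_p": inter})
    return pd.DataFrame(rows)


def _dta_analysis(analysis: pd.DataFrame) -> dict:
    """Screening meta-analysis per test and sex, with threshold check."""
    out: dict = {}
    for test in ("MMSE", "MoCA"):
        col = test.lower()
        usable = analysis[analysis[col].notna()]
        if usable.empty:
            continue
        tables = dta.build_all_2x2(usable, test)
        if not tables:
            continue
        points = pd.DataFrame(
            [dict(zip(("sens", "spec"), dta.sens_spec(t))) for t in tables])
        points = points.dropna()
        if len(points) >= 3:
            verdict, rho, _ = dta.threshold_effect_check(points)
        else:
            verdict, rho = "little_evidence", float("nan")
        entry: dict = {"threshold_effect": verdict, "spearman": rho,
                       "n_strata": len(tables)}
        for sex in ("woman", "man"):
            sex_tables = [t for t in tables if t.sex == sex]
            if not sex_tables:
                continue
            for margin in ("sens", "spec"):
                xs = [(t.tp, t.n_diseased) if margin == "sens"
                      else (t.tn, t.n_nondiseased) for t in sex_tables]
                xs = [(x, n) for x, n in xs if n > 0]
                if not xs:
                    continue
                meta = dta.univariate_re_meta(*zip(*xs))
                entry[f"{margin}_{sex}"] = {
                    "pooled": meta.pooled, "ci_low": meta.ci_low,
                    "ci_high": meta.ci_high, "tau": meta.tau,
                    "k": meta.k_studies}
        for margin in ("sens", "spec"):
            tw = [t for t in tables if t.sex == "woman"]
            tm = [t for t in tables if t.sex == "man"]
            if tw and tm:
                cmp_res = dta.compare_sex_accuracy(tw, tm, margin)
                entry[f"{margin}_sex_p"] = cmp_res.p_value
        out[test] = entry
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate -> harmonize -> classify -> associate -> dta end-to-end.

    Deterministic for a fixed ``config.seed``; writes all result tables
    under ``config.outdir`` plus ``run_log.json`` recording the seed and
    every exclusion.
    """
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        gc = GeneratorConfig(seed=config.seed, **config.generator_overrides)
        study = generate_study(gc)
        participants, scores = study.participants, study.test_scores
    else:
        if not (config.participants_csv and config.scores_csv):
            raise ValueError("real-data mode needs participants_csv and scores_csv")
        participants = pd.read_csv(config.participants_csv)
        scores = pd.read_csv(config.scores_csv)
        from .harmonize import harmonize_scores, load_domain_map, load_norms
        dm = load_domain_map(config.domain_map_csv)
        norms = load_norms(config.norms_csv) if config.norms_csv else None
        scores = harmonize_scores(scores, dm, norms)

    if "impaired" not in scores.columns:
        from .harmonize import flag_test_impairment
        scores = scores.copy()
        scores["impaired"] = pd.array(
            [flag_test_impairment(p) if pd.notna(p) else None
             for p in scores["percentile"]], dtype="boolean")

    classified = classify.classify_participants(scores)
    merged = participants.merge(classified, on="id", how="left")
    merged["psci"] = merged["psci"].fillna("indeterminate")
    merged["n_domains_available"] = merged["n_domains_available"].fillna(0)

    n_indeterminate = int((merged["psci"] == "indeterminate").sum())
    analysis = merged[merged["psci"] != "indeterminate"].copy()
    exclusions = {"input_n": int(len(participants)),
                  "indeterminate_psci": n_indeterminate,
                  "analyzed_n": int(len(analysis))}

    associations = _associations(analysis)
    dta_results = _dta_analysis(analysis)
    baseline = baseline_table(merged)

    merged.to_csv(outdir / "classification.csv", index=False)
    associations.to_csv(outdir / "associations.csv", index=False)
    baseline.to_csv(outdir / "baseline_table.csv", index=False)
    with open(outdir / "dta_meta.json", "w") as fh:
        json.dump(dta_results, fh, indent=2, default=float)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"seed": config.seed, "exclusions": exclusions,
                   "thresholds": {
                       "impairment_percentile": config.impairment_percentile,
                       "domain_impaired_fraction": config.domain_impaired_fraction,
                       "min_domains_to_rule_out": config.min_domains_to_rule_out,
                       "mmse_cutoff": config.mmse_cutoff,
                       "moca_cutoff": config.moca_cutoff,
                       "small_subcortical_max_volume_ml":
                           config.small_subcortical_max_volume_ml,
                       "age_split_years": config.age_split_years}},
                  fh, indent=2)
    logger.info("pipeline complete: %s", exclusions)
    return PipelineResult(participants=merged, classified=classified,
                          associations=associations, dta_results=dta_results,
                          exclusions=exclusions)
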