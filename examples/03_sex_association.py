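"""Cohort-adjusted odds ratios for sex differences in domain impairment.

Simulates the default study, classifies everyone, and fits the primary
logistic model per domain: women are the reference group, so an odds
ratio above 1 means the domain is more often impaired in men.
"""

import pandas as pd

from pscikit import (
    DOMAINS,
    GeneratorConfig,
    classify_participants,
    fit_logistic_cohort_adjusted,
    generate_study,
    odds_ratio_ci,
)
from pscikit.harmonize import flag_test_impairment

study = generate_study(GeneratorConfig(seed=7))
scores = study.test_scores.copy()
scores["impaired"] = pd.array(
    [flag_test_impairment(p) for p in scores["percentile"]], dtype="boolean")
merged = study.participants.merge(
    classify_participants(scores), on="id", how="left")
analysis = merged[merged["psci"].isin(["present", "absent"])]

print("men-vs-women odds ratios (cohort-adjusted):")
outcome = (analysis["psci"] == "present").astype(int)
fit = fit_logistic_cohort_adjusted(outcome, analysis["sex"], analysis["cohort"])
r = odds_ratio_ci(fit, outcome="psci")
print(f"  PSCI: OR {r.or_point:.2f} [{r.ci_low:.2f}-{r.ci_high:.2f}]")

for dom in DOMAINS:
    sub = analysis[analysis[f"impaired_{dom}"].notna()]
    keep = sub.groupby("cohort")[f"impaired_{dom}"].nunique()
    sub = sub[sub["cohort"].isin(keep[keep == 2].index)]
    fit = fit_logistic_cohort_adjusted(
        sub[f"impaired_{dom}"].astype(int), sub["sex"], sub["cohort"])
    r = odds_ratio_ci(fit, outcome=dom)
    print(f"  {dom}: OR {r.or_point:.2f} [{r.ci_low:.2f}-{r.ci_high:.2f}]")
# With the default calibration, PSCI itself shows no sex difference
# (OR near 1) while verbal memory leans toward men (OR > 1) and
# attention/executive and language lean toward women (OR < 1).
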