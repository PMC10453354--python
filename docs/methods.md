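# Methods

## The problem

About half of ischemic-stroke survivors develop poststroke cognitive
impairment (PSCI). Whether its occurrence and profile differ between
women and men matters clinically: screening instruments weight
cognitive abilities differently, so sex differences in the *profile* of
impairment can translate into sex differences in how well a screener
detects PSCI. `pscikit` implements the full analysis chain for this
question on pooled multi-cohort data: harmonization of heterogeneous
neuropsychological batteries, rule-based PSCI classification,
cohort-adjusted sex association models, and diagnostic-accuracy
meta-analysis of the MMSE and MoCA screeners against the
neuropsychological gold standard.

Because patient-level data of this kind are not publicly deposited, the
package ships a synthetic multi-cohort generator with the same
statistical structure, and every stage is tested end-to-end on it.

## Classification rules

All rule constants live in `pscikit.config`:

| rule | default | unit |
|---|---|---|
| test impairment | percentile < 5 (strict) | norm-referenced percentile |
| domain impairment | impaired fraction of available tests > 0.5 (strict) | per subject |
| PSCI present | >= 1 impaired domain | — |
| PSCI absent | 0 impaired domains and >= 3 available | — |
| MMSE positive | score < 25 | points |
| MoCA positive | score < 26 | points |
| small subcortical infarct | single, supratentorial, no cortical involvement, volume <= 4.19 mL | mL (2 cm sphere) |
| age strata | < 65 vs >= 65 | years |
| education strata | categories {1,2} vs {3,4} | 4-category variable |

Decisions taken where the rules leave room:

* A percentile of exactly 5.0 is **not** impaired, and a domain with
  exactly half of its tests impaired is **not** impaired — both rules
  are strict inequalities.
* A patient with an impaired domain is PSCI-present even when fewer
  than three domains were assessed; the three-domain minimum is only
  needed to *rule out* PSCI. Patients who are neither present nor
  ruled out are *indeterminate* and are excluded from association and
  screening analyses; the pipeline reports their count rather than
  imputing a verdict.
* The lesion-volume comparison happens at the two-decimal precision the
  threshold is stated in, so 4.19 mL is small-subcortical and 4.20 mL
  is not.
* The default years-to-category education recode is 1 = 0–6 y,
  2 = 7–11 y, 3 = 12–13 y (high-school complete), 4 = >= 14 y. The
  four-category scheme is a consortium convention whose band
  boundaries are not printed anywhere authoritative, so the bands are a
  configurable table with this default, and "below high school" means
  categories {1,2}.

## Harmonization

Cognitive performance is expressed as norm-referenced percentiles.
When a cohort supplies raw scores, the percentile is `100*Phi(z)` with
`z = (raw - mean)/sd` (sign flipped for lower-is-better scores) from a
per-cohort, per-test Gaussian norm table. Real normative practice uses
regression-based demographic corrections that cannot be reproduced from
published material; the mean/SD Gaussian model is the minimal faithful
stand-in, and cohorts that publish percentiles directly can supply them
as-is, bypassing the conversion. A per-norm `sex_adjusted` flag is
carried as metadata because whether local norms correct for sex is
cohort-specific and often unknowable.

## Association models

The primary model is `logit P(impaired) = b0 + b_sex I(man) + cohort
indicators`, women as reference, the alphabetically first cohort as
reference level, fitted by Newton/IRLS to gradient tolerance 1e-8
(at most 100 iterations). No demographic covariates are added because
the percentiles are already norm-corrected for them. CIs and p-values
are Wald-based, matching the default output of the mainstream
commercial packages this kind of analysis is usually run in. A
coefficient diverging beyond |beta| > 15 raises a separation error
rather than silently penalizing; in the orchestrated pipeline, cohorts
with no outcome variation for a given domain (common for rare domains
in small cohorts) are dropped from that domain's fit and logged,
since they carry no within-cohort information about the sex effect.

Stratified analyses refit the model per stratum (cohort adjustment
dropped when stratifying by cohort itself). Effect modification is
tested by adding stratum main effect and sex-by-stratum product terms
to the pooled model (Wald p on the product term). Age-adjusted
women-to-men prevalence differences come from the linear probability
model `outcome ~ I(woman) + age` with t-based CIs, reported in
percentage points.

## Screening meta-analysis

Per cohort-sex stratum, screening scores are cross-tabulated against
the NTB-based PSCI verdict. Pooling uses the binomial-normal model

    x_i ~ Binomial(n_i, invlogit(mu + u_i)),  u_i ~ N(0, tau^2)

by maximum marginal likelihood. The marginal integral is evaluated
with *adaptive* Gauss–Hermite quadrature: per study, a Newton search
finds the posterior mode of `u_i`, the integrand is rescaled by the
local curvature, and 21 nodes are laid along that scale. Adaptivity
matters because at study sizes in the thousands the integrand is far
narrower than the prior scale `tau`; naive quadrature centered at zero
misses it. Optimization is L-BFGS-B within bounds followed by a
Nelder–Mead polish (the finite-difference gradient is noisy at machine
precision near the optimum). `tau` is constrained nonnegative;
estimates below 1e-4 are reported as exactly 0 with a boundary flag,
and the Wald CI for `mu` then uses the profile curvature in `mu` alone.
A single study returns its observed proportion exactly. Zero cells
need no continuity correction: the exact binomial likelihood handles
them.

When the study points in ROC space show a threshold effect, sensitivity
and specificity are pooled jointly by the bivariate model: paired
logits with a bivariate normal random effect `(tau_sens, tau_spec,
rho)` and exact binomial margins, integrated by 15x15 adaptive 2-D
Gauss–Hermite quadrature after per-study mode/curvature
standardization. With either `tau` at the boundary, `rho` is
unidentified and reported as 0. The threshold-effect check is the
Spearman rank correlation between logit(sens) and logit(1-spec) across
studies; correlation >= 0.5 counts as evidence (the criterion is
configurable — no numeric rule is standard).

Sex differences in a pooled margin are tested by meta-regression: all
cohort-sex arms share one binomial-normal model with a fixed sex effect
on the pooled logit and a common between-study SD. The Wald statistic
for the sex effect is referred to a t distribution with (arms - 2)
degrees of freedom. With a handful of studies per sex, ML
underestimates `tau` and the normal reference rejects a true null ~11%
of the time at nominal 5% in our null simulations; the small-sample t
reference — standard practice in random-effects meta-regression —
brings this to ~7%, and a likelihood-ratio variant was no better
(~10%). The whole construction is this package's choice: published
analyses of this design report sex-difference p-values without naming
a method.

Forest tables give per-study Clopper–Pearson (exact binomial) 95%
intervals and a pooled row from the univariate fit.

## The synthetic generator

`GeneratorConfig` defaults define a nine-cohort study of 2,343
patients, 38% women, with uneven cohort sizes (largest ~40%),
per-domain assessment probabilities spanning 0.34–0.98, cohort-specific
battery sizes of 1–3 tests per domain, MMSE in four cohorts, MoCA in
three, none in two. Each patient-domain draws one latent impairment
indicator `Bernoulli(impair_prob[domain, sex])` shared by all of that
domain's tests; impaired tests draw percentiles Uniform(0,5), intact
ones Uniform(5,100), so the downstream <5th-percentile rule recovers
the latent state exactly, and the empirical domain impairment rate
converges to the configured probability whatever the battery size.
`true_psci` (>= 1 latently impaired domain) is the synthetic ground
truth that screening accuracy is calibrated against: a screen is
positive with probability `sens` given true PSCI and `1 - spec`
otherwise, then an integer score is placed on the matching side of the
cutoff.

The default per-domain, per-sex impairment probabilities are calibrated
so the implied domain prevalences span the observed 11–29% range and
the implied men-vs-women odds ratios equal the headline effects this
analysis is built to detect (verbal memory 0.25/0.3228 → OR 1.43,
attention/executive 0.29/0.2369 → OR 0.76, language 0.20/0.1435 →
OR 0.67, remaining domains near 1). Ages are Normal(68.3, 11.8) for
women and Normal(64.9, 11.8) for men (a single SD keeps the config
small; age only feeds stratification and adjustment), education
categories are drawn so ~71% of women and ~45% of men fall below high
school, and small-subcortical infarct probabilities are 0.35/0.28.
Randomness is split into independent substreams (covariates, cognitive
scores, missingness, screeners) from one seed, so perturbing one
mechanism leaves the others' draws intact.

One visible consequence of assuming independent domains: at the
observed 11–29% domain rates, the implied latent PSCI prevalence is
~79%, well above the ~51% real cohorts show, because in patients
impairments cluster across domains. The defaults are calibrated to the
domain-level prevalences and odds ratios (the quantities the analysis
estimates); matching the 51% headline prevalence instead requires
either correlated domains (out of scope) or uniformly lower rates
(as in the six-by-11.2% construction used in the recovery checks,
where 1 − (1 − 0.112)^6 ≈ 51%).

What the generator does **not** emulate: correlation between domains
beyond the independence of their latent indicators, regression-based
norms, informative missingness (assessment is independent of
impairment), item-level screener structure, prestroke decline, and
lesion anatomy beyond the four fields the infarct rule needs. Passing
tests therefore demonstrate that the *rules and estimators* are
correct under the assumed structure, not that real cohort data meet
that structure.

## Numerical and simulation choices

* Quadrature: 21 nodes (1-D) and 15x15 (2-D); doubling nodes moves
  pooled logits by < 1e-4 on the standard fixtures (tested).
* Empirical logits with a 0.5 continuity offset are used only for
  optimizer starting values, never for inference.
* Parameter-recovery checks run at n = 45,000 (odds ratios; 3
  Monte-Carlo SEs ≈ 7%), n = 40,000 (PSCI prevalence; ±1 point), and
  k = 3–4 cohorts × n = 5,000 (meta-analysis; ±0.02). Null-calibration
  checks use 500 replicates at n = 600 (interaction) and 4 cohorts ×
  500/arm (sex comparison). These sizes make the whole suite run in a
  few minutes on one CPU while keeping Monte-Carlo error well inside
  the assertion tolerances.
* The generator treats 2,343 as the study size; consortium reports
  print both 2,343 and 2,434 in different places, and the smaller,
  more frequently printed figure was adopted.

## Known limitations

* No HSROC (Rutter–Gatsonis) parameterization of the bivariate model;
  no optimal-cutoff search; no rendering of figures (plot-ready tables
  only).
* No mixed-effects (random cohort intercept) association models and no
  multiple-imputation for missing covariates; exclusion is listwise per
  analysis, with counts logged.
* No multiplicity correction anywhere (by design; single pre-specified
  contrasts).
* The bivariate fit needs >= 3 studies with both margins nonzero and
  will refuse otherwise, pointing to the univariate route.
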