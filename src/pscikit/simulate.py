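"""Synthetic multi-cohort study generator.

No patient-level data from the pooled stroke cohorts are deposited, so
the pipeline ships a generator that emulates their statistical
structure: nine cohorts totalling 2,343 patients (38% women), each with
its own neuropsychological battery (differing numbers of tests per
domain), per-domain assessment rates between 34% and 98%,
sex-differential latent impairment probabilities per domain, and a
cognitive screening instrument (MMSE in four cohorts, MoCA in three,
none in two) whose agreement with true PSCI is controlled by per-cohort,
per-sex sensitivity and specificity.

Impairment is encoded in percentile space: an impaired test draws its
norm-referenced percentile from Uniform(0, 5), an intact one from
Uniform(5, 100), so the <5th-percentile rule downstream recovers the
latent indicator exactly.  Each patient-domain carries one latent
impairment indicator shared by all of that domain's tests, so the
empirical domain impairment rate converges to the configured
probability whatever the battery size.  ``true_psci`` is the latent
ground truth — at least one of the six domains latently impaired — and
exists only in synthetic data.

Randomness is driven by one global seed split into independent
substreams (patients/covariates, test scores, missingness, screeners),
so changing e.g. the missingness pattern leaves the latent cognitive
draws untouched.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import DOMAINS, MMSE_CUTOFF, MOCA_CUTOFF, SEX_LEVELS
from .errors import ConfigurationError

__all__ = ["GeneratorConfig", "StudyData", "generate_study", "generate_dta_cohorts"]

# Default per-domain, per-sex latent impairment probabilities.  Chosen so
# the implied domain prevalences span the observed 11-29% range and the
# implied men-vs-women odds ratios are the headline effects: verbal
# memory 1.43, attention/executive 0.76, language 0.67, others near 1.
_DEFAULT_IMPAIR_PROB: dict[str, dict[str, float]] = {
    "attention_executive": {"woman": 0.29, "man": 0.2369},
    "processing_speed": {"woman": 0.23, "man": 0.23},
    "language": {"woman": 0.20, "man": 0.1435},
    "verbal_memory": {"woman": 0.25, "man": 0.3228},
    "visuospatial_perception": {"woman": 0.29, "man": 0.28},
    "visuospatial_memory": {"woman": 0.11, "man": 0.13},
}

# Per-domain probability that a patient was assessed on the domain at
# all; the observed per-domain assessment rates range from 34% to 98%.
_DEFAULT_ASSESS_PROB: dict[str, float] = {
    "attention_executive": 0.98,
    "processing_speed": 0.95,
    "language": 0.90,
    "verbal_memory": 0.93,
    "visuospatial_perception": 0.85,
    "visuospatial_memory": 0.34,
}

_DEFAULT_COHORTS = tuple(f"cohort_{i + 1:02d}" for i in range(9))

# Uneven cohort sizes typical of a pooled consortium (largest ~40%).
_DEFAULT_WEIGHTS = (0.40, 0.17, 0.11, 0.09, 0.07, 0.06, 0.05, 0.03, 0.02)

_DEFAULT_SCREENER = ("MMSE", "MMSE", "MMSE", "MMSE", "MoCA", "MoCA", "MoCA",
                     "none", "none")

# Screening accuracy against true PSCI: centred on the pooled MMSE
# (sens 0.53 women / 0.27 men, spec 0.80 / 0.96) and MoCA (sens
# 0.91 / 0.86, spec 0.29 / 0.28) estimates, with mild cohort scatter
# added in generate_study via the configured values per cohort.
_DEFAULT_SENS = {"MMSE": {"woman": 0.53, "man": 0.27},
                 "MoCA": {"woman": 0.91, "man": 0.86}}
_DEFAULT_SPEC = {"MMSE": {"woman": 0.80, "man": 0.96},
                 "MoCA": {"woman": 0.29, "man": 0.28}}


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must be in [0, 1], got {value}")


@dataclasses.dataclass
class GeneratorConfig:
    """Parameters of the synthetic multi-cohort study.

    Defaults reproduce the pooled study's marginal structure; all
    fields can be overridden for targeted simulations.
    """

    n_total: int = 2343
    prop_women: float = 0.38
    n_cohorts: int = 9
    cohort_weights: Sequence[float] = _DEFAULT_WEIGHTS
    domain_names: Sequence[str] = DOMAINS
    #: tests per domain for each cohort: mapping cohort index -> 6 counts.
    tests_per_domain: Sequence[Sequence[int]] | None = None
    domain_assess_prob: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(_DEFAULT_ASSESS_PROB))
    impair_prob: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: {d: dict(v) for d, v in _DEFAULT_IMPAIR_PROB.items()})
    screener: Sequence[str] = _DEFAULT_SCREENER
    screener_sens: Mapping[str, Mapping[str, float]] | None = None
    screener_spec: Mapping[str, Mapping[str, float]] | None = None
    age_mean_by_sex: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"woman": 68.3, "man": 64.9})
    age_sd: float = 11.8
    educ_dist_by_sex: Mapping[str, Sequence[float]] = dataclasses.field(
        default_factory=lambda: {"woman": (0.30, 0.41, 0.14, 0.15),
                                 "man": (0.15, 0.30, 0.25, 0.30)})
    small_subcortical_prob_by_sex: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"woman": 0.35, "man": 0.28})
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_prob("prop_women", self.prop_women)
        if self.n_total < self.n_cohorts:
            raise ConfigurationError(
                f"n_total ({self.n_total}) < n_cohorts ({self.n_cohorts})")
        if len(self.cohort_weights) != self.n_cohorts:
            raise ConfigurationError("cohort_weights length != n_cohorts")
        w = np.asarray(self.cohort_weights, dtype=float)
        if (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigurationError("cohort_weights must be >=0 and sum to 1")
        if len(self.domain_names) != 6:
            raise ConfigurationError("exactly 6 cognitive domains are required")
        if self.tests_per_domain is None:
            # battery sizes differ by cohort: 1-3 tests per domain
            rng = np.random.default_rng(12345)  # fixed: battery design, not data
            self.tests_per_domain = [
                [int(rng.integers(1, 4)) for _ in self.domain_names]
                for _ in range(self.n_cohorts)
            ]
        if len(self.tests_per_domain) != self.n_cohorts:
            raise ConfigurationError("tests_per_domain needs one row per cohort")
        for row in self.tests_per_domain:
            if len(row) != 6 or any(t < 0 for t in row):
                raise ConfigurationError("tests_per_domain rows need 6 counts >= 0")
        for d in self.domain_names:
            _check_prob(f"domain_assess_prob[{d}]", self.domain_assess_prob[d])
            for s in SEX_LEVELS:
                _check_prob(f"impair_prob[{d}][{s}]", self.impair_prob[d][s])
        if len(self.screener) != self.n_cohorts:
            raise ConfigurationError("screener needs one entry per cohort")
        if any(s not in ("MMSE", "MoCA", "none") for s in self.screener):
            raise ConfigurationError("screener entries must be MMSE, MoCA or none")
        if self.screener_sens is None:
            self.screener_sens = {t: dict(v) for t, v in _DEFAULT_SENS.items()}
        if self.screener_spec is None:
            self.screener_spec = {t: dict(v) for t, v in _DEFAULT_SPEC.items()}
        for table in (self.screener_sens, self.screener_spec):
            for t, by_sex in table.items():
                for s, p in by_sex.items():
                    _check_prob(f"screener accuracy [{t}][{s}]", p)
        for s in SEX_LEVELS:
            probs = np.asarray(self.educ_dist_by_sex[s], dtype=float)
            if len(probs) != 4 or (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError("educ_dist_by_sex needs 4 probs summing to 1")
            _check_prob(f"small_subcortical_prob_by_sex[{s}]",
                        self.small_subcortical_prob_by_sex[s])


@dataclasses.dataclass
class StudyData:
    """A generated study: one row per patient plus a long test-score table."""

    participants: pd.DataFrame
    test_scores: pd.DataFrame

    def to_csv(self, outdir, prefix: str = "synthetic") -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / f"{prefix}_participants.csv", index=False)
        self.test_scores.to_csv(out / f"{prefix}_test_scores.csv", index=False)


def generate_study(config: GeneratorConfig) -> StudyData:
    """Draw a full synthetic multi-cohort study.

    Deterministic for a fixed ``config.seed``.  See the module
    docstring for the generative model.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng_pat, rng_scores, rng_miss, rng_screen = (
        np.random.default_rng(s) for s in root.spawn(4))

    n = config.n_total
    domains = list(config.domain_names)
    cohort_labels = [f"cohort_{i + 1:02d}" for i in range(config.n_cohorts)]

    cohort_idx = rng_pat.choice(config.n_cohorts, size=n,
                                p=np.asarray(config.cohort_weights, float))
    sex = np.where(rng_pat.random(n) < config.prop_women, "woman", "man")

    age = np.empty(n)
    educ4 = np.empty(n, dtype=int)
    nihss = np.empty(n, dtype=int)
    small_sub = np.empty(n, dtype=bool)
    for s in SEX_LEVELS:
        m = sex == s
        k = int(m.sum())
        age[m] = np.clip(
            rng_pat.normal(config.age_mean_by_sex[s], config.age_sd, size=k), 18, 99)
        educ4[m] = rng_pat.choice(
            [1, 2, 3, 4], size=k, p=np.asarray(config.educ_dist_by_sex[s], float))
        # stroke severity: women present slightly more severe (median 3 vs 2)
        nihss[m] = rng_pat.poisson(3.2 if s == "woman" else 2.6, size=k)
        small_sub[m] = rng_pat.random(k) < config.small_subcortical_prob_by_sex[s]

    volume = np.where(small_sub,
                      rng_pat.uniform(0.05, 4.19, size=n),
                      rng_pat.uniform(4.20, 120.0, size=n))
    supratentorial = np.where(small_sub, True, rng_pat.random(n) < 0.85)
    cortical = np.where(small_sub, False, rng_pat.random(n) < 0.70)
    count_inf = np.where(small_sub, 1, rng_pat.integers(1, 4, size=n))

    # latent per-test impairment indicators and percentile scores
    sex_is_w = sex == "woman"
    rows: dict[str, list] = {k: [] for k in
                             ("id", "cohort", "test_name", "domain", "percentile")}
    true_dom_imp = np.zeros((n, 6), dtype=bool)
    for d_i, dom in enumerate(domains):
        p_w = config.impair_prob[dom]["woman"]
        p_m = config.impair_prob[dom]["man"]
        p_imp = np.where(sex_is_w, p_w, p_m)
        assessed = rng_miss.random(n) < config.domain_assess_prob[dom]
        n_tests = np.array([config.tests_per_domain[c][d_i] for c in cohort_idx])
        max_t = int(n_tests.max(initial=0))
        if max_t == 0:
            continue
        # one latent impairment indicator per patient-domain, shared by all
        # of the domain's tests, so the empirical domain impairment rate
        # converges to impair_prob regardless of battery size
        ind = rng_scores.random(n) < p_imp
        u_low = rng_scores.uniform(0.0, 5.0, size=(n, max_t))
        u_high = rng_scores.uniform(5.0, 100.0, size=(n, max_t))
        pct = np.where(ind[:, None], u_low, u_high)
        active = np.arange(max_t)[None, :] < n_tests[:, None]
        true_dom_imp[:, d_i] = (n_tests > 0) & ind
        take = active & assessed[:, None]
        pid, tid = np.nonzero(take)
        rows["id"].extend(pid)
        rows["cohort"].extend(cohort_idx[pid])
        rows["test_name"].extend(
            f"{dom}_t{t + 1}" for t in tid)
        rows["domain"].extend([dom] * len(pid))
        rows["percentile"].extend(pct[pid, tid])

    true_psci = true_dom_imp.any(axis=1)

    # screening scores conditioned on true PSCI
    mmse = np.full(n, np.nan)
    moca = np.full(n, np.nan)
    for c_i, label in enumerate(cohort_labels):
        tool = config.screener[c_i]
        if tool == "none":
            continue
        cutoff = MMSE_CUTOFF if tool == "MMSE" else MOCA_CUTOFF
        target = mmse if tool == "MMSE" else moca
        for s in SEX_LEVELS:
            m = (cohort_idx == c_i) & (sex == s)
            k = int(m.sum())
            if k == 0:
                continue
            sens = config.screener_sens[tool][s]
            spec = config.screener_spec[tool][s]
            p_pos = np.where(true_psci[m], sens, 1.0 - spec)
            pos = rng_screen.random(k) < p_pos
            below = rng_screen.integers(max(cutoff - 10, 0), cutoff, size=k)
            at_or_above = rng_screen.integers(cutoff, 31, size=k)
            target[m] = np.where(pos, below, at_or_above)

    ids = [f"p{i:06d}" for i in range(n)]
    participants = pd.DataFrame({
        "id": ids,
        "cohort": [cohort_labels[c] for c in cohort_idx],
        "sex": sex,
        "age": np.round(age, 1),
        "education4": educ4,
        "nihss": nihss,
        "count_of_infarcts": count_inf,
        "supratentorial": supratentorial.astype(bool),
        "cortical_involvement": cortical.astype(bool),
        "volume_ml": np.round(volume, 2),
        "mmse": mmse,
        "moca": moca,
        "true_psci": true_psci,
    })
    scores = pd.DataFrame({
        "id": [ids[i] for i in rows["id"]],
        "cohort": [cohort_labels[c] for c in rows["cohort"]],
        "test_name": rows["test_name"],
        "domain": rows["domain"],
        "percentile": rows["percentile"],
    })
    return StudyData(participants=participants, test_scores=scores)


def generate_dta_cohorts(
    k: int, n_per_cohort: int, true_props: Sequence[float], seed: int
) -> pd.DataFrame:
    """Draw per-cohort binomial event counts for meta-analysis fixtures.

    Returns a DataFrame with columns ``cohort``, ``events``, ``total``;
    ``events ~ Binomial(n_per_cohort, true_props[i])`` independently.
    """
    if len(true_props) != k:
        raise ConfigurationError("true_props length must equal k")
    for p in true_props:
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"true proportion outside [0, 1]: {p}")
    rng = np.random.default_rng(seed)
    events = rng.binomial(n_per_cohort, np.asarray(true_props, float))
    return pd.DataFrame({
        "cohort": [f"study_{i + 1}" for i in range(k)],
        "events": events,
        "total": n_per_cohort,
    })
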