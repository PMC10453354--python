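import numpy as np
import pandas as pd
import pytest

from pscikit import DOMAINS, GeneratorConfig, generate_study
from pscikit.harmonize import flag_test_impairment


@pytest.fixture(scope="session")
def small_study():
    """A small default-config synthetic study shared across tests."""
    return generate_study(GeneratorConfig(n_total=800, seed=42))


@pytest.fixture(scope="session")
def classified_small_study(small_study):
    from pscikit import classify_participants

    scores = small_study.test_scores.copy()
    scores["impaired"] = pd.array(
        [flag_test_impairment(p) for p in scores["percentile"]],
        dtype="boolean")
    cls = classify_participants(scores)
    return small_study.participants.merge(cls, on="id", how="left")


def single_test_study(n_total, prop_women, impair_prob_by_domain, seed,
                      n_cohorts=9):
    """A study with one test per domain, all domains assessed.

    ``impair_prob_by_domain`` maps domain -> {'woman': p, 'man': p}.
    Domains not mentioned get probability 0.2 for both sexes.
    """
    impair = {d: dict(impair_prob_by_domain.get(d, {"woman": 0.2, "man": 0.2}))
              for d in DOMAINS}
    cfg = GeneratorConfig(
        n_total=n_total, prop_women=prop_women, n_cohorts=n_cohorts,
        cohort_weights=[1.0 / n_cohorts] * n_cohorts,
        tests_per_domain=[[1] * 6] * n_cohorts,
        domain_assess_prob={d: 1.0 for d in DOMAINS},
        impair_prob=impair, seed=seed)
    return generate_study(cfg)


def classify_study(study):
    from pscikit import classify_participants

    scores = study.test_scores.copy()
    scores["impaired"] = pd.array(
        [flag_test_impairment(p) for p in scores["percentile"]],
        dtype="boolean")
    cls = classify_participants(scores)
    return study.participants.merge(cls, on="id", how="left")
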