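"""Analysis constants and run configuration.

Every threshold used anywhere in the pipeline lives here, as a named
constant with its clinical default, so a single grep shows the rules in
force:

* a test score below the 5th norm-referenced percentile is impaired;
* a cognitive domain is impaired when strictly more than half of the
  available tests on it are impaired;
* poststroke cognitive impairment (PSCI) is impairment in at least one
  domain, and can only be ruled out when at least three domains were
  assessed;
* MMSE screens positive below 25, MoCA below 26;
* a small subcortical infarct is a single supratentorial infarct without
  cortical involvement of at most 4.19 mL (a sphere of 2 cm diameter);
* age strata split at 65 years.
"""

from __future__ import annotations

import dataclasses
import pathlib
import tomllib
from typing import Any

#: The six harmonized cognitive domains, in canonical order.
DOMAINS: tuple[str, ...] = (
    "attention_executive",
    "processing_speed",
    "language",
    "verbal_memory",
    "visuospatial_perception",
    "visuospatial_memory",
)

#: Norm-referenced percentile below which a single test is impaired (strict <).
IMPAIRMENT_PERCENTILE: float = 5.0

#: Fraction of available tests on a domain that must be impaired (strict >).
DOMAIN_IMPAIRED_FRACTION: float = 0.5

#: Minimum number of assessed domains needed to rule PSCI out.
MIN_DOMAINS_TO_RULE_OUT: int = 3

#: MMSE screens positive when the score is strictly below this cutoff.
MMSE_CUTOFF: int = 25

#: MoCA screens positive when the score is strictly below this cutoff.
MOCA_CUTOFF: int = 26

#: Maximum lesion volume (mL) for a small subcortical infarct (inclusive).
SMALL_SUBCORTICAL_MAX_VOLUME_ML: float = 4.19

#: Age (years) splitting the young/old strata (<65 vs >=65).
AGE_SPLIT_YEARS: int = 65

#: Education categories counted as "below high school" ({1,2} vs {3,4}).
EDUCATION_BELOW_HS_CATEGORIES: frozenset[int] = frozenset({1, 2})

#: Two-sided significance threshold used in reports (no multiplicity correction).
SIGNIFICANCE_LEVEL: float = 0.05

SEX_LEVELS: tuple[str, str] = ("woman", "man")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Thresholds default to the clinical rule constants above; overriding
    them is supported for sensitivity analyses but the defaults are the
    published rules.
    """

    seed: int = 0
    outdir: str = "psci_output"
    simulate: bool = True
    participants_csv: str | None = None
    scores_csv: str | None = None
    norms_csv: str | None = None
    domain_map_csv: str | None = None

    impairment_percentile: float = IMPAIRMENT_PERCENTILE
    domain_impaired_fraction: float = DOMAIN_IMPAIRED_FRACTION
    min_domains_to_rule_out: int = MIN_DOMAINS_TO_RULE_OUT
    mmse_cutoff: int = MMSE_CUTOFF
    moca_cutoff: int = MOCA_CUTOFF
    small_subcortical_max_volume_ml: float = SMALL_SUBCORTICAL_MAX_VOLUME_ML
    age_split_years: int = AGE_SPLIT_YEARS

    generator_overrides: dict[str, Any] = dataclasses.field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str | pathlib.Path) -> "RunConfig":
        """Load a run configuration from a TOML file.

        Unknown keys raise, so typos in threshold names fail loudly
        instead of silently running with defaults.
        """
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
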