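"""Domain impairment, PSCI classification and infarct typing.

The classification rules, applied per subject:

* a domain is *available* when at least one of its tests has a score,
  and *impaired* when strictly more than 50% of the available tests on
  it are impaired;
* PSCI is *present* with >=1 impaired domain; *absent* only when no
  domain is impaired and >=3 domains were available; otherwise the
  verdict is *indeterminate* and the patient is excluded from the
  association and diagnostic-accuracy analyses;
* an infarct is *small subcortical* iff it is single, supratentorial,
  without cortical involvement, and its volume is at most 4.19 mL.

A patient with an impaired domain is classified present even when fewer
than three domains were assessed: the three-domain minimum is only
needed to rule PSCI out.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .config import (
    DOMAIN_IMPAIRED_FRACTION,
    DOMAINS,
    MIN_DOMAINS_TO_RULE_OUT,
    SMALL_SUBCORTICAL_MAX_VOLUME_ML,
)
from .harmonize import TestResult

__all__ = [
    "DomainStatus",
    "CognitiveProfile",
    "InfarctInfo",
    "assess_domain",
    "classify_psci",
    "classify_infarct_type",
    "classify_participants",
]

PsciVerdict = Literal["present", "absent", "indeterminate"]


@dataclasses.dataclass(frozen=True)
class DomainStatus:
    """Availability and impairment of one cognitive domain for one patient."""

    domain: str
    n_tests_available: int
    n_tests_impaired: int

    def __post_init__(self) -> None:
        if self.n_tests_impaired > self.n_tests_available:
            raise ValueError("more impaired tests than available tests")
        if min(self.n_tests_available, self.n_tests_impaired) < 0:
            raise ValueError("negative test counts")

    @property
    def available(self) -> bool:
        return self.n_tests_available >= 1

    @property
    def impaired(self) -> bool | None:
        """Impaired iff strictly more than half of available tests are; None if unassessed."""
        if not self.available:
            return None
        return self.n_tests_impaired / self.n_tests_available > DOMAIN_IMPAIRED_FRACTION


@dataclasses.dataclass(frozen=True)
class CognitiveProfile:
    """Per-domain status and the PSCI verdict for one patient."""

    domains: tuple[DomainStatus, ...]
    psci: PsciVerdict

    @property
    def n_domains_available(self) -> int:
        return sum(d.available for d in self.domains)

    @property
    def n_domains_impaired(self) -> int:
        return sum(bool(d.impaired) for d in self.domains)


@dataclasses.dataclass(frozen=True)
class InfarctInfo:
    """Lesion characteristics needed for infarct typing."""

    count_of_infarcts: int
    supratentorial: bool
    cortical_involvement: bool
    volume_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError(f"negative lesion volume: {self.volume_ml}")


def assess_domain(tests: Iterable[TestResult], domain: str | None = None) -> DomainStatus:
    """Summarize one patient's tests on a single domain.

    Tests without a percentile are not available and do not count in
    either numerator or denominator.
    """
    tests = list(tests)
    domains = {t.domain for t in tests}
    if domain is None:
        if len(domains) != 1:
            raise ValueError(f"tests span multiple domains: {sorted(domains)}")
        domain = next(iter(domains))
    elif domains - {domain}:
        raise ValueError(f"tests from other domains passed for {domain!r}")
    scored = [t for t in tests if t.percentile is not None]
    return DomainStatus(
        domain=domain,
        n_tests_available=len(scored),
        n_tests_impaired=sum(bool(t.impaired) for t in scored),
    )


def classify_psci(domains: Iterable[DomainStatus]) -> PsciVerdict:
    """Apply the PSCI rule to the six domain statuses of one patient."""
    statuses = list(domains)
    if len(statuses) != len(DOMAINS):
        raise ValueError(f"expected {len(DOMAINS)} domain slots, got {len(statuses)}")
    n_impaired = sum(bool(d.impaired) for d in statuses)
    n_available = sum(d.available for d in statuses)
    if n_impaired >= 1:
        return "present"
    if n_available >= MIN_DOMAINS_TO_RULE_OUT:
        return "absent"
    return "indeterminate"


def classify_infarct_type(
    info: InfarctInfo | None = None,
    *,
    count_of_infarcts: int | None = None,
    supratentorial: bool | None = None,
    cortical_involvement: bool | None = None,
    volume_ml: float | None = None,
) -> Literal["small_subcortical", "other"]:
    """Type an infarct as small subcortical versus other.

    Small subcortical requires all of: a single infarct, supratentorial
    location, no cortical involvement, and volume <= 4.19 mL (the
    volume of a 2 cm diameter sphere).  Volume is compared at the
    2-decimal precision the threshold is stated in.
    """
    if info is None:
        info = InfarctInfo(
            count_of_infarcts=count_of_infarcts,
            supratentorial=supratentorial,
            cortical_involvement=cortical_involvement,
            volume_ml=volume_ml,
        )
    small = (
        info.count_of_infarcts == 1
        and info.supratentorial
        and not info.cortical_involvement
        and round(info.volume_ml, 2) <= SMALL_SUBCORTICAL_MAX_VOLUME_ML
    )
    return "small_subcortical" if small else "other"


def classify_participants(harmonized_scores: pd.DataFrame) -> pd.DataFrame:
    """Classify every patient in a harmonized long score table.

    Input columns: ``id``, ``domain``, ``percentile``, ``impaired``
    (from :func:`pscikit.harmonize.harmonize_scores`).  Returns one row
    per patient: per-domain ``avail_*`` and ``impaired_*`` columns,
    ``n_domains_available``, ``n_domains_impaired`` and the ``psci``
    verdict.  Patients appear even if all their scores are missing
    (verdict indeterminate).
    """
    df = harmonized_scores
    scored = df[df["percentile"].notna()]
    avail = (
        scored.groupby(["id", "domain"], observed=True)["impaired"]
        .agg(n_av="size", n_imp="sum")
        .reset_index()
    )
    avail["dom_impaired"] = avail["n_imp"] / avail["n_av"] > DOMAIN_IMPAIRED_FRACTION

    out = pd.DataFrame({"id": pd.unique(df["id"])}).set_index("id")
    piv = avail.pivot(index="id", columns="domain", values="dom_impaired")
    piv = piv.reindex(out.index)
    for dom in DOMAINS:
        col = piv[dom] if dom in piv.columns else pd.Series(np.nan, index=out.index)
        out[f"avail_{dom}"] = col.notna().to_numpy()
        out[f"impaired_{dom}"] = pd.array(
            [None if pd.isna(v) else bool(v) for v in col], dtype="boolean")
    out["n_domains_available"] = out[[f"avail_{d}" for d in DOMAINS]].sum(axis=1)
    out["n_domains_impaired"] = (
        out[[f"impaired_{d}" for d in DOMAINS]].fillna(False).sum(axis=1).astype(int)
    )
    out["psci"] = [
        "present" if ni >= 1
        else ("absent" if na >= MIN_DOMAINS_TO_RULE_OUT else "indeterminate")
        for ni, na in zip(out["n_domains_impaired"], out["n_domains_available"])
    ]
    return out.reset_index()
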