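"""Harmonization of heterogeneous cohort data.

Cohorts contribute different neuropsychological batteries, different
education codings and different local norms.  This module converts them
to the common analysis representation: a 4-category education variable,
norm-referenced percentiles on every test, and a per-test impairment
flag (<5th percentile).

Percentiles are computed from a Gaussian norm model (mean/SD per cohort
and test); cohorts that publish percentiles directly can supply them and
bypass the conversion.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import DOMAINS, IMPAIRMENT_PERCENTILE
from .errors import MappingError

__all__ = [
    "TestResult",
    "NormEntry",
    "DEFAULT_EDUCATION_YEARS_SCHEME",
    "recode_education",
    "percentile_from_norms",
    "flag_test_impairment",
    "load_norms",
    "load_domain_map",
    "harmonize_scores",
]


@dataclasses.dataclass
class TestResult:
    """One neuropsychological test administration for one patient."""

    test_name: str
    domain: str
    raw_score: float | None = None
    percentile: float | None = None
    impaired: bool | None = None

    def __post_init__(self) -> None:
        if self.domain not in DOMAINS:
            raise ValueError(f"unknown cognitive domain: {self.domain!r}")
        if self.percentile is not None:
            if not 0.0 <= self.percentile <= 100.0:
                raise ValueError(f"percentile out of [0, 100]: {self.percentile}")
            if self.impaired is None:
                self.impaired = flag_test_impairment(self.percentile)


@dataclasses.dataclass(frozen=True)
class NormEntry:
    """Normative mean/SD for one test in one cohort.

    ``higher_is_better`` orients the score: True for accuracy-type
    scores, False for completion times.  ``sex_adjusted`` records
    whether the local norms already correct for sex; it is carried as
    metadata and does not change the percentile computation.
    """

    cohort: str
    test_name: str
    norm_mean: float
    norm_sd: float
    higher_is_better: bool = True
    sex_adjusted: bool = False

    def __post_init__(self) -> None:
        if not self.norm_sd > 0:
            raise ValueError(f"norm_sd must be positive, got {self.norm_sd}")


#: Default years-of-education to 4-category recode:
#: 1 = 0-6 y, 2 = 7-11 y, 3 = 12-13 y (high school complete), 4 = >=14 y.
DEFAULT_EDUCATION_YEARS_SCHEME: tuple[tuple[float, int], ...] = (
    (6, 1),
    (11, 2),
    (13, 3),
    (math.inf, 4),
)


def recode_education(raw, scheme=None, *, cohort: str = "?") -> int | None:
    """Recode a cohort's raw education value to the 4-category variable.

    Parameters
    ----------
    raw
        Years of education (numeric) or a local categorical code.
        Missing values (None/NaN) propagate to ``None``.
    scheme
        Either a sequence of ``(upper_bound_years, category)`` bands
        applied to numeric years (default: 1 = <=6 y, 2 = 7-11 y,
        3 = 12-13 y, 4 = >=14 y), or a mapping from local codes to
        categories 1-4 for cohorts that supply categories.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    if isinstance(scheme, dict):
        try:
            cat = scheme[raw]
        except KeyError:
            raise MappingError(
                f"cohort {cohort!r}: education value {raw!r} not in recode scheme"
            ) from None
    else:
        bands = DEFAULT_EDUCATION_YEARS_SCHEME if scheme is None else tuple(scheme)
        years = float(raw)
        if years < 0:
            raise MappingError(f"cohort {cohort!r}: negative education years {raw!r}")
        cat = next(c for bound, c in bands if years <= bound)
    if cat not in (1, 2, 3, 4):
        raise MappingError(f"cohort {cohort!r}: recoded category {cat!r} not in 1-4")
    return int(cat)


def percentile_from_norms(raw_score: float, norm: NormEntry) -> float:
    """Express a raw test score as a norm-referenced percentile (0-100).

    The percentile is 100*Phi(z) with z = (raw - mean)/sd when higher
    scores are better, and z = (mean - raw)/sd otherwise, so that low
    percentiles always mean poor performance.
    """
    if norm.higher_is_better:
        z = (raw_score - norm.norm_mean) / norm.norm_sd
    else:
        z = (norm.norm_mean - raw_score) / norm.norm_sd
    return 100.0 * stats.norm.cdf(z)


def flag_test_impairment(percentile: float) -> bool:
    """True iff the percentile is strictly below the 5th.

    A score at exactly the 5th percentile is *not* impaired.
    """
    if not 0.0 <= percentile <= 100.0:
        raise ValueError(f"percentile out of [0, 100]: {percentile}")
    return percentile < IMPAIRMENT_PERCENTILE


# ---------------------------------------------------------------------------
# Table-level interfaces (CSV)
# ---------------------------------------------------------------------------

def load_norms(path) -> dict[tuple[str, str], NormEntry]:
    """Read a normative table CSV.

    Columns: cohort, test_name, norm_mean, norm_sd, higher_is_better
    (0/1), and optionally sex_adjusted (0/1).
    """
    df = pd.read_csv(path)
    out: dict[tuple[str, str], NormEntry] = {}
    for row in df.itertuples(index=False):
        entry = NormEntry(
            cohort=str(row.cohort),
            test_name=str(row.test_name),
            norm_mean=float(row.norm_mean),
            norm_sd=float(row.norm_sd),
            higher_is_better=bool(row.higher_is_better),
            sex_adjusted=bool(getattr(row, "sex_adjusted", False)),
        )
        out[entry.cohort, entry.test_name] = entry
    return out


def load_domain_map(path) -> dict[tuple[str, str], str]:
    """Read a test-to-domain mapping CSV with columns cohort, test_name, domain."""
    df = pd.read_csv(path)
    mapping: dict[tuple[str, str], str] = {}
    for row in df.itertuples(index=False):
        key = (str(row.cohort), str(row.test_name))
        domain = str(row.domain)
        if domain not in DOMAINS:
            raise MappingError(f"unknown domain {domain!r} for {key}")
        if key in mapping and mapping[key] != domain:
            raise MappingError(f"test {key} mapped to more than one domain")
        mapping[key] = domain
    return mapping


def harmonize_scores(
    scores: pd.DataFrame,
    domain_map: dict[tuple[str, str], str],
    norms: dict[tuple[str, str], NormEntry] | None = None,
) -> pd.DataFrame:
    """Harmonize a long participant-by-test score table.

    ``scores`` needs columns ``id``, ``cohort``, ``test_name`` and
    either ``percentile`` (used as-is) or ``raw_score`` (converted via
    ``norms``).  Returns the table with ``domain``, ``percentile`` and
    ``impaired`` columns; rows whose score is missing keep
    ``impaired`` as NA.
    """
    df = scores.copy()
    keys = list(zip(df["cohort"].astype(str), df["test_name"].astype(str)))
    try:
        df["domain"] = [domain_map[k] for k in keys]
    except KeyError as exc:
        raise MappingError(f"test not in domain map: {exc.args[0]}") from None

    if "percentile" not in df.columns:
        df["percentile"] = np.nan
    need = df["percentile"].isna() & df.get("raw_score", pd.Series(np.nan, index=df.index)).notna()
    if need.any():
        if norms is None:
            raise MappingError("raw scores supplied but no normative table given")
        pct = np.full(len(df), np.nan)
        for i in np.flatnonzero(need.to_numpy()):
            key = keys[i]
            if key not in norms:
                raise MappingError(f"no norms for cohort/test {key}")
            pct[i] = percentile_from_norms(float(df["raw_score"].iloc[i]), norms[key])
        df.loc[need, "percentile"] = pct[need.to_numpy()]

    present = df["percentile"].notna()
    bad = present & ~df["percentile"].between(0.0, 100.0)
    if bad.any():
        raise ValueError("percentiles out of [0, 100] in score table")
    df["impaired"] = pd.array(
        [flag_test_impairment(p) if ok else None
         for p, ok in zip(df["percentile"], present)],
        dtype="boolean",
    )
    return df
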