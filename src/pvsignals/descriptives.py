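"""Demographic, temporal, and serious-outcome descriptives per drug."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reports import OUTCOMES, DrugLexicon, ReportStore, filter_primary_suspect
from .rounding import round_half_away

AGE_BINS = ("<18", "18-40", "41-65", ">65", "unknown")


def _bin_age(age: float) -> str:
    # bins close as [0,18), [18,40], (40,65], (65,inf); the published table
    # prints integer-age bins 18-40 / 41-65 so the 40/41 edge is implicit
    if np.isnan(age):
        return "unknown"
    if age < 18:
        return "<18"
    if age <= 40:
        return "18-40"
    if age <= 65:
        return "41-65"
    return ">65"


@dataclass(frozen=True)
class DemographicSummary:
    drug: str
    total: int
    sex_counts: dict[str, int]
    sex_pct: dict[str, float]
    age_median: float | None  # None when no age is known
    age_q1: float | None
    age_q3: float | None
    age_bin_counts: dict[str, int]
    age_bin_pct: dict[str, float]
    country_counts: dict[str, int]  # includes "unknown"
    country_pct: dict[str, float]


@dataclass(frozen=True)
class OutcomeSummary:
    drug: str
    total: int
    counts: dict[str, int]
    pct: dict[str, float]


@dataclass(frozen=True)
class YearlySeries:
    drug: str
    counts: dict[int, int]  # year -> retained report count


def summarize_demographics(
    store: ReportStore,
    drug: str,
    lexicon: DrugLexicon | None = None,
    ndigits: int = 2,
) -> DemographicSummary:
    """Sex/age/country breakdown of a drug's primary-suspect reports.

    Age median and quartiles use linear interpolation over known ages only;
    unknowns are reported as their own category, never dropped from the
    denominator.
    """
    subset = filter_primary_suspect(store, drug, lexicon)
    frame = subset.frame
    total = len(frame)

    def pct(n: int) -> float:
        return round_half_away(100 * n / total, ndigits) if total else 0.0

    sex_counts = {s: int((frame["sex"] == s).sum()) for s in ("female", "male", "unknown")}
    ages = frame["age_years"].to_numpy(dtype=float)
    known = ages[~np.isnan(ages)]
    if known.size:
        q1, med, q3 = np.percentile(known, [25, 50, 75])  # linear interpolation
        age_median, age_q1, age_q3 = float(med), float(q1), float(q3)
    else:
        age_median = age_q1 = age_q3 = None
    bin_counts = Counter(_bin_age(a) for a in ages)
    age_bin_counts = {b: bin_counts.get(b, 0) for b in AGE_BINS}
    country_counter = Counter(
        c if c is not None else "unknown" for c in frame["country"]
    )
    country_counts = dict(
        sorted(country_counter.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return DemographicSummary(
        drug=drug,
        total=total,
        sex_counts=sex_counts,
        sex_pct={k: pct(v) for k, v in sex_counts.items()},
        age_median=age_median,
        age_q1=age_q1,
        age_q3=age_q3,
        age_bin_counts=age_bin_counts,
        age_bin_pct={k: pct(v) for k, v in age_bin_counts.items()},
        country_counts=country_counts,
        country_pct={k: pct(v) for k, v in country_counts.items()},
    )


def summarize_outcomes(
    store: ReportStore,
    drug: str,
    lexicon: DrugLexicon | None = None,
    ndigits: int = 2,
) -> OutcomeSummary:
    """Serious-outcome counts: a report contributes once per category it carries."""
    subset = filter_primary_suspect(store, drug, lexicon)
    total = len(subset)
    counter: Counter[str] = Counter()
    for outcomes in subset.frame["outcomes"]:
        counter.update(outcomes)
    counts = {c: counter.get(c, 0) for c in sorted(OUTCOMES)}
    pct = {
        c: round_half_away(100 * n / total, ndigits) if total else 0.0
        for c, n in counts.items()
    }
    return OutcomeSummary(drug=drug, total=total, counts=counts, pct=pct)


def yearly_counts(
    store: ReportStore, drug: str, lexicon: DrugLexicon | None = None
) -> YearlySeries:
    """Report count per calendar year of the retained report version."""
    subset = filter_primary_suspect(store, drug, lexicon)
    counts = subset.frame["year"].value_counts().sort_index()
    return YearlySeries(
        drug=drug, counts={int(y): int(c) for y, c in counts.items()}
    )


def demographics_frame(summary: DemographicSummary) -> pd.DataFrame:
    """Flatten a demographic summary into a tidy (section, category, n, pct) table."""
    rows = []
    for cat, n in summary.sex_counts.items():
        rows.append(("sex", cat, n, summary.sex_pct[cat]))
    rows.append(("age", "median", summary.age_median, None))
    rows.append(("age", "q1", summary.age_q1, None))
    rows.append(("age", "q3", summary.age_q3, None))
    for cat, n in summary.age_bin_counts.items():
        rows.append(("age_bin", cat, n, summary.age_bin_pct[cat]))
    for cat, n in summary.country_counts.items():
        rows.append(("country", cat, n, summary.country_pct[cat]))
    rows.append(("total", "total", summary.total, 100.0 if summary.total else 0.0))
    return pd.DataFrame(rows, columns=["section", "category", "n", "pct"])
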