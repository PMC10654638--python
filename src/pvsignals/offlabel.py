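"""Off-label indication mining and within-indication adverse-event profiles.

A drug's label merges the approved indications and labeled adverse events
of all its marketed specifications.  Off-label use is exact set difference
on normalized terms: an indication recorded in the database but absent from
the merged approved list.  Within an indication subgroup, unlabeled events
are profiled with an optional grouping map that aggregates related
preferred terms under an umbrella term.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass

from .errors import ConfigError, LexiconError
from .reports import (
    DrugLexicon,
    ReportStore,
    filter_primary_suspect,
    normalize_term,
    normalize_terms,
)
from .rounding import round_half_away

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DrugLabel:
    """Merged label content for one drug (all specifications combined)."""

    drug: str
    approved_indications: frozenset[str]
    labeled_aes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "drug", normalize_term(self.drug))
        object.__setattr__(
            self, "approved_indications", normalize_terms(self.approved_indications)
        )
        object.__setattr__(self, "labeled_aes", normalize_terms(self.labeled_aes))


def load_labels(path) -> dict[str, DrugLabel]:
    """Read drug labels from the structured JSON config.

    Schema: {canonical: {"approved_indications": [...], "labeled_aes": [...]}}
    (extra keys such as "synonyms" are ignored so lexicon and labels can
    share one file).
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {
        normalize_term(name): DrugLabel(
            drug=name,
            approved_indications=frozenset(entry.get("approved_indications", [])),
            labeled_aes=frozenset(entry.get("labeled_aes", [])),
        )
        for name, entry in raw.items()
    }


def load_lexicon(path) -> DrugLexicon:
    """Read a drug synonym lexicon from the same JSON config as labels."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return DrugLexicon(
        {name: frozenset(entry.get("synonyms", [])) for name, entry in raw.items()}
    )


@dataclass(frozen=True)
class IndicationCount:
    indication: str
    n: int
    pct: float  # of the drug's total primary-suspect reports


@dataclass(frozen=True)
class AEProfileEntry:
    term: str  # event or umbrella group name
    n: int
    pct: float  # of reports carrying the target indication
    members: tuple[str, ...] = ()  # constituent terms when grouped


def find_offlabel(
    store: ReportStore,
    drug: str,
    label: DrugLabel,
    lexicon: DrugLexicon | None = None,
    ndigits: int = 2,
) -> list[IndicationCount]:
    """Rank indications recorded for the drug but absent from its label.

    A report counts once per distinct indication term; percentages use the
    drug's total primary-suspect report count as denominator (reports with
    no recorded indication stay in the denominator).  Sorted by count
    descending, ties broken lexicographically.
    """
    subset = filter_primary_suspect(store, drug, lexicon)
    total = len(subset)
    counts: Counter[str] = Counter()
    for inds in subset.frame["indications"]:
        counts.update(inds - label.approved_indications)
    out = [
        IndicationCount(term, n, round_half_away(100 * n / total, ndigits))
        for term, n in counts.items()
    ]
    out.sort(key=lambda r: (-r.n, r.indication))
    return out


def load_grouping(path) -> dict[str, frozenset[str]]:
    """Read an umbrella-term grouping map (JSON: group -> member terms).

    An empty file body maps to the identity grouping.  A member listed
    twice within a group, or shared between two groups, is a validation
    error.
    """
    with open(path, encoding="utf-8") as fh:
        text = fh.read().strip()
    raw = json.loads(text) if text else {}
    grouping: dict[str, frozenset[str]] = {}
    seen: dict[str, str] = {}
    for group, members in raw.items():
        group = normalize_term(group)
        normed = [normalize_term(m) for m in members]
        if len(set(normed)) != len(normed):
            raise ConfigError(f"group {group!r} lists a member twice")
        for m in normed:
            if m in seen:
                raise ConfigError(
                    f"term {m!r} belongs to both {seen[m]!r} and {group!r}"
                )
            seen[m] = group
        grouping[group] = frozenset(normed)
    return grouping


def profile_indication_aes(
    store: ReportStore,
    drug: str,
    indication: str,
    label: DrugLabel,
    grouping: dict[str, frozenset[str]] | None = None,
    lexicon: DrugLexicon | None = None,
    ndigits: int = 1,
) -> list[AEProfileEntry]:
    """Profile unlabeled adverse events within one indication subgroup.

    The denominator is the number of the drug's primary-suspect reports
    carrying ``indication``.  Events in the drug's labeled-AE set are
    excluded.  With a grouping map, a report counts once per group whose
    members intersect its events; ungrouped events stand alone.
    """
    indication = normalize_term(indication)
    subset = filter_primary_suspect(store, drug, lexicon)
    mask = subset.frame["indications"].map(lambda s: indication in s).to_numpy()
    denom = int(mask.sum())
    if denom == 0:
        logger.warning(
            "no %s reports carry indication %r; empty profile", drug, indication
        )
        return []
    grouping = grouping or {}
    member_to_group = {m: g for g, ms in grouping.items() for m in ms}
    counts: Counter[str] = Counter()
    for events in subset.frame.loc[mask, "events"]:
        unlabeled = events - label.labeled_aes
        counts.update({member_to_group.get(t, t) for t in unlabeled})
    out = [
        AEProfileEntry(
            term,
            n,
            round_half_away(100 * n / denom, ndigits),
            members=tuple(sorted(grouping.get(term, ()))),
        )
        for term, n in counts.items()
    ]
    out.sort(key=lambda r: (-r.n, r.term))
    return out
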