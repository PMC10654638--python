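"""Data model, I/O, drug-name normalization, deduplication and role filtering
for spontaneous adverse-event report stores.

A :class:`ReportStore` wraps a :class:`pandas.DataFrame` with one row per
individual safety report.  Multi-valued fields (drugs, events, indications,
outcomes) are held as immutable Python objects in object-dtype columns so
that bulk operations stay vectorized while the record-level
:class:`SafetyReport` API remains available.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidTermError, LexiconError, ParseError, StoreStateError

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Terms and roles

PRIMARY_SUSPECT = "primary_suspect"
SECONDARY_SUSPECT = "secondary_suspect"
CONCOMITANT = "concomitant"
INTERACTING = "interacting"
ROLES = frozenset({PRIMARY_SUSPECT, SECONDARY_SUSPECT, CONCOMITANT, INTERACTING})

SEXES = frozenset({"female", "male", "unknown"})

OUTCOMES = frozenset(
    {
        "death",
        "life_threatening",
        "hospitalization",
        "disability",
        "congenital_anomaly",
        "required_intervention",
        "other",
    }
)

_WS = re.compile(r"\s+")


def normalize_term(raw: str) -> str:
    """Canonicalize free text: trim, case-fold, collapse internal whitespace.

    Raises
    ------
    InvalidTermError
        If the input is empty after normalization.
    """
    out = _WS.sub(" ", str(raw)).strip().casefold()
    if not out:
        raise InvalidTermError(f"term is empty after normalization: {raw!r}")
    return out


def normalize_terms(raw: Iterable[str]) -> frozenset[str]:
    """Normalize a collection of terms into a duplicate-free set."""
    return frozenset(normalize_term(t) for t in raw)


# ---------------------------------------------------------------------------
# Drug lexicon


@dataclass(frozen=True)
class DrugLexicon:
    """Canonical drug name -> set of synonyms (generic and trade names).

    The canonical name itself always resolves.  Construction fails if any
    normalized synonym maps to two canonical names.
    """

    entries: Mapping[str, frozenset[str]]
    _reverse: Mapping[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        entries = {
            normalize_term(name): normalize_terms(syns) | {normalize_term(name)}
            for name, syns in self.entries.items()
        }
        reverse: dict[str, str] = {}
        for name, syns in entries.items():
            for syn in syns:
                other = reverse.get(syn)
                if other is not None and other != name:
                    raise LexiconError(
                        f"synonym {syn!r} maps to both {other!r} and {name!r}"
                    )
                reverse[syn] = name
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "_reverse", reverse)

    def __contains__(self, canonical: str) -> bool:
        return normalize_term(canonical) in self.entries

    def resolve(self, verbatim: str) -> str | None:
        """Return the canonical name for ``verbatim`` or None if unresolved."""
        try:
            key = normalize_term(verbatim)
        except InvalidTermError:
            return None
        return self._reverse.get(key)


def resolve_drug(verbatim: str, lexicon: DrugLexicon) -> str | None:
    """Resolve a verbatim drug name against a lexicon; None when unknown."""
    return lexicon.resolve(verbatim)


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class DrugEntry:
    """One drug mention on a report, with its reporting role."""

    verbatim_name: str
    canonical_name: str | None
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {sorted(ROLES)}")


@dataclass(frozen=True)
class SafetyReport:
    """One spontaneous adverse-event report (a single submitted version)."""

    isr_id: int
    case_id: int
    version: int
    drugs: tuple[DrugEntry, ...]
    events: frozenset[str]
    indications: frozenset[str]
    sex: str = "unknown"
    age_years: float | None = None
    country: str | None = None
    year: int = 0
    outcomes: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.drugs:
            raise ValueError("a report must list at least one drug")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.age_years is not None and self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        if self.version < 0:
            raise ValueError("version must be non-negative")
        bad = self.outcomes - OUTCOMES
        if bad:
            raise ValueError(f"unknown outcome categories: {sorted(bad)}")


_COLUMNS = [
    "isr_id",
    "case_id",
    "version",
    "drugs",
    "events",
    "indications",
    "sex",
    "age_years",
    "country",
    "year",
    "outcomes",
]


class ReportStore:
    """A collection of safety reports backed by a DataFrame.

    Parameters
    ----------
    frame:
        One row per report with the documented columns.  ``drugs`` holds
        tuples of :class:`DrugEntry`; ``events``/``indications``/``outcomes``
        hold frozensets of normalized terms; ``age_years`` uses NaN and
        ``country`` uses None for unknown.
    deduplicated:
        True when at most one report per case_id is present.
    """

    def __init__(self, frame: pd.DataFrame, deduplicated: bool = False):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"report frame missing columns: {missing}")
        if frame["isr_id"].duplicated().any():
            raise ValueError("isr_id values must be unique within a store")
        if deduplicated and frame["case_id"].duplicated().any():
            raise ValueError("store flagged deduplicated but case_ids repeat")
        self._frame = frame[_COLUMNS].reset_index(drop=True)
        self.deduplicated = deduplicated
        self._ps_cache: dict[str, np.ndarray] = {}

    # -- construction -------------------------------------------------------

    @classmethod
    def from_reports(
        cls, reports: Iterable[SafetyReport], deduplicated: bool = False
    ) -> "ReportStore":
        rows = [
            (
                r.isr_id,
                r.case_id,
                r.version,
                r.drugs,
                r.events,
                r.indications,
                r.sex,
                np.nan if r.age_years is None else float(r.age_years),
                r.country,
                r.year,
                r.outcomes,
            )
            for r in reports
        ]
        frame = pd.DataFrame(rows, columns=_COLUMNS)
        if not rows:  # preserve dtypes for the empty store
            frame = frame.astype(
                {"isr_id": int, "case_id": int, "version": int, "year": int}
            )
        return cls(frame, deduplicated=deduplicated)

    # -- basic API ----------------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def __len__(self) -> int:
        return len(self._frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReportStore):
            return NotImplemented
        return self.deduplicated == other.deduplicated and self._frame.equals(
            other._frame
        )

    def reports(self) -> Iterator[SafetyReport]:
        for row in self._frame.itertuples(index=False):
            yield SafetyReport(
                isr_id=int(row.isr_id),
                case_id=int(row.case_id),
                version=int(row.version),
                drugs=row.drugs,
                events=row.events,
                indications=row.indications,
                sex=row.sex,
                age_years=None if pd.isna(row.age_years) else float(row.age_years),
                country=row.country,
                year=int(row.year),
                outcomes=row.outcomes,
            )

    # -- role filtering -----------------------------------------------------

    def primary_suspect_mask(self, drug: str) -> np.ndarray:
        """Boolean mask of reports with ``drug`` in the primary-suspect role."""
        drug = normalize_term(drug)
        cached = self._ps_cache.get(drug)
        if cached is None:
            cached = np.fromiter(
                (
                    any(
                        e.canonical_name == drug and e.role == PRIMARY_SUSPECT
                        for e in entry
                    )
                    for entry in self._frame["drugs"]
                ),
                dtype=bool,
                count=len(self._frame),
            )
            self._ps_cache[drug] = cached
        return cached

    def subset(self, mask: np.ndarray) -> "ReportStore":
        return ReportStore(self._frame.loc[mask], deduplicated=self.deduplicated)


def require_deduplicated(store: ReportStore, op: str) -> None:
    if not store.deduplicated:
        raise StoreStateError(f"{op} requires a deduplicated store")


def deduplicate(store: ReportStore) -> ReportStore:
    """Keep one report per case: the highest (version, isr_id). Idempotent."""
    frame = store.frame.sort_values(
        ["case_id", "version", "isr_id"], kind="mergesort"
    ).drop_duplicates("case_id", keep="last")
    frame = frame.sort_values("isr_id", kind="mergesort")
    out = ReportStore(frame, deduplicated=True)
    logger.info("deduplicate: %d -> %d reports", len(store), len(out))
    return out


def filter_primary_suspect(
    store: ReportStore, drug: str, lexicon: DrugLexicon | None = None
) -> ReportStore:
    """Reports where ``drug`` is listed in the primary-suspect role.

    When a lexicon is given, ``drug`` must be one of its canonical names.
    """
    require_deduplicated(store, "filter_primary_suspect")
    if lexicon is not None and drug not in lexicon:
        raise LexiconError(f"{drug!r} is not a canonical name in the lexicon")
    return store.subset(store.primary_suspect_mask(drug))


# ---------------------------------------------------------------------------
# Delimited I/O
#
# Tab-separated, UTF-8, header row.  Multi-valued fields use ";" between
# entries; a drug entry is "verbatim|role".  Empty string means unknown.

_FIELD_SEP = ";"
_ROLE_SEP = "|"


def _parse_row(
    row: dict[str, str], line: int, lexicon: DrugLexicon | None
) -> SafetyReport:
    try:
        drugs = []
        for token in filter(None, row["drugs"].split(_FIELD_SEP)):
            verbatim, _, role = token.rpartition(_ROLE_SEP)
            if not verbatim:
                raise ParseError(f"drug entry {token!r} lacks a role", line)
            # without a lexicon, fall back to identity resolution so stores
            # written by this package stay queryable on their own
            canonical = (
                lexicon.resolve(verbatim)
                if lexicon is not None
                else normalize_term(verbatim)
            )
            drugs.append(DrugEntry(verbatim.strip(), canonical, role))
        return SafetyReport(
            isr_id=int(row["isr_id"]),
            case_id=int(row["case_id"]),
            version=int(row["version"]),
            drugs=tuple(drugs),
            events=normalize_terms(filter(None, row["events"].split(_FIELD_SEP))),
            indications=normalize_terms(
                filter(None, row["indications"].split(_FIELD_SEP))
            ),
            sex=row["sex"] or "unknown",
            age_years=float(row["age_years"]) if row["age_years"] else None,
            country=row["country"] or None,
            year=int(row["year"]),
            outcomes=frozenset(filter(None, row["outcomes"].split(_FIELD_SEP))),
        )
    except ParseError:
        raise
    except (KeyError, ValueError, InvalidTermError) as exc:
        raise ParseError(str(exc), line) from exc


def read_reports(
    path, lexicon: DrugLexicon | None = None, strict: bool = True
) -> ReportStore:
    """Read a report store from the documented TSV schema.

    Malformed rows raise :class:`ParseError` with their line number when
    ``strict``; otherwise they are skipped with a warning.
    """
    reports: list[SafetyReport] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(_COLUMNS) - set(reader.fieldnames):
            raise ParseError(f"missing header columns; expected {_COLUMNS}", 1)
        for i, row in enumerate(reader, start=2):
            try:
                reports.append(_parse_row(row, i, lexicon))
            except ParseError as exc:
                if strict:
                    raise
                logger.warning("skipping malformed row: %s", exc)
    return ReportStore.from_reports(reports)


def write_reports(store: ReportStore, path) -> None:
    """Write a store to the documented TSV schema (lossless round trip)."""
    frame = store.frame
    out = pd.DataFrame(
        {
            "isr_id": frame["isr_id"],
            "case_id": frame["case_id"],
            "version": frame["version"],
            "drugs": [
                _FIELD_SEP.join(f"{e.verbatim_name}{_ROLE_SEP}{e.role}" for e in t)
                for t in frame["drugs"]
            ],
            "events": [_FIELD_SEP.join(sorted(s)) for s in frame["events"]],
            "indications": [_FIELD_SEP.join(sorted(s)) for s in frame["indications"]],
            "sex": frame["sex"].replace("unknown", ""),
            "age_years": frame["age_years"].map(
                lambda a: "" if pd.isna(a) else format(a, "g")
            ),
            "country": frame["country"].map(lambda c: c or ""),
            "year": frame["year"],
            "outcomes": [_FIELD_SEP.join(sorted(s)) for s in frame["outcomes"]],
        }
    )
    out.to_csv(path, sep="\t", index=False)
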