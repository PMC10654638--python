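"""Overlap and tiering of significant signal sets between two drugs.

Shared adverse events are compared on point ROR values only (no CI-overlap
test is applied; confidence intervals should be consulted before reading a
tier as evidence of a real difference).  The two directional tier
thresholds are independent because published comparisons often use
asymmetric cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

from .stats import SignalStats

A_STRONGER = "a_stronger"
B_STRONGER = "b_stronger"
TIE = "tie"


@dataclass(frozen=True)
class OverlapRecord:
    """One adverse event significant for both drugs."""

    event: str
    stats_a: SignalStats
    stats_b: SignalStats
    ror_diff: float  # ror_a - ror_b
    direction: str  # a_stronger | b_stronger | tie
    tier: str | None  # e.g. "d>20" when the difference clears its threshold


@dataclass(frozen=True)
class ComparisonSummary:
    n_overlap: int
    n_a_stronger: int
    n_b_stronger: int
    n_ties: int
    records: tuple[OverlapRecord, ...]  # sorted by |ror_diff| descending

    def tiered(self, direction: str) -> tuple[OverlapRecord, ...]:
        return tuple(
            r for r in self.records if r.direction == direction and r.tier is not None
        )


def compare_signals(
    signals_a: list[SignalStats],
    signals_b: list[SignalStats],
    threshold_a: float = 20.0,
    threshold_b: float = 50.0,
) -> ComparisonSummary:
    """Intersect two significant-signal lists and tier by ROR difference.

    A record is tiered ``d>threshold_a`` when ror_a − ror_b strictly exceeds
    ``threshold_a``, and ``d>threshold_b`` when ror_b − ror_a strictly
    exceeds ``threshold_b``.  Equal RORs are direction ``tie`` and never
    tiered.
    """
    by_a = {s.event: s for s in signals_a if s.significant}
    by_b = {s.event: s for s in signals_b if s.significant}
    records = []
    for event in by_a.keys() & by_b.keys():
        sa, sb = by_a[event], by_b[event]
        diff = sa.ror - sb.ror
        if diff > 0:
            direction = A_STRONGER
            tier = f"d>{threshold_a:g}" if diff > threshold_a else None
        elif diff < 0:
            direction = B_STRONGER
            tier = f"d>{threshold_b:g}" if -diff > threshold_b else None
        else:
            direction, tier = TIE, None
        records.append(OverlapRecord(event, sa, sb, diff, direction, tier))
    records.sort(key=lambda r: (-abs(r.ror_diff), r.event))
    return ComparisonSummary(
        n_overlap=len(records),
        n_a_stronger=sum(r.direction == A_STRONGER for r in records),
        n_b_stronger=sum(r.direction == B_STRONGER for r in records),
        n_ties=sum(r.direction == TIE for r in records),
        records=tuple(records),
    )
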