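"""Construct report stores that encode known marginal counts.

Useful for turning published summary-table counts (totals, subgroup sizes,
event counts) into a concrete store on which the summary operations can be
re-run, and for building large degenerate stores quickly in tests.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reports import PRIMARY_SUSPECT, DrugEntry, ReportStore, normalize_terms


def replicated_store(
    blocks: Iterable[tuple[int, Mapping]], deduplicated: bool = True
) -> ReportStore:
    """Build a store from (count, row-spec) blocks.

    Each block contributes ``count`` identical reports (distinct ids).  The
    row spec accepts ``drug`` (primary-suspect canonical name), ``role``,
    ``events``, ``indications``, ``sex``, ``age_years``, ``country``,
    ``year`` and ``outcomes``; omitted fields default to unknown/empty.
    """
    frames = []
    next_id = 1
    for count, spec in blocks:
        if count <= 0:
            continue
        drug = spec.get("drug", "drug")
        drugs = (DrugEntry(drug, drug, spec.get("role", PRIMARY_SUSPECT)),)
        events = normalize_terms(spec.get("events", ()))
        indications = normalize_terms(spec.get("indications", ()))
        outcomes = frozenset(spec.get("outcomes", ()))
        ids = np.arange(next_id, next_id + count)
        next_id += count
        frames.append(
            pd.DataFrame(
                {
                    "isr_id": ids,
                    "case_id": ids,
                    "version": np.ones(count, dtype=int),
                    "drugs": [drugs] * count,
                    "events": [events] * count,
                    "indications": [indications] * count,
                    "sex": spec.get("sex", "unknown"),
                    "age_years": float(spec.get("age_years", np.nan)),
                    "country": spec.get("country", None),
                    "year": int(spec.get("year", 2020)),
                    "outcomes": [outcomes] * count,
                }
            )
        )
    frame = pd.concat(frames, ignore_index=True)
    return ReportStore(frame, deduplicated=deduplicated)
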