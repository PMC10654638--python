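"""Synthetic spontaneous-report generator with known ground truth.

Report stores are drawn from a fully specified generative model: each report
gets one primary-suspect drug from a categorical share vector (a catch-all
``background`` pseudo-drug absorbs the remaining share so the comparator
margin is well populated), events are independent Bernoulli draws whose
probability is raised for planted drug–event pairs to hit a target reporting
odds ratio, and duplicates are re-emitted copies of existing cases with an
incremented version.  Every quantity a downstream test needs is recorded in
a :class:`GroundTruthLedger`.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import compress
from typing import Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigError
from .reports import PRIMARY_SUSPECT, DrugEntry, ReportStore, normalize_term
from .stats import ContingencyTable

BACKGROUND_DRUG = "background"


def planted_event_prob(target_ror: float, p0: float) -> float:
    """Drug-arm event probability whose odds are target_ror × odds(p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if target_ror <= 0:
        raise ValueError("target_ror must be positive")
    return target_ror * p0 / (1 - p0 + target_ror * p0)


class PlantedAssociation(BaseModel):
    """One drug–event pair with a target reporting odds ratio."""

    drug: str
    event: str
    target_ror: float = Field(gt=0)
    background_event_prob: float = Field(gt=0, lt=1)

    @model_validator(mode="after")
    def _normalize(self):
        self.drug = normalize_term(self.drug)
        self.event = normalize_term(self.event)
        return self


class AgeModel(BaseModel):
    mean: float = 68.0
    sd: float = 12.0
    unknown_prob: float = Field(default=0.0, ge=0, le=1)


class SimulationConfig(BaseModel):
    """Full generative specification for a synthetic report store.

    ``drug_shares`` may sum to less than 1; the remainder is assigned to the
    ``background`` pseudo-drug.  ``indication_vocab`` maps drug → term →
    per-report probability.  ``duplicate_rate`` is the fraction of the
    ``n_reports`` total that are re-emitted copies of earlier cases.
    """

    n_reports: int = Field(gt=0)
    drug_shares: dict[str, float]
    event_vocab: dict[str, float] = Field(default_factory=dict)
    indication_vocab: dict[str, dict[str, float]] = Field(default_factory=dict)
    planted: list[PlantedAssociation] = Field(default_factory=list)
    duplicate_rate: float = Field(default=0.0, ge=0, lt=1)
    sex_dist: dict[str, float] = Field(
        default_factory=lambda: {"female": 0.7, "male": 0.2, "unknown": 0.1}
    )
    age: AgeModel = Field(default_factory=AgeModel)
    country_dist: dict[str, float] = Field(
        default_factory=lambda: {"us": 0.7, "canada": 0.05, "other": 0.25}
    )
    year_weights: dict[int, float] = Field(default_factory=lambda: {2020: 1.0})
    outcome_probs: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self):
        self.drug_shares = {normalize_term(k): v for k, v in self.drug_shares.items()}
        self.event_vocab = {normalize_term(k): v for k, v in self.event_vocab.items()}
        self.indication_vocab = {
            normalize_term(d): {normalize_term(t): p for t, p in terms.items()}
            for d, terms in self.indication_vocab.items()
        }
        total = sum(self.drug_shares.values())
        if any(v < 0 for v in self.drug_shares.values()) or total > 1 + 1e-12:
            raise ConfigError("drug_shares must be non-negative and sum to at most 1")
        for vocab in (self.event_vocab, *self.indication_vocab.values()):
            if any(not 0 <= p <= 1 for p in vocab.values()):
                raise ConfigError("all vocabulary probabilities must lie in [0, 1]")
        for pa in self.planted:
            if pa.drug not in self.drug_shares:
                raise ConfigError(f"planted drug {pa.drug!r} has no share")
            p1 = planted_event_prob(pa.target_ror, pa.background_event_prob)
            if not p1 < 1:
                raise ConfigError(f"planted pair {pa.drug}/{pa.event} is infeasible")
        if any(not 0 <= p <= 1 for p in self.outcome_probs.values()):
            raise ConfigError("outcome probabilities must lie in [0, 1]")
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def n_duplicates(self) -> int:
        return int(round(self.duplicate_rate * self.n_reports))

    @property
    def n_cases(self) -> int:
        return self.n_reports - self.n_duplicates

    def drug_names(self) -> list[str]:
        names = list(self.drug_shares)
        if sum(self.drug_shares.values()) < 1 - 1e-12:
            names.append(BACKGROUND_DRUG)
        return names

    def share(self, drug: str) -> float:
        if drug == BACKGROUND_DRUG and drug not in self.drug_shares:
            return 1.0 - sum(self.drug_shares.values())
        return self.drug_shares[drug]

    def event_terms(self) -> list[str]:
        terms = dict.fromkeys(self.event_vocab)
        terms.update(dict.fromkeys(pa.event for pa in self.planted))
        return list(terms)

    def event_prob(self, drug: str, event: str) -> float:
        """P(event on a report | index drug), honouring planted pairs."""
        fallback = None
        for pa in self.planted:
            if pa.event == event:
                if pa.drug == drug:
                    return planted_event_prob(pa.target_ror, pa.background_event_prob)
                fallback = pa.background_event_prob
        if fallback is not None:
            return fallback
        return self.event_vocab.get(event, 0.0)


@dataclass(frozen=True)
class PlantedTruth:
    target_ror: float
    cell_probs: tuple[float, float, float, float]  # (DE, De, dE, de) per report


@dataclass(frozen=True)
class GroundTruthLedger:
    """Generator-side bookkeeping for downstream verification."""

    n_cases: int
    drug_case_counts: Mapping[str, int]
    planted: Mapping[tuple[str, str], PlantedTruth]
    duplicate_of: Mapping[int, int]  # duplicate isr_id -> original isr_id


def expected_table(
    config: SimulationConfig, drug: str, event: str
) -> ContingencyTable:
    """Expectation of each 2×2 cell under the generative model (real-valued).

    Cell probabilities are scaled by the post-deduplication case count.
    """
    drug = normalize_term(drug)
    event = normalize_term(event)
    names = config.drug_names()
    if drug not in names:
        raise ConfigError(f"{drug!r} is not a drug in this configuration")
    if event not in config.event_terms():
        raise ConfigError(f"{event!r} is not an event in this configuration")
    n = config.n_cases
    share_d = config.share(drug)
    p1 = config.event_prob(drug, event)
    DE = n * share_d * p1
    De = n * share_d * (1 - p1)
    dE = n * sum(
        config.share(o) * config.event_prob(o, event) for o in names if o != drug
    )
    de = n * (1 - share_d) - dE
    return ContingencyTable(DE, De, dE, de, real_valued=True)


def _draw_multivalued(
    rng: np.random.Generator,
    n: int,
    terms: list[str],
    probs: np.ndarray,
) -> list[frozenset[str]]:
    """One frozenset per row; probs has shape (n, len(terms))."""
    if not terms:
        return [frozenset()] * n
    hits = rng.random((n, len(terms))) < probs
    return [frozenset(compress(terms, row)) for row in hits]


def generate_reports(
    config: SimulationConfig,
) -> tuple[ReportStore, GroundTruthLedger]:
    """Draw a synthetic store and its ground-truth ledger.

    Deterministic for a fixed config (seed included); random streams are
    split per component so vocabulary changes do not perturb unrelated
    draws.
    """
    seq = np.random.SeedSequence(config.seed)
    rng_drugs, rng_events, rng_inds, rng_demo, rng_dups = (
        np.random.default_rng(s) for s in seq.spawn(5)
    )
    n = config.n_cases
    names = config.drug_names()
    shares = np.array([config.share(d) for d in names], dtype=float)
    shares = shares / shares.sum()
    drug_idx = rng_drugs.choice(len(names), size=n, p=shares)

    # one primary-suspect DrugEntry tuple per drug, shared across rows
    entry_for = np.empty(len(names), dtype=object)
    for i, name in enumerate(names):
        entry_for[i] = (DrugEntry(name, name, PRIMARY_SUSPECT),)
    drugs_col = entry_for[drug_idx]

    # events: per-term probability vector depends on the index drug
    terms = config.event_terms()
    prob_by_drug = np.array(
        [[config.event_prob(d, t) for t in terms] for d in names]
    )
    events_col = _draw_multivalued(rng_events, n, terms, prob_by_drug[drug_idx])

    # indications: per-drug vocabularies
    ind_terms = sorted({t for v in config.indication_vocab.values() for t in v})
    ind_prob_by_drug = np.array(
        [
            [config.indication_vocab.get(d, {}).get(t, 0.0) for t in ind_terms]
            for d in names
        ]
    )
    inds_col = _draw_multivalued(rng_inds, n, ind_terms, ind_prob_by_drug[drug_idx])

    # demographics
    sex_cats = list(config.sex_dist)
    sex_p = np.array(list(config.sex_dist.values()), dtype=float)
    sex_col = np.array(sex_cats, dtype=object)[
        rng_demo.choice(len(sex_cats), size=n, p=sex_p / sex_p.sum())
    ]
    ages = np.clip(rng_demo.normal(config.age.mean, config.age.sd, size=n), 0, None)
    ages = np.round(ages)
    if config.age.unknown_prob > 0:
        ages[rng_demo.random(n) < config.age.unknown_prob] = np.nan
    countries = list(config.country_dist)
    c_p = np.array(list(config.country_dist.values()), dtype=float)
    country_col = np.array(countries, dtype=object)[
        rng_demo.choice(len(countries), size=n, p=c_p / c_p.sum())
    ]
    years = np.array(list(config.year_weights), dtype=int)
    y_p = np.array(list(config.year_weights.values()), dtype=float)
    year_col = years[rng_demo.choice(len(years), size=n, p=y_p / y_p.sum())]
    outcome_cats = list(config.outcome_probs)
    outcome_p = np.array(
        [config.outcome_probs[c] for c in outcome_cats], dtype=float
    )
    outcomes_col = _draw_multivalued(
        rng_demo, n, outcome_cats, np.broadcast_to(outcome_p, (n, len(outcome_cats)))
    )

    frame = pd.DataFrame(
        {
            "isr_id": np.arange(1, n + 1),
            "case_id": np.arange(1, n + 1),
            "version": np.ones(n, dtype=int),
            "drugs": drugs_col,
            "events": events_col,
            "indications": inds_col,
            "sex": sex_col,
            "age_years": ages,
            "country": country_col,
            "year": year_col,
            "outcomes": outcomes_col,
        }
    )

    # duplicates: re-emit existing cases with incremented versions; multiple
    # duplicates of one case get successive versions
    n_dup = config.n_duplicates
    duplicate_of: dict[int, int] = {}
    if n_dup:
        dup_idx = rng_dups.choice(n, size=n_dup, replace=n_dup > n)
        dup_frame = frame.iloc[dup_idx].copy()
        dup_frame["isr_id"] = np.arange(n + 1, n + n_dup + 1)
        bump = pd.Series(dup_idx).groupby(dup_idx).cumcount().to_numpy()
        dup_frame["version"] = dup_frame["version"].to_numpy() + 1 + bump
        duplicate_of = dict(
            zip(dup_frame["isr_id"].tolist(), (dup_idx + 1).tolist())
        )
        frame = pd.concat([frame, dup_frame], ignore_index=True)

    store = ReportStore(frame)

    counts = np.bincount(drug_idx, minlength=len(names))
    planted_truth = {}
    for pa in config.planted:
        t = expected_table(config, pa.drug, pa.event)
        planted_truth[(pa.drug, pa.event)] = PlantedTruth(
            target_ror=pa.target_ror,
            cell_probs=(t.DE / t.N, t.De / t.N, t.dE / t.N, t.de / t.N),
        )
    ledger = GroundTruthLedger(
        n_cases=n,
        drug_case_counts={d: int(c) for d, c in zip(names, counts)},
        planted=planted_truth,
        duplicate_of=duplicate_of,
    )
    return store, ledger
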