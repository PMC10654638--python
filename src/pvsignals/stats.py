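"""Disproportionality statistics for drug–event pairs.

Implements the 2×2 contingency machinery used in spontaneous-report signal
detection: reporting odds ratio (ROR) with Wald 95% CI, proportional
reporting ratio (PRR), the Yates-continuity-corrected chi-squared, the
composite significance criteria, ranked signal detection over a report
store, and a numerical "reconstruction oracle" that back-solves a full
table from published (DE, D, ROR, χ²) summaries.

Statistics on degenerate tables (zero cells/margins) are returned as
non-evaluable results carrying a reason code rather than raised.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .errors import LexiconError, UnsolvableError
from .reports import (
    DrugLexicon,
    ReportStore,
    normalize_term,
    require_deduplicated,
)

Z_95 = 1.96


@dataclass(frozen=True)
class ContingencyTable:
    """Cells of the exposure-by-event 2×2 table.

    ``DE``: index drug and event; ``De``: index drug, no event;
    ``dE``: other reports with event; ``de``: other reports without event.
    Cells are integer counts in normal operation; reconstruction produces
    real-valued cells flagged with ``real_valued``.
    """

    DE: float
    De: float
    dE: float
    de: float
    real_valued: bool = False

    def __post_init__(self):
        for name in ("DE", "De", "dE", "de"):
            v = getattr(self, name)
            if v < 0 or math.isnan(v):
                raise ValueError(f"cell {name} must be non-negative, got {v}")

    @property
    def D(self) -> float:
        return self.DE + self.De

    @property
    def d(self) -> float:
        return self.dE + self.de

    @property
    def E(self) -> float:
        return self.DE + self.dE

    @property
    def e(self) -> float:
        return self.De + self.de

    @property
    def N(self) -> float:
        return self.DE + self.De + self.dE + self.de

    def transpose(self) -> "ContingencyTable":
        return replace(self, dE=self.De, De=self.dE)

    def swap_columns(self) -> "ContingencyTable":
        return replace(self, DE=self.dE, dE=self.DE, De=self.de, de=self.De)


@dataclass(frozen=True)
class RorResult:
    """ROR point estimate with Wald CI; ``reason`` set when non-evaluable."""

    ror: float
    ci_low: float
    ci_high: float
    reason: str | None = None

    @property
    def evaluable(self) -> bool:
        return self.reason is None


_NON_EVALUABLE_ROR = RorResult(math.nan, math.nan, math.nan, "zero cell")


def compute_ror(table: ContingencyTable, z: float = Z_95) -> RorResult:
    """Reporting odds ratio (DE·de)/(De·dE) with log-scale Wald CI.

    Non-evaluable (reason code, no exception) when any denominator cell
    would be zero.
    """
    if min(table.DE, table.De, table.dE, table.de) <= 0:
        zero = [
            n for n in ("DE", "De", "dE", "de") if getattr(table, n) <= 0
        ]
        return RorResult(math.nan, math.nan, math.nan, f"zero cell: {','.join(zero)}")
    ror = (table.DE * table.de) / (table.De * table.dE)
    se = math.sqrt(1 / table.DE + 1 / table.De + 1 / table.dE + 1 / table.de)
    return RorResult(ror, ror * math.exp(-z * se), ror * math.exp(z * se))


@dataclass(frozen=True)
class PrrResult:
    prr: float
    reason: str | None = None

    @property
    def evaluable(self) -> bool:
        return self.reason is None


def compute_prr(table: ContingencyTable) -> PrrResult:
    """Proportional reporting ratio (DE/D)/(dE/d)."""
    if table.D <= 0 or table.d <= 0:
        return PrrResult(math.nan, "zero margin")
    if table.dE <= 0:
        return PrrResult(math.nan, "zero dE cell")
    return PrrResult((table.DE / table.D) / (table.dE / table.d))


@dataclass(frozen=True)
class Chi2Result:
    chi2: float
    reason: str | None = None

    @property
    def evaluable(self) -> bool:
        return self.reason is None


def compute_chi2_yates(table: ContingencyTable) -> Chi2Result:
    """Yates-corrected chi-squared N·(|DE·de − dE·De| − N/2)²/(D·d·E·e).

    The continuity term is clamped: below-independence fluctuation smaller
    than N/2 yields exactly 0 (the literal formula would be positive at
    exact independence).
    """
    D, d, E, e, N = table.D, table.d, table.E, table.e, table.N
    if min(D, d, E, e) <= 0:
        return Chi2Result(math.nan, "zero margin")
    diff = abs(table.DE * table.de - table.dE * table.De)
    if diff < N / 2:
        return Chi2Result(0.0)
    return Chi2Result(N * (diff - N / 2) ** 2 / (D * d * E * e))


# ---------------------------------------------------------------------------
# Significance criteria


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds for a significant drug–event signal.

    Defaults use inclusive (≥) comparisons for DE/ROR/PRR/χ²; the CI lower
    bound is always a strict (>) comparison.  ``strict=True`` switches
    DE/ROR/PRR/χ² to strict (>) comparisons.
    """

    min_de: float = 3
    min_ror: float = 2.0
    min_ci_low: float = 1.0
    min_prr: float = 2.0
    min_chi2: float = 4.0
    z: float = Z_95
    strict: bool = False

    def __post_init__(self):
        for name in ("min_de", "min_ror", "min_ci_low", "min_prr", "min_chi2", "z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def _meets(self, value: float, threshold: float) -> bool:
        if math.isnan(value):
            return False
        return value > threshold if self.strict else value >= threshold


@dataclass(frozen=True)
class SignalStats:
    """Disproportionality summary for one drug–event pair."""

    drug: str
    event: str
    DE: int
    ror: float
    ci_low: float
    ci_high: float
    prr: float
    chi2: float
    significant: bool


def evaluate_signal(
    table: ContingencyTable,
    criteria: SignalCriteria = SignalCriteria(),
    drug: str = "",
    event: str = "",
) -> SignalStats:
    """Apply the composite criteria; non-evaluable statistics fail theirs."""
    ror = compute_ror(table, z=criteria.z)
    prr = compute_prr(table)
    chi2 = compute_chi2_yates(table)
    significant = (
        criteria._meets(table.DE, criteria.min_de)
        and ror.evaluable
        and criteria._meets(ror.ror, criteria.min_ror)
        and ror.ci_low > criteria.min_ci_low
        and prr.evaluable
        and criteria._meets(prr.prr, criteria.min_prr)
        and chi2.evaluable
        and criteria._meets(chi2.chi2, criteria.min_chi2)
    )
    return SignalStats(
        drug=drug,
        event=event,
        DE=int(table.DE) if not table.real_valued else table.DE,
        ror=ror.ror,
        ci_low=ror.ci_low,
        ci_high=ror.ci_high,
        prr=prr.prr,
        chi2=chi2.chi2,
        significant=significant,
    )


# ---------------------------------------------------------------------------
# Store-level operations


def build_table(
    store: ReportStore,
    drug: str,
    event: str,
    lexicon: DrugLexicon | None = None,
) -> ContingencyTable:
    """2×2 table for one drug–event pair over a deduplicated store.

    Exposure means the drug is in the primary-suspect role; the comparator
    margin is every other report in the store.
    """
    require_deduplicated(store, "build_table")
    if lexicon is not None and drug not in lexicon:
        raise LexiconError(f"{drug!r} is not a canonical name in the lexicon")
    event = normalize_term(event)
    ps = store.primary_suspect_mask(drug)
    has_event = store.frame["events"].map(lambda s: event in s).to_numpy()
    DE = int((ps & has_event).sum())
    De = int((ps & ~has_event).sum())
    dE = int((~ps & has_event).sum())
    de = len(store) - DE - De - dE
    return ContingencyTable(DE, De, dE, de)


def detect_signals(
    store: ReportStore,
    drug: str,
    criteria: SignalCriteria = SignalCriteria(),
    lexicon: DrugLexicon | None = None,
) -> list[SignalStats]:
    """Score every event reported at least once with the index drug.

    Returns one :class:`SignalStats` per distinct event term with DE ≥ 1,
    significant signals first sorted by DE descending (ties broken
    lexicographically by term), then the remainder in the same order.
    """
    require_deduplicated(store, "detect_signals")
    if lexicon is not None and drug not in lexicon:
        raise LexiconError(f"{drug!r} is not a canonical name in the lexicon")
    ps = store.primary_suspect_mask(drug)
    events_col = store.frame["events"]
    de_counts: Counter[str] = Counter()
    bg_counts: Counter[str] = Counter()
    for exposed, evs in zip(ps, events_col):
        (de_counts if exposed else bg_counts).update(evs)
    n_exposed = int(ps.sum())
    n_total = len(store)
    out = []
    for event, DE in de_counts.items():
        dE = bg_counts.get(event, 0)
        table = ContingencyTable(
            DE, n_exposed - DE, dE, n_total - n_exposed - dE
        )
        out.append(evaluate_signal(table, criteria, drug=drug, event=event))
    out.sort(key=lambda s: (not s.significant, -s.DE, s.event))
    return out


def significant_signals(signals: list[SignalStats]) -> list[SignalStats]:
    return [s for s in signals if s.significant]


# ---------------------------------------------------------------------------
# Reconstruction oracle
#
# Published summary rows print (DE, D, ROR, PRR, χ²) but not the background
# margin.  Because ROR and PRR share the single background odds ratio
# r = dE/de, the printed (DE, D, ROR) pin every ratio except the background
# scale s = de; χ² then determines s numerically.


def implied_prr(DE: float, D: float, ror: float) -> float:
    """The PRR uniquely implied by (DE, D, ROR).

    With r = (DE/De)/ROR the background odds, PRR = (DE/D)·(1+r)/r.
    """
    De = D - DE
    if not 0 < DE < D:
        raise ValueError("DE must satisfy 0 < DE < D")
    if ror <= 0:
        raise ValueError("ror must be positive")
    r = (DE / De) / ror
    return (DE / D) * (1 + r) / r


def chi2_asymptote(DE: float, D: float, ror: float) -> float:
    """Supremum of the Yates χ² over all backgrounds consistent with (DE, D, ROR)."""
    De = D - DE
    r = (DE / De) / ror
    return (abs(DE - r * De) - (1 + r) / 2) ** 2 / (D * r)


def reconstruct_table(
    DE: float, D: float, ror: float, chi2: float, rtol: float = 1e-9
) -> ContingencyTable:
    """Back-solve the full 2×2 table from (DE, D, ROR, Yates χ²).

    The background is parameterized as (dE, de) = (r·s, s); χ² is strictly
    increasing in s toward a finite asymptote, so s is found by bracketed
    root-finding.  Raises :class:`UnsolvableError` when ``chi2`` is at or
    beyond the asymptote.
    """
    De = D - DE
    if not 0 < DE < D:
        raise ValueError("DE must satisfy 0 < DE < D")
    r = (DE / De) / ror
    limit = chi2_asymptote(DE, D, ror)
    if chi2 >= limit:
        raise UnsolvableError(
            f"chi2 {chi2} is not attainable; asymptote is {limit}", asymptote=limit
        )

    def objective(s: float) -> float:
        res = compute_chi2_yates(
            ContingencyTable(DE, De, r * s, s, real_valued=True)
        )
        return res.chi2 - chi2

    lo, hi = 1e-9, 1e-6
    f_lo = objective(lo)
    f_hi = objective(hi)
    while f_lo * f_hi > 0:
        lo, f_lo = hi, f_hi
        hi *= 10.0
        if hi > 1e18:
            raise UnsolvableError("failed to bracket the chi2 root below 1e18")
        f_hi = objective(hi)
    s = brentq(objective, lo, hi, xtol=1e-12, rtol=8.882e-16, maxiter=200)
    table = ContingencyTable(DE, De, r * s, s, real_valued=True)
    achieved = compute_chi2_yates(table).chi2
    if not math.isclose(achieved, chi2, rel_tol=rtol):
        raise UnsolvableError(
            f"bisection did not converge: achieved {achieved}, wanted {chi2}"
        )
    return table
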