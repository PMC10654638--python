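"""Self-consistency verifier for bundled published summary rows.

Each bundled row prints (DE, ROR, CI lower bound, PRR, Yates χ²) for one
drug–event pair plus the drug's total report count.  Two independent checks
tie the statistics together without access to the original database:

* the PRR implied by (DE, D, ROR) through the shared background odds must
  match the printed PRR;
* the 95% CI lower bound of the table reconstructed from
  (DE, D, ROR, χ²) must match the printed bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .errors import UnsolvableError
from .stats import compute_ror, implied_prr, reconstruct_table

DEFAULT_PRR_TOL = 0.01  # absolute, matches the 3-decimal printing precision
DEFAULT_CI_RTOL = 0.002  # relative


@dataclass(frozen=True)
class RowCheck:
    drug: str
    event: str
    printed_prr: float
    implied_prr: float
    printed_ci_low: float
    reconstructed_ci_low: float | None
    passed: bool
    note: str = ""


def load_reference_rows(path=None) -> tuple[dict[str, int], list[dict]]:
    """Load (drug totals, rows) from a JSON file or the bundled dataset."""
    if path is None:
        text = (
            resources.files("pvsignals.data")
            .joinpath("reference_stats.json")
            .read_text(encoding="utf-8")
        )
        raw = json.loads(text)
    else:
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
    return raw["drug_totals"], raw["rows"]


def verify_reference_rows(
    path=None,
    prr_tol: float = DEFAULT_PRR_TOL,
    ci_rtol: float = DEFAULT_CI_RTOL,
) -> list[RowCheck]:
    """Run both consistency checks on every bundled row."""
    totals, rows = load_reference_rows(path)
    checks = []
    for row in rows:
        D = totals[row["drug"]]
        prr_hat = implied_prr(row["DE"], D, row["ror"])
        prr_ok = abs(prr_hat - row["prr"]) <= prr_tol
        note = ""
        try:
            table = reconstruct_table(row["DE"], D, row["ror"], row["chi2"])
            ci_hat = compute_ror(table).ci_low
            ci_ok = abs(ci_hat - row["ci_low"]) <= ci_rtol * row["ci_low"]
        except UnsolvableError as exc:
            ci_hat, ci_ok, note = None, False, str(exc)
        checks.append(
            RowCheck(
                drug=row["drug"],
                event=row["event"],
                printed_prr=row["prr"],
                implied_prr=prr_hat,
                printed_ci_low=row["ci_low"],
                reconstructed_ci_low=ci_hat,
                passed=prr_ok and ci_ok,
                note=note,
            )
        )
    return checks
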