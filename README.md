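# pvsignals

Disproportionality analysis for spontaneous adverse-event report databases
(FAERS-style), built as a reusable pipeline:

- **`pvsignals.reports`** — report data model, TSV reader/writer, drug-name
  normalization against a synonym lexicon, case-level deduplication
  (highest `(version, isr_id)` per case wins), and primary-suspect role
  filtering.
- **`pvsignals.simulate`** — a synthetic report generator with known ground
  truth: planted drug–event reporting odds ratios, injected duplicate case
  versions, demographic/yearly/outcome distributions, and a ledger of
  expected 2×2 cells, so every downstream stage is testable without any
  database download.
- **`pvsignals.stats`** — the statistics engine: 2×2 contingency tables,
  ROR with Wald 95% CI, PRR, Yates-corrected χ² (clamped at exact
  independence), composite significance criteria
  (DE ≥ 3, ROR ≥ 2, CI lower bound > 1, PRR ≥ 2, χ² ≥ 4; strict-mode flag
  switches ≥ to >), ranked signal detection, and a reconstruction oracle
  that back-solves a full table from published `(DE, D, ROR, χ²)` rows by
  bracketed bisection on the background size.
- **`pvsignals.compare`** — overlap of two drugs' significant-signal sets
  with direction and asymmetric ROR-difference tiers.
- **`pvsignals.offlabel`** — off-label indication mining by set difference
  against merged drug labels, and within-indication profiles of unlabeled
  adverse events with optional umbrella-term grouping.
- **`pvsignals.descriptives`** — demographic (sex/age/country), serious
  outcome, and yearly report summaries.

Bundled data (`src/pvsignals/data/`): a two-drug synonym lexicon and label
file for denosumab / zoledronic acid, an umbrella-term grouping example, and
a published-statistics reference file used by the self-consistency verifier.

## CLI

```sh
pvsignals simulate --config config.json --seed 7 --out reports.tsv --ledger-out ledger.json
pvsignals signals --reports reports.tsv --drug denosumab --out signals_a.tsv
pvsignals signals --reports reports.tsv --drug "zoledronic acid" --out signals_b.tsv
pvsignals compare --signals-a signals_a.tsv --signals-b signals_b.tsv --out overlap.tsv
pvsignals offlabel --reports reports.tsv --drug denosumab --label labels.json --out offlabel.tsv
pvsignals offlabel --reports reports.tsv --drug denosumab --label labels.json \
    --indication "breast cancer" --grouping groups.json --out profile.tsv
pvsignals describe --reports reports.tsv --drug denosumab --out-prefix desc
pvsignals verify-reference
```

Report TSV schema: one row per report; columns `isr_id, case_id, version,
drugs, events, indications, sex, age_years, country, year, outcomes`;
multi-valued fields are `;`-joined, drug entries are `name|role`, empty
string means unknown.

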