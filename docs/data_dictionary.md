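# Data dictionary

All tabular files are UTF-8 CSV: comma separator, dot decimal, ISO-8601
dates, flags serialised as `true`/`false` (on reading, `1/0/yes/no` are also
accepted). A JSON-lines alternative (`.jsonl`) with identical field names is
read for the five system exports. Money is written with exactly two decimals.
No file may contain identity fields; only pseudonyms and case ids appear.

## System exports

### ecrf.csv — clinical documentation (anchor system)

One row per documented eCRF data item.

| column | type | meaning |
|---|---|---|
| ecrf_pseudonym | string | eCRF-system pseudonym of the participant |
| centre_id | string | recruiting centre |
| visit_id | string | visit instance identifier |
| visit_type_id | string | visit type (must resolve in the catalogue for billing) |
| visit_date | date | ISO-8601 |
| form_id | string | sub-form the item belongs to |
| item_id | string | eCRF item identifier (input to the mapping table) |
| value | string | opaque documented value |
| submitted | flag | form page submitted by the centre |
| plausibility_pass | flag | automated plausibility/completeness check result |
| case_review_pass | flag | local case review result for the sub-form |
| consent_registered | flag | case-level consent flag, replicated per record |

Key: (`ecrf_pseudonym`, `visit_id`, `form_id`, `item_id`) must be unique.

### biosamples.csv

| column | type | meaning |
|---|---|---|
| bio_pseudonym | string | biosampling-system pseudonym |
| visit_id | string | visit the sample belongs to |
| sample_type | string | e.g. `edta-pbmc` (must match a bio rule to be billable) |
| aliquot_count | int ≥ 0 | registered aliquots |
| registered | flag | sample registered in the system |

### imaging.csv

| column | type | meaning |
|---|---|---|
| img_pseudonym | string | imaging-system pseudonym |
| visit_id | string | visit the series belongs to |
| modality | string | e.g. `echo` (must match an imaging rule to be billable) |
| series_count | int ≥ 0 | uploaded series |
| uploaded | flag | upload completed |

### centres.csv

| column | type | meaning |
|---|---|---|
| centre_id | string | unique centre identifier |
| display_letter | A–Z | pseudonymous letter, unique within a cohort |
| cohort | enum | `HAP`, `POP`, `SUEP` |
| centre_class | enum | `AMC`, `non-AMC` |
| target_cases | number ≥ 0 | recruitment target; fractional values allowed (e.g. 73.5) |

### linkage.csv — trusted-third-party style pseudonym linkage

| column | type | meaning |
|---|---|---|
| case_id | string | reimbursement case identifier |
| ecrf_pseudonym | string | required; the eCRF anchors the case |
| bio_pseudonym | string | optional |
| img_pseudonym | string | optional |

Each pseudonym may map to at most one case; each case appears once.

## Configuration files

### mapping.csv — eCRF item → reimbursement item

| column | meaning |
|---|---|
| ecrf_item_id | eCRF item identifier |
| reimbursement_item_id | catalogue item (must resolve) |
| condition | `always`, `value-present`, or `plausibility-pass` |
| reviewed | flag; review metadata per row |

Multiple rows per eCRF item are allowed (one activity can trigger several
fees).

### rules.yaml — eligibility, biosampling and imaging rules

```yaml
cohort: HAP
require_consent: true
require_case_review: false
required_forms:
  baseline: [baseline-form]
  discharge: [discharge-form]
bio_rules:
  - {sample_type: edta-pbmc, min_aliquots: 1, fee_item_id: pbmc}
img_rules:
  - {modality: echo, require_upload: true, fee_item_id: echocardiogram}
```

### Catalogue

Either a single JSON document (`schema_version`, `rates`, `items`, `visits`;
money as strings) or a CSV directory with `rates.csv`, `items.csv` (wide
per-role columns `sp_minutes`/`sp_cost_eur`, …), `visits.csv` (long format:
one row per item multiplicity) and `meta.csv` (`key`,`value`; carries
`schema_version`).

### announced.csv — optional, next to the exports

Announced visits for imputation and the follow-up schedule:
`case_id`, `visit_type_id`, `due_date` (ISO). Visits due on/after the
documentation freeze and not documented are imputed.

## Outputs of `pbrm calc`

- `statements.csv` — one row per statement line: `case_id`, `centre_id`,
  `cohort`, `visit_id`, `visit_type_id`, `item_id`, `count`,
  `unit_cost_eur`, `amount_eur`, `source` (`ecrf`/`bio`/`imaging`),
  `imputed`.
- `centre_summary.csv` — per centre: counts, totals, mean per case, source
  shares, FU fulfilment, initiation fee, grand total, target.
- `cohort_summary.csv` — per cohort: exact sums over centres.
- `run_ledger.json` — run id, SHA-256 input digests, catalogue version,
  timestamp, iteration counter.
- `coordination_*.{csv,md}` — coordination-scope reports; `pbrm report`
  regenerates centre-scope views byte-identically from the same run.
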