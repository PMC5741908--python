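# File formats

All tabular files are UTF-8 CSV with a header row; all timestamps are
ISO-8601 **with an explicit UTC offset** (comparisons happen in UTC).
Only empty cells are treated as missing when files are read back (the
sodium code `NA` is a value, not a missing marker).

## Rule config (YAML or JSON)

Top-level keys: `analytes`, `code_maps`, `normality_ranges`, `rules`.

```yaml
analytes:
  - canonical_id: NA            # unique short token
    display_name: Sodium
    local_codes: {SAP: NA-S, GALILEO: "0401"}   # per requesting system

code_maps:                      # optional extra (system -> local -> canonical)
  SAP: {SODIUM: NA}

normality_ranges:
  - analyte: NA
    sex: ANY                    # F | M | ANY; exact sex beats ANY at lookup
    age_min_years: 18           # inclusive
    age_max_years: null         # exclusive; null = unbounded
    lower: 135.0
    upper: 145.0
    units: mmol/L

rules:
  - rule_id: R_NA_24H
    analyte: NA
    min_interval: 24h           # "24h" | "3d" | "6mo"; 1mo = 30d = 720h
    prior_criteria: TIME_AND_QUANT   # TIME_ONLY (default) | TIME_AND_QUANT
    incompatible_with: []       # analytes blocked within the same order
    priority_scope: ROUTINE     # ROUTINE | URGENT | ANY
    ward_groups: []             # empty = all wards
    outcome: WARN_WITH_MOTIVATION    # BLOCK | WARN_WITH_MOTIVATION
    sample_type: serum          # token or ANY
    reporting_comment: Sodium already executed in the latest 24 h
```

Validation is aggregate: loading reports every violation (unresolved
references, duplicate ids, inverted or overlapping normality ranges,
self-incompatibility, empty comments), not just the first.

## Patients CSV

`patient_id, sex (F|M), birth_date (YYYY-MM-DD)` — synthetic cohorts add
`age, ward, group`.

## Results CSV

`patient_id, analyte, collected_at, value, units, executed` — `value`
may be empty for non-numeric tests; `executed` boolean.

## Orders CSV (request level)

One row per requested test:
`order_id, patient_id, ward_group, requesting_system, ordered_at,
analyte, priority (ROUTINE|URGENT), sample_type` — rows sharing an
`order_id` form one order. `analyte` may be a canonical id or a local
code of the requesting system.

## Resolutions CSV

`order_id, alert_id, action (CANCELLED|OVERRIDDEN), motivation_code,
free_text` — `motivation_code` one of SPECIALIST_REQUEST,
CLINICAL_EVIDENCE, LAB_DATA_CONFIRMATION, OTHER (OTHER requires
`free_text`).

## Ward/period summaries CSV

`ward, group (INTERVENTION|CONTROL), period (PRE|POST), n_tests,
total_cost` — each ward exactly once per period.

## Audit log (JSON lines)

One screening event per line:

```json
{"timestamp": "...", "requesting_system": "SAP", "order_id": "O1",
 "n_requests": 2,
 "alerts": [{"alert_id": "O1:A1", "rule_id": "R_NA_24H", "analyte": "NA",
             "kind": "WARN_WITH_MOTIVATION", "reason": "TOO_SOON",
             "comment": "...", "elapsed_hours": 10.0,
             "prior_in_normal_range": true,
             "prior_result_ref": {...}, "prior_report": {...}}],
 "resolutions": [{"alert_id": "O1:A1", "action": "OVERRIDDEN",
                  "motivation": {"code": "SPECIALIST_REQUEST"}}],
 "unmapped_codes": []}
```

## Likert survey CSV

One row per respondent, one column per item, integer scores 1–5, empty
cells allowed (listwise deletion applies for Cronbach's alpha).
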