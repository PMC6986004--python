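# Registry file schemas

All registry files are UTF-8, comma-separated, with a mandatory header
row.  Dates are ISO 8601 (`YYYY-MM-DD`); optional date cells are left
empty.  Multi-valued cells are semicolon-delimited within the cell.
`read_registry` enforces these schemas and rejects rows violating type
invariants with 1-based row numbers (header = row 1).

## demographics.csv

| column | type | notes |
|---|---|---|
| person_id | string | linkage key, identical across registries |
| sex | `male` / `female` | |
| birth_date | date | |
| death_date | date, optional | must be ≥ birth_date |
| residence_intervals | list | `start/end` pairs joined by `;`, empty `end` = still open; half-open `[start, end)`; sorted, non-overlapping |

Example cell: `2000-01-01/2016-05-01;2017-02-01/`

## hdr.csv — hospital discharge abstracts

| column | type | notes |
|---|---|---|
| person_id | string | |
| admission_date | date | ≤ discharge_date |
| discharge_date | date | window membership uses this date |
| diagnoses | 1–6 ICD-9-CM codes, `;`-joined | first = primary |
| procedures | 0–6 ICD-9-CM procedure codes, `;`-joined | |
| service_codes | 0+ regional complex-package codes, `;`-joined | P583 family |

## ter.csv — ticket exemptions

| column | type | notes |
|---|---|---|
| person_id | string | |
| code | exemption code | e.g. `025.585` |
| start_date | date | |
| end_date | date, optional | empty = still active |

## ossis.csv — outpatient specialist services

| column | type | notes |
|---|---|---|
| person_id | string | |
| service_date | date | |
| service_code | regional service code | e.g. `89.7`, `90.33.4`, `39.95.1` |
| branch | specialty branch, optional | nephrology = `29`; empty = unknown |

## pharm.csv — drug dispensings

| column | type | notes |
|---|---|---|
| person_id | string | |
| dispensing_date | date | |
| atc | ATC code | validated against the ATC level grammar |

## ldr.csv — dialysis registry (gold standard)

| column | type | notes |
|---|---|---|
| person_id | string | |
| start_date | date | start of chronic dialysis |
| modality | `hemodialysis` / `peritoneal` | |

## ground_truth.csv (synthetic runs only)

`person_id, is_case (0/1), severity (higher/lower/empty), on_dialysis
(0/1), excluded_reason (death/emigration/empty)`

## Reference population file (direct standardization)

`age_class, sex, weight` — one row per stratum; weights are counts or
proportions, normalized internally within the margin being
standardized.
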