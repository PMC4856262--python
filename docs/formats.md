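# Table formats

All tables are UTF-8, comma-delimited CSV with a mandatory header row and
ISO-8601 (`YYYY-MM-DD`) dates.  Every interval computed from them is
half-open `[start, end)` at day resolution.

## patients.csv

| column          | type            | notes                                   |
|-----------------|-----------------|-----------------------------------------|
| patient_id      | string          | unique within the dataset               |
| sex             | `male\|female`  |                                         |
| birth_date      | date            |                                         |
| death_date      | date or empty   | empty = alive at last follow-up         |
| last_seen_date  | date            | last recorded activity                  |
| diabetes        | 0/1             | disease-registry membership             |
| hypertension    | 0/1             |                                         |
| cvd             | 0/1             | cardiovascular disease registry         |

Row invariants: `death_date >= birth_date` (when present),
`last_seen_date >= birth_date`.  Violating rows are rejected individually
with a line-numbered diagnostic; the rest of the file still loads.

## dispenses.csv — pharmacy purchases

`patient_id, date, drug_code` — one row per dispense.  `drug_code` is
resolved through the drug dictionary; unmapped codes are retained but
ignored by the exposure builder.

## infusions.csv — hospital infusion claims

`patient_id, date, agent_code` — one row per administration.

## surgeries.csv

`patient_id, date, procedure` with `procedure` one of
`liver_metastasectomy`, `lung_metastasectomy`, `definitive_rt`, `other`.
Only the first three qualify a patient for the Surgery group.

## labs.csv

`patient_id, date, test, value` with `test` one of `platelets`,
`leukocytes`, `cholesterol`, `ldl`, `urine_protein`, `cea`; `value` is a
finite decimal in test-specific units.

## drug_dict.csv

`drug_code, agent_class, category`.  `agent_class` is one of `FP_oral`,
`FP_iv`, `oxaliplatin`, `irinotecan`, `bevacizumab`, `cetuximab`,
`panitumumab`, `non_oncology`.  `category` is meaningful for
`non_oncology` codes only: `narcotic`, `corticosteroid`, `diuretic`,
`gi_ppi`, `antiemetic`, or `other`.  Duplicate codes with identical
mappings collapse to one entry; conflicting duplicates are an error.
A synthetic editable default ships at `carelines/data/drug_dict.csv`;
real deployments supply their own mapping (e.g. derived from ATC/RxNorm).

## Pipeline outputs

`lines.csv` (from `carelines segment`): `patient_id, line_number, start,
end, backbone, biologics` (semicolon-joined), `resumption`, `states_json`.

`cohort.csv` (from `carelines cohort`): one row per eligible patient with
`os_months, os_event, dot_months, dot_event, group, first_line_backbone,
age, sex, max_line_number, received_both_aggressive,
anti_egfr_after_index, med_<category>` flags and `lab_<test>` baselines.
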