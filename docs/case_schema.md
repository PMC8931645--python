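# Case-definition file format

A case is one UTF-8 JSON document holding the simulation author's
answer key. Example (minimal but complete):

```json
{
  "case_id": "cholecystitis-demo",
  "relevant_items": {
    "s": ["df_ruq_pain", "df_fever"],
    "a": ["q_onset", "q_fatty_meal", "q_nausea"],
    "p": ["palpation_ruq", "murphy_sign"],
    "m": ["abdominal_ultrasound"]
  },
  "factors": [
    {"id": "df_ruq_pain", "label": "right upper quadrant pain", "source_section": "s"},
    {"id": "df_fever", "label": "fever 38 C", "source_section": "s"}
  ],
  "hypotheses": [
    {"id": "dx_cholecystitis", "label": "acute cholecystitis", "is_correct_final": true},
    {"id": "dx_ulcer", "label": "peptic ulcer", "is_correct_final": false}
  ],
  "binary_reference": [
    {"factor_id": "df_ruq_pain", "hypothesis_id": "dx_cholecystitis", "anchor": "increase"},
    {"factor_id": "df_ruq_pain", "hypothesis_id": "dx_ulcer", "anchor": "neutral"},
    {"factor_id": "df_fever", "hypothesis_id": "dx_cholecystitis", "anchor": "increase"},
    {"factor_id": "df_fever", "hypothesis_id": "dx_ulcer", "anchor": "decrease"}
  ],
  "critical_acts": [
    {"act_id": "S", "description": "read the scenario",
     "bound_action": {"section": "s", "item_id": "df_ruq_pain"}},
    {"act_id": "P", "description": "palpate the abdomen",
     "bound_action": {"section": "p", "item_id": "palpation_ruq"}},
    {"act_id": "M", "description": "check the Murphy sign",
     "bound_action": {"section": "p", "item_id": "murphy_sign"}},
    {"act_id": "U", "description": "request the abdominal ultrasound",
     "bound_action": {"section": "m", "item_id": "abdominal_ultrasound"}},
    {"act_id": "D", "description": "select the correct diagnosis",
     "bound_action": {"section": "r", "item_id": "dx_cholecystitis"}}
  ],
  "desired_path": "SPMUD"
}
```

## Fields and invariants

- `relevant_items` — explicit relevant-item lists, keyed by the four
  data-gathering section codes `s` (scenario), `a` (anamnesis), `p`
  (physical examination), `m` (medical tests). Lists may be empty; a
  section with an empty reference set is *not assessable* and is
  excluded from composite averages. Item ids must be unique per
  section and must not contain `::`.
- `factors` / `hypotheses` — diagnostic factors and hypotheses with
  unique ids. Every declared hypothesis is by definition a
  "reasonable" hypothesis (the reference set of section `h`); at least
  one must have `is_correct_final: true` (the reference set of section
  `r`).
- `binary_reference` — exactly one entry per (factor, hypothesis)
  pair; `anchor` is one of `increase`, `neutral`, `decrease`. The
  reference set of section `b` is the set of pair ids
  `"<factor_id>::<hypothesis_id>"`.
- `critical_acts` — key actions labelled by a single unique uppercase
  character, each bound to a concrete `(section, item_id)` that must
  be a relevant item of that section.
- `desired_path` — a string of declared act ids, each at most once:
  the expected execution order.

## Action-log file format

One student's log is line-delimited JSON: a header line followed by
one record per line, in execution order.

```
{"student_id": "student-007", "case_id": "cholecystitis-demo"}
{"seq": 1, "section": "s", "item_id": "df_ruq_pain", "relevant": true, "attempt": 1, "payload": null}
{"seq": 2, "section": "b", "item_id": "df_fever::dx_ulcer", "relevant": true, "attempt": 1, "payload": "decrease"}
```

- `seq` is strictly increasing; only order matters, no timestamps.
- `attempt` > 1 is permitted only in section `b` (anchor revisions);
  all metrics score attempt 1 only.
- For section `b`, `item_id` is the pair id and `payload` the anchor
  the student chose; for section `r`, `item_id` is the hypothesis
  selected as final diagnosis.
- `relevant` is a cache: when a case is supplied at read time the flag
  is recomputed from the case, which is authoritative, and
  disagreements trigger a warning.
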