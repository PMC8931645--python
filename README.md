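# vpslearn

Learning analytics for **virtual-patient simulator (VPS) logs**, aimed
at medical educators who want *remediable* insight into how students
work through a simulated clinical case — not just whether they got the
diagnosis.

A VPS records every action a learner takes across the seven phases of
an encounter: reading the input **s**cenario, **a**namnesis, **p**hysical
examination, **m**edical tests, **h**ypothesis generation, **b**inary
analysis (labelling each diagnostic-factor/hypothesis pair as
`increase` / `neutral` / `decrease`), and the final **r**esult. Given
the case author's answer key, `vpslearn` computes:

- **Section scores** — per section, sensitivity (fraction of relevant
  items covered), precision (fraction of the student's actions that
  were relevant), and their harmonic mean
  `F1 = 2·sens·prec/(sens+prec)` ∈ [0, 1].
- **Composite scores** — the overall score (mean of the seven F1
  values), the collection score (sections s, a, p, m) and the
  analytical score (h, b, r), plus class ranks.
- **Methodological score** — the action sequence is encoded as a
  section string with contiguous repeats collapsed (Φ; `sssaapp` →
  `sap`), and five workflow parameters are combined as a Euclidean
  norm `sqrt(p1²+…+p5²)` ∈ [0, √5]: prefix conformance to `sap`
  (Levenshtein similarity), suffix conformance to `br`,
  hypothesis-before-test ordering, section coverage, and a revisit
  penalty `1/(1+R)`.
- **Path analysis** — each student's critical-diagnostic-act sequence
  versus the author's desired execution path, with cohort path
  frequencies and flow-diagram exports.
- **Cohort analytics & validation** — class mean/SD, 0.05-bin score
  histograms, radar-chart data (student vs class-mean F1 per
  section), and Spearman rank correlation of each metric against an
  external exam score.
- **Synthetic cohorts** — a generator with interpretable skill
  parameters (thoroughness θ, noise λ, binary-analysis accuracy β,
  order-discipline δ) so the whole stack is testable and demo-able
  without real student data.

See `docs/methods.md` for the model and its assumptions, and
`docs/case_schema.md` for the case and log file formats.

## Worked example

Simulate a 25-student class and build the cohort report:

```bash
vpslearn simulate --students 25 --seed 7 --out demo
vpslearn cohort --case demo/case.json --logs demo/logs --out demo/report
```

which logs

```
INFO vpslearn: wrote case + 25 logs -> demo
INFO vpslearn: cohort of 25: mean overall 0.677 (SD 0.102) -> demo/report
```

`demo/report/summary.json` then reads

```json
{
  "case_id": "synthetic-case-7",
  "n_students": 25,
  "mean_overall": 0.6771570999130371,
  "sd_overall": 0.10215385253092131,
  "n_desired_path": 2
}
```

i.e. the class averaged 0.68 on the overall score (sample SD 0.10)
and only 2 of 25 students executed the critical diagnostic acts in
the author's desired order `SPMUD`. Per-student rows in
`students.csv` show how the same overall score can hide different
profiles — e.g.

```
student_id   overall  collection  analytical  methodological  phi       path
student-000  0.714    0.739       0.681       2.236           saphmbr   PUD
student-001  0.571    0.544       0.608       1.118           bmhasrpb  DMP
```

student-000 followed a perfectly linear workflow (Φ = `saphmbr`,
methodological score √5 ≈ 2.236, the maximum) while student-001
jumped straight into the binary analysis and tests before any
hypothesis (score 1.118), flagging a methodology problem independent
of content knowledge. `paths.csv`, `histogram.csv`, `radar.csv` and
`flows.csv` carry the cohort distributions and chart data;
`vpslearn validate --external exam.csv ...` adds the Spearman
validation table (rho, p, n per metric).

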