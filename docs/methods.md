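# Methods

## The measurement problem

A virtual-patient simulator logs every action a learner takes while
working through a clinical case: selecting text in the presenting
scenario, asking history questions, performing examinations, ordering
tests, formulating hypotheses, filling in the binary analysis
(labelling each diagnostic-factor/hypothesis pair as raising, lowering
or not changing the hypothesis's probability — a 3-anchor
script-concordance exercise), and committing to a final diagnosis.
Because the case author has declared in advance which actions are
correct, the log supports two orthogonal kinds of assessment:

1. **Content**: did the student find the relevant information and
   avoid superfluous actions? (section metrics → composite scores)
2. **Method**: did the student move through the encounter in a
   clinically sound order? (methodological score, path analysis)

## Section metrics

For each of the seven sections `s a p m h b r` we compute

- sensitivity `= |relevant items acted on| / |relevant items in case|`
- precision `= |relevant items acted on| / |distinct items acted on|`
- `F1 = 2·sens·prec / (sens + prec)`, defined as 0 when both are 0.

Counting is over **distinct** items: a question asked twice counts
once in both numerator and denominator. This reads the metric as
*coverage of the reference set*; penalizing repetition is the job of
the workflow score, and double-counting repeats would conflate the two
axes. Binary analysis is scored on **first attempts only**: the first
anchor the student commits for a pair either matches the reference or
does not; later revisions are recorded but never scored. The final
diagnosis section uses the same pattern with the correct final
diagnoses as reference set, so a single-answer case degenerates to 1/1
or 0/1.

Degenerate inputs are made total rather than fatal: a student with no
actions in a section gets precision 0 (an inactive section is
maximally penalized), and a section whose reference set is empty is
flagged *not assessable* and excluded from every composite average
(its sensitivity denominator is undefined; a well-authored case
populates all seven).

## Composite scores

The overall score is the arithmetic mean of the assessable sections'
F1 values; the collection score averages the four data-gathering
sections `s a p m` and the analytical score the three data-analysis
sections `h b r`. The source describes "combining" the seven values
without printing a rule; the unweighted mean is the natural choice
compatible with the 0–1 range, and a weight vector is exposed for
instructors who want to emphasize particular sections. With all seven
sections assessable, `7·overall = 4·collection + 3·analytical` holds
exactly. Ranks (1 = best) use competition ranking ("1224") so tied
students share the better rank.

## Methodological score

The log's section codes, concatenated in execution order and with runs
of contiguous identical characters collapsed, form the execution
string Φ (`sssaapp` → `sap`). Five bounded parameters are read off Φ:

| param | meaning | default-relevant choices |
|-------|---------|--------------------------|
| p1 | Levenshtein similarity of Φ's ≤3-char prefix to `sap` | short Φ compares whatever prefix exists, penalizing truncated workflows proportionally |
| p2 | similarity of Φ's ≤2-char suffix to `br` | likewise for the suffix |
| p3 | 1 iff first `h` precedes first `m` | no `m` in Φ → 1 (no violation occurred); `m` without any `h` → 0 |
| p4 | fraction of the 7 sections present in Φ | — |
| p5 | `1/(1+R)` with `R = |Φ| − |distinct(Φ)|` | R counts *revisits*: returns to a section already visited, the back-and-forth pattern the score penalizes; contiguous repeats are already collapsed |

and combined as the Euclidean norm `sqrt(Σ pᵢ²)` ∈ [0, √5], attained
exactly at a perfect linear workflow (Φ = `saphmbr`). The score is
reported raw, with `score/√5` available as a normalized companion
column. Levenshtein similarity is the standard normalized form
`1 − lev(x,y)/max(|x|,|y|)`, clamped to [0,1] with the both-empty case
defined as 1, so all five parameters live on the same scale. An empty
log yields the documented degenerate vector `(0, 0, 1, 0, 1)` and
score √2.

Φ is built from **all** logged actions by default: the worked
`sssaapp` example consists of ordinary scenario/history/exam actions,
not designated key acts. A `critical` mode restricted to
critical-act executions is available behind a flag
(`--phi-mode critical`), since the prose describing Φ is ambiguous on
this point; critical-act sequencing also has its own dedicated
analysis below.

## Path analysis

Each critical act is bound to a concrete (section, item) pair, so a
student's path is simply the act labels in order of first execution;
acts never executed are absent. A path "matches" only if it equals
the desired path exactly. Cohort aggregation yields the distinct
paths with counts and cohort fractions (flow-diagram data: `flows.csv`
exports width-proportional transition edges), and presence/absence
queries express questions such as "reached the diagnosis without any
physical examination" (`present="D", absent="PM"`). Human-readable
output rounds percentages half-up to integers (3/36 → 8%); machine
output keeps exact fractions.

## Cohort analytics and validation

The class report contains per-student composites, methodological
components and paths; the class mean and **sample** (n−1) standard
deviation of the overall score; a histogram of overall scores with 20
right-open bins of width 0.05 on [0,1] (the last bin closed so 1.0 is
counted); per-section class-mean F1 (the baseline ring of a radar
chart, with `radar_data` returning the student/class pairs per
section); and competition ranks per metric.

External validation uses the Spearman rank correlation between each
main metric (overall, collection, analytical, methodological) and an
external examination score. Ties receive average ranks; rho is the
Pearson correlation of the rank vectors; the two-sided p-value uses
the t approximation `t = rho·sqrt((n−2)/(1−rho²))` on n−2 degrees of
freedom, which is adequate for class sizes of a few dozen (an exact
permutation test would only matter below n ≈ 10). Students missing
either value are dropped pairwise and the paired n is reported. If
either variable is constant across the paired students, rho is
undefined and the result is flagged rather than fabricated.

## Synthetic cohorts

No real student logs can ship with the package, so the generator
simulates them from four interpretable parameters: thoroughness θ
(P(each relevant item is acted on); also drives binary-analysis
attempt coverage and the final-diagnosis choice), noise λ (Poisson
mean count of irrelevant actions per section, drawn from per-student
decoy pools), binary-analysis accuracy β (P(first-attempt anchor
correct); wrong answers are uniform over the two other anchors), and
discipline δ (P(sections emitted in the canonical order
`s a p h m b r` with no revisits); an undisciplined student shuffles
the section blocks and splits off k extra single-action revisit
bursts, k geometric with mean 2, placed so that they create genuine
revisits in Φ). By construction the expected section sensitivity is θ
and the expected first-attempt binary-analysis accuracy is β, which
the parameter-recovery tests verify to within 3 standard errors at
n = 200; discipline affects only the workflow parameters, letting
tests demonstrate that the methodological score is orthogonal to
content skill.

Defaults model a mid-ability class — θ = 0.7, λ = 2, β = 0.65,
δ = 0.5 — on a default case with 5/8/6/5 relevant items in the
gathering sections, 4 hypotheses (one correct) and a 3×4
binary-analysis matrix, with five critical acts forming the desired
path `SPMUD`. Cohort generation splits one global seed into
per-student streams, so a cohort is reproducible and students keep
their logs when the class grows.

What the simulator does *not* emulate: natural-language matching
errors between student phrasing and the author's question bank (logs
are assumed already resolved to item ids), item difficulty or
importance weighting, learning within a session, and time-on-task.
Passing tests therefore certify the *metrics pipeline*, not any claim
about real student populations.

## Problem sizes and numerical notes

The test suite uses cohorts of 10–200 students and the acceptance
checks use exhaustive edit-distance verification up to string length
3 (160,801 pairs) plus 4000 seeded random pairs up to length 7
against an independent alignment library; section metrics are
verified against a set-based recount on 500 random fixtures. All
randomness is seeded; scoring itself contains none. Floating-point
comparisons in tests use relative tolerance ~1e-6 and the Euclidean
norm identity is asserted to 1e-12.

## Known limitations

- The combination rule for composites and the repetition definition R
  are documented choices where the source description is silent or
  ambiguous; both are isolated behind small functions and a config
  hook.
- Competition ranking and half-up percent rounding are conventions,
  not derived requirements.
- The p-value of the Spearman test is approximate for very small n;
  below ~10 paired students an exact method should be preferred.
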