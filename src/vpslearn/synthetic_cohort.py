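"""Synthetic cases and student cohorts.

Real simulation logs are student data and cannot ship with the package,
so every metric is exercised against simulated students whose behavior
is controlled by four interpretable parameters:

``thoroughness`` (θ)
    Probability that each author-relevant item is acted on, per
    section; also the probability a binary-analysis pair is attempted
    and the probability the correct final diagnosis is chosen.
``noise`` (λ)
    Expected number of irrelevant actions per section, Poisson
    distributed, drawn from a per-section decoy pool.
``ba_accuracy`` (β)
    Probability an attempted binary-analysis pair gets the correct
    anchor on the first try; wrong answers pick uniformly among the
    other two anchors.
``discipline`` (δ)
    Probability the student works through the sections in the canonical
    order scenario → anamnesis → examination → hypotheses → tests →
    binary analysis → result with no revisits.  An undisciplined
    student shuffles the section blocks and additionally splits off
    ``k`` extra revisit bursts, ``k`` geometric with mean 2 — this
    degrades the workflow parameters (prefix/suffix conformance,
    hypothesis-before-test ordering, repetition penalty) independently
    of content skill.

Defaults model a mid-ability class: θ=0.7, λ=2, β=0.65, δ=0.5.  By
construction the expected section sensitivity equals θ and the expected
first-attempt binary-analysis accuracy equals β, which is what the
parameter-recovery tests check.  Generation is reproducible: one global
seed feeds a splittable per-student stream, so cohorts are identical
across runs and students keep their logs when the cohort grows.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .action_log import ActionLog, ActionRecord
from .case_model import (
    ANCHORS,
    CANONICAL_EXECUTION_ORDER,
    BinaryAnalysisEntry,
    BoundAction,
    CriticalActSpec,
    DiagnosticFactor,
    DiagnosticHypothesis,
    SimulationCase,
    pair_id,
)

DEFAULT_ITEMS_PER_SECTION: Dict[str, int] = {"s": 5, "a": 8, "p": 6, "m": 5}


@dataclass(frozen=True)
class StudentProfile:
    """Behavioral parameters of one simulated student."""

    thoroughness: float = 0.7
    noise: float = 2.0
    ba_accuracy: float = 0.65
    discipline: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("thoroughness", "ba_accuracy", "discipline"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise < 0:
            raise ValueError(f"noise={self.noise} must be non-negative")


def generate_case(
    n_items_per_section: Optional[Dict[str, int]] = None,
    n_hypotheses: int = 4,
    n_factors: int = 3,
    seed: int = 0,
    case_id: Optional[str] = None,
) -> SimulationCase:
    """Generate a fully populated, valid case.

    ``n_items_per_section`` gives the relevant-item counts for the four
    data-gathering sections (defaults: 5 scenario factors, 8 questions,
    6 examinations, 5 tests).  One hypothesis is the correct final
    diagnosis; the binary-analysis reference covers all
    ``n_factors x n_hypotheses`` pairs with random anchors.  Five
    critical acts (S, P, M, U, D) bound to concrete items define the
    desired path ``SPMUD`` when the section sizes allow, fewer acts
    otherwise.
    """
    counts = dict(DEFAULT_ITEMS_PER_SECTION)
    if n_items_per_section:
        counts.update(n_items_per_section)
    if min(counts.values()) < 1 or n_hypotheses < 1 or n_factors < 1:
        raise ValueError("all item counts must be >= 1")
    rng = np.random.default_rng(seed)

    relevant_items = {
        sec: [f"{sec}_item{i}" for i in range(counts[sec])] for sec in ("s", "a", "p", "m")
    }
    factors = [
        DiagnosticFactor(id=f"df{i}", label=f"diagnostic factor {i}", source_section="s")
        for i in range(n_factors)
    ]
    hypotheses = [
        DiagnosticHypothesis(
            id=f"dh{i}", label=f"hypothesis {i}", is_correct_final=(i == 0)
        )
        for i in range(n_hypotheses)
    ]
    binary_reference = [
        BinaryAnalysisEntry(
            factor_id=f.id,
            hypothesis_id=h.id,
            anchor=str(rng.choice(ANCHORS)),
        )
        for f in factors
        for h in hypotheses
    ]

    act_bindings: List[Tuple[str, str, str, str]] = [
        ("S", "read the input scenario", "s", relevant_items["s"][0]),
        ("P", "key physical examination", "p", relevant_items["p"][0]),
    ]
    if counts["p"] >= 2:
        act_bindings.append(("M", "confirmatory examination sign", "p", relevant_items["p"][1]))
    act_bindings.append(("U", "decisive medical test", "m", relevant_items["m"][0]))
    act_bindings.append(("D", "correct final diagnosis", "r", hypotheses[0].id))

    critical_acts = [
        CriticalActSpec(
            act_id=aid,
            description=desc,
            bound_action=BoundAction(section=sec, item_id=item),
        )
        for aid, desc, sec, item in act_bindings
    ]
    return SimulationCase(
        case_id=case_id or f"synthetic-case-{seed}",
        relevant_items=relevant_items,
        factors=factors,
        hypotheses=hypotheses,
        binary_reference=binary_reference,
        critical_acts=critical_acts,
        desired_path="".join(a.act_id for a in critical_acts),
    )


def _section_blocks(
    case: SimulationCase, profile: StudentProfile, rng: np.random.Generator
) -> List[Tuple[str, List[ActionRecord]]]:
    """One block of unsequenced records per section, canonical order."""
    theta, lam, beta = profile.thoroughness, profile.noise, profile.ba_accuracy
    correct_final = sorted(case.relevant_set("r"))
    wrong_final = sorted(h.id for h in case.hypotheses if not h.is_correct_final)
    blocks: List[Tuple[str, List[ActionRecord]]] = []
    for sec in CANONICAL_EXECUTION_ORDER:
        recs: List[ActionRecord] = []
        if sec in ("s", "a", "p", "m", "h"):
            hits = [it for it in sorted(case.relevant_set(sec)) if rng.random() < theta]
            decoys = [f"decoy_{sec}{i}" for i in range(rng.poisson(lam))]
            items = [(it, True) for it in hits] + [(it, False) for it in decoys]
            rng.shuffle(items)
            recs = [
                ActionRecord(seq=1, section=sec, item_id=it, relevant=rel)
                for it, rel in items
            ]
        elif sec == "b":
            for item in sorted(case.relevant_set("b")):
                if rng.random() >= theta:
                    continue
                ref = case.reference_anchor(item)
                if rng.random() < beta:
                    anchor = ref
                else:
                    anchor = str(rng.choice([a for a in ANCHORS if a != ref]))
                recs.append(
                    ActionRecord(
                        seq=1, section="b", item_id=item,
                        relevant=anchor == ref, payload=anchor,
                    )
                )
        else:  # final diagnosis: one choice
            if rng.random() < theta or not wrong_final:
                choice, rel = correct_final[0], True
            else:
                choice, rel = str(rng.choice(wrong_final)), False
            recs = [ActionRecord(seq=1, section="r", item_id=choice, relevant=rel)]
        if recs:
            blocks.append((sec, recs))
    return blocks


def _inject_indiscipline(
    blocks: List[Tuple[str, List[ActionRecord]]], rng: np.random.Generator
) -> List[Tuple[str, List[ActionRecord]]]:
    """Shuffle section blocks and split off extra revisit bursts."""
    blocks = [(sec, list(recs)) for sec, recs in blocks]
    rng.shuffle(blocks)
    n_revisits = int(rng.geometric(0.5))  # mean 2
    for _ in range(n_revisits):
        splittable = [i for i, (_, recs) in enumerate(blocks) if len(recs) >= 2]
        if not splittable:
            break
        i = int(rng.choice(splittable))
        sec, recs = blocks[i]
        moved = recs.pop()
        # place the burst where it creates a genuine revisit (neighbors differ)
        for _try in range(10):
            pos = int(rng.integers(0, len(blocks) + 1))
            left = blocks[pos - 1][0] if pos > 0 else None
            right = blocks[pos][0] if pos < len(blocks) else None
            if left != sec and right != sec:
                break
        blocks.insert(pos, (sec, [moved]))
    return [b for b in blocks if b[1]]


def generate_log(case: SimulationCase, profile: StudentProfile) -> ActionLog:
    """Simulate one student's pass through the case.

    At θ=1, λ=0, β=1, δ=1 the log is perfect: every section F1 is 1 and
    the methodological score attains its maximum sqrt(5).
    """
    rng = np.random.default_rng(profile.seed)
    blocks = _section_blocks(case, profile, rng)
    if rng.random() >= profile.discipline:
        blocks = _inject_indiscipline(blocks, rng)
    records = []
    seq = 1
    for _, recs in blocks:
        for rec in recs:
            records.append(rec.model_copy(update={"seq": seq}))
            seq += 1
    return ActionLog(
        student_id=f"student-{profile.seed}", case_id=case.case_id, records=records
    )


def _jitter_probability(p: float, rng: np.random.Generator, concentration: float) -> float:
    if p <= 0.0 or p >= 1.0 or concentration <= 0:
        return p
    return float(rng.beta(p * concentration, (1.0 - p) * concentration))


def sample_profiles(
    n_students: int,
    seed: int,
    base: Optional[StudentProfile] = None,
    vary: bool = True,
    concentration: float = 30.0,
) -> List[StudentProfile]:
    """Per-student profiles from a splittable stream rooted at ``seed``.

    With ``vary=True`` each probability parameter is drawn from a Beta
    distribution with the base value as mean (``concentration``
    controls spread) and the noise rate from a Gamma with the base
    mean, giving a heterogeneous but controlled class.  With
    ``vary=False`` every student has exactly the base parameters and
    only their private random stream differs.
    """
    base = base or StudentProfile()
    root = np.random.SeedSequence(seed)
    profiles = []
    for child in root.spawn(n_students):
        student_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        if vary:
            rng = np.random.default_rng(child)
            profiles.append(
                StudentProfile(
                    thoroughness=_jitter_probability(base.thoroughness, rng, concentration),
                    noise=float(rng.gamma(4.0, base.noise / 4.0)) if base.noise > 0 else 0.0,
                    ba_accuracy=_jitter_probability(base.ba_accuracy, rng, concentration),
                    discipline=_jitter_probability(base.discipline, rng, concentration),
                    seed=student_seed,
                )
            )
        else:
            profiles.append(replace(base, seed=student_seed))
    return profiles


def generate_cohort(
    case: SimulationCase,
    n_students: int,
    seed: int,
    base: Optional[StudentProfile] = None,
    vary: bool = True,
) -> List[ActionLog]:
    """Simulate a class of ``n_students`` logs for ``case``."""
    logs = []
    for i, profile in enumerate(sample_profiles(n_students, seed, base, vary)):
        log = generate_log(case, profile)
        logs.append(
            ActionLog(
                student_id=f"student-{i:03d}", case_id=case.case_id, records=log.records
            )
        )
    return logs
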