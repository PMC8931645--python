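"""Per-section sensitivity, precision and F1.

For each of the seven sections of the encounter the student receives

* a **sensitivity**: the fraction of the author's relevant items for
  that section the student covered, and
* a **precision**: the fraction of the student's distinct actions in
  that section that were relevant,

combined into a single score by the harmonic mean
``F1 = 2·s·p / (s + p)`` (0 when both are 0), so a perfect section —
everything relevant found, nothing superfluous done — scores exactly 1.

Counting is over *distinct* items: asking the same question twice counts
once in both numerator and denominator.  Repetition is a workflow
property and is penalized by the methodological score, not here.

Binary analysis is special: only the **first attempt** on each
factor-hypothesis pair is scored, and an attempt is correct iff the
chosen anchor equals the reference anchor.  The sensitivity denominator
is the number of pairs in the reference matrix; the precision
denominator is the number of pairs the student actually attempted.

A section for which the case defines no relevant item has an undefined
sensitivity denominator; it is flagged *not assessable* and excluded
from every composite average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from .action_log import ActionLog
from .case_model import SECTION_CODES, SimulationCase
from .errors import ScoringError


@dataclass(frozen=True)
class SectionScore:
    """Sensitivity/precision/F1 for one section, with the raw counts."""

    section: str
    sensitivity: float
    precision: float
    f1: float
    n_relevant_total: int
    n_relevant_found: int
    n_actions: int
    assessable: bool = True


def section_f1(sensitivity: float, precision: float) -> float:
    """Harmonic mean of sensitivity and precision; 0 when both are 0."""
    for name, v in (("sensitivity", sensitivity), ("precision", precision)):
        if not 0.0 <= v <= 1.0:
            raise ScoringError(f"{name}={v} outside [0, 1]")
    if sensitivity + precision == 0.0:
        return 0.0
    return 2.0 * sensitivity * precision / (sensitivity + precision)


def _binary_counts(case: SimulationCase, log: ActionLog) -> tuple[int, int, int]:
    """(n_reference_pairs, n_attempt1_pairs_executed, n_correct_attempt1)."""
    n_ref = case.n_relevant("b")
    attempted: dict[str, str | None] = {}
    for rec in log.section_records("b"):
        if rec.attempt == 1 and rec.item_id not in attempted:
            attempted[rec.item_id] = rec.payload
    n_correct = sum(
        1
        for item, anchor in attempted.items()
        if (ref := case.reference_anchor(item)) is not None and anchor == ref
    )
    return n_ref, len(attempted), n_correct


def _plain_counts(case: SimulationCase, log: ActionLog, section: str) -> tuple[int, int, int]:
    """(n_relevant_total, n_distinct_actions, n_relevant_found)."""
    relevant = case.relevant_set(section)
    acted = {rec.item_id for rec in log.section_records(section)}
    return len(relevant), len(acted), len(acted & relevant)


def score_section(case: SimulationCase, log: ActionLog, section: str) -> SectionScore:
    """Score one section of one student's log against the case."""
    if section not in SECTION_CODES:
        raise ScoringError(f"unknown section code {section!r}")
    if section == "b":
        n_total, n_actions, n_found = _binary_counts(case, log)
    else:
        n_total, n_actions, n_found = _plain_counts(case, log, section)

    if n_total == 0:
        return SectionScore(
            section=section,
            sensitivity=float("nan"),
            precision=float("nan"),
            f1=float("nan"),
            n_relevant_total=0,
            n_relevant_found=n_found,
            n_actions=n_actions,
            assessable=False,
        )

    sensitivity = n_found / n_total
    precision = n_found / n_actions if n_actions > 0 else 0.0
    return SectionScore(
        section=section,
        sensitivity=sensitivity,
        precision=precision,
        f1=section_f1(sensitivity, precision),
        n_relevant_total=n_total,
        n_relevant_found=n_found,
        n_actions=n_actions,
    )


def section_sensitivity(case: SimulationCase, log: ActionLog, section: str) -> float:
    return score_section(case, log, section).sensitivity


def section_precision(case: SimulationCase, log: ActionLog, section: str) -> float:
    return score_section(case, log, section).precision


def score_all_sections(case: SimulationCase, log: ActionLog) -> List[SectionScore]:
    """One :class:`SectionScore` per section, in canonical order s,a,p,m,h,b,r."""
    return [score_section(case, log, sec) for sec in SECTION_CODES]
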