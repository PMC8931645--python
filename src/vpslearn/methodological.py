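"""Methodological score: conformance of the diagnostic workflow.

The student's action sequence is encoded as an **execution string**:
one character per action, the character being the action's section code
(``s a p m h b r``).  Runs of contiguous identical characters are
collapsed to one — identifying three scenario factors, asking two
questions and performing two examinations gives the raw string
``sssaapp`` and the collapsed string ``sap``.  The collapsed string is
called Φ (phi).

Five bounded parameters are computed from Φ:

``p1``
    Levenshtein similarity of the first three characters of Φ to the
    reference prefix ``sap`` — a sound work-up starts with the
    scenario, then history, then physical examination.
``p2``
    Levenshtein similarity of the last two characters of Φ to the
    reference suffix ``br`` — the case should close with the binary
    analysis followed by the final diagnosis.
``p3``
    1 if the first hypothesis (``h``) precedes the first medical test
    (``m``), else 0 — tests should follow a hypothesis, never precede
    it.  A Φ with no medical test commits no ordering violation and
    scores 1; a Φ with tests but no hypothesis scores 0.
``p4``
    Fraction of the 7 sections present in Φ (coverage).
``p5``
    ``1/(1+R)`` where ``R = |Φ| − |distinct(Φ)|`` counts section
    *revisits* after collapsing — back-and-forth movement between
    sections is penalized, a strictly linear pass scores 1.

The methodological score is the Euclidean norm
``sqrt(p1² + p2² + p3² + p4² + p5²)``, in ``[0, sqrt(5)]``, maximal
exactly for a perfect linear workflow such as Φ = ``saphmbr``.

Levenshtein similarity is the unit-cost edit distance normalized as
``1 − lev(x, y)/max(|x|, |y|)`` (1 when both strings are empty), so it
is bounded in [0, 1] like the other four parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .action_log import ActionLog
from .case_model import SECTION_CODES, SimulationCase
from .errors import ScoringError

PREFIX_REFERENCE = "sap"
SUFFIX_REFERENCE = "br"

MAX_SCORE = math.sqrt(5.0)


@dataclass(frozen=True)
class ExecutionString:
    """Raw and run-collapsed encodings of a student's action sequence."""

    raw: str
    collapsed: str


@dataclass(frozen=True)
class MethodologicalComponents:
    """Φ, the five workflow parameters, the revisit count R and the score."""

    phi: str
    p1: float
    p2: float
    p3: int
    p4: float
    p5: float
    revisits: int
    score: float

    @property
    def normalized(self) -> float:
        """Score rescaled to [0, 1]."""
        return self.score / MAX_SCORE


def collapse_runs(raw: str) -> str:
    """Collapse runs of contiguous identical characters; idempotent."""
    out = []
    for ch in raw:
        if not out or out[-1] != ch:
            out.append(ch)
    return "".join(out)


def build_execution_string(
    log: ActionLog,
    mode: str = "all",
    case: Optional[SimulationCase] = None,
) -> ExecutionString:
    """Encode a log's action sequence as section characters.

    ``mode="all"`` (default) uses every logged action; ``mode="critical"``
    restricts to executions of the case's critical diagnostic acts and
    therefore requires ``case``.
    """
    if mode == "all":
        raw = "".join(rec.section for rec in log.records)
    elif mode == "critical":
        if case is None:
            raise ScoringError("mode='critical' requires the case")
        bound = {
            (act.bound_action.section, act.bound_action.item_id)
            for act in case.critical_acts
        }
        raw = "".join(
            rec.section for rec in log.records if (rec.section, rec.item_id) in bound
        )
    else:
        raise ScoringError(f"unknown phi mode {mode!r}; use 'all' or 'critical'")
    return ExecutionString(raw=raw, collapsed=collapse_runs(raw))


def levenshtein_distance(x: str, y: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if len(x) < len(y):
        x, y = y, x
    prev = list(range(len(y) + 1))
    for i, cx in enumerate(x, start=1):
        cur = [i]
        for j, cy in enumerate(y, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (cx != cy)))
        prev = cur
    return prev[len(y)]


def levenshtein_similarity(x: str, y: str) -> float:
    """``1 − lev(x, y)/max(|x|, |y|)``; 1.0 when both strings are empty."""
    longest = max(len(x), len(y))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein_distance(x, y) / longest


def compute_p1(phi: str) -> float:
    """Similarity of Φ's (≤3-character) prefix to the reference ``sap``."""
    return levenshtein_similarity(phi[:3], PREFIX_REFERENCE)


def compute_p2(phi: str) -> float:
    """Similarity of Φ's (≤2-character) suffix to the reference ``br``."""
    suffix = phi[-2:] if phi else ""
    return levenshtein_similarity(suffix, SUFFIX_REFERENCE)


def compute_p3(phi: str) -> int:
    """1 iff the first hypothesis precedes the first medical test."""
    h, m = phi.find("h"), phi.find("m")
    if m == -1:
        return 1
    if h == -1:
        return 0
    return 1 if h < m else 0


def compute_p4(phi: str) -> float:
    """Fraction of the 7 sections that appear in Φ."""
    return len(set(phi)) / len(SECTION_CODES)


def count_revisits(phi: str) -> int:
    """R: number of returns to an already-visited section in collapsed Φ."""
    return len(phi) - len(set(phi))


def compute_p5(phi: str) -> float:
    """``1/(1+R)``: 1 for a strictly linear pass, smaller with revisits."""
    return 1.0 / (1.0 + count_revisits(phi))


def methodological_score(
    log: ActionLog,
    mode: str = "all",
    case: Optional[SimulationCase] = None,
) -> MethodologicalComponents:
    """Compute Φ, p1–p5, R and the Euclidean-norm score for one log.

    An empty log yields the documented degenerate output
    ``p = (0, 0, 1, 0, 1)`` and score ``sqrt(2)``.
    """
    phi = build_execution_string(log, mode=mode, case=case).collapsed
    p1 = compute_p1(phi)
    p2 = compute_p2(phi)
    p3 = compute_p3(phi)
    p4 = compute_p4(phi)
    p5 = compute_p5(phi)
    score = math.sqrt(p1 * p1 + p2 * p2 + p3 * p3 + p4 * p4 + p5 * p5)
    return MethodologicalComponents(
        phi=phi, p1=p1, p2=p2, p3=p3, p4=p4, p5=p5,
        revisits=count_revisits(phi), score=score,
    )
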