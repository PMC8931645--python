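"""Composite scores: overall, collection and analytical.

The seven section F1 values are combined into a single **overall**
score, and into two block scores: **collection** over the four
data-gathering sections (scenario, anamnesis, physical examination,
medical tests) and **analytical** over the three data-analysis sections
(hypotheses, binary analysis, final diagnosis).  The combination rule
is the unweighted arithmetic mean over the assessable sections; custom
non-negative weights may be supplied.  With all seven sections
assessable and uniform weights the identity
``7·overall = 4·collection + 3·analytical`` holds exactly.

Ranks (1 = best) use competition ranking: tied students share the best
rank of their group and the following rank is skipped ("1224").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .case_model import ANALYTICAL_SECTIONS, COLLECTION_SECTIONS, SECTION_CODES
from .errors import ScoringError
from .section_metrics import SectionScore


@dataclass(frozen=True)
class CompositeScores:
    overall: float
    collection: float
    analytical: float
    assessable_sections: Tuple[str, ...]


def _mean_f1(
    scores: Sequence[SectionScore],
    sections: Sequence[str],
    weights: Optional[Mapping[str, float]] = None,
) -> float:
    by_sec: Dict[str, SectionScore] = {s.section: s for s in scores}
    missing = set(sections) - set(by_sec)
    if missing:
        raise ScoringError(f"missing section scores for {sorted(missing)}")
    usable = [by_sec[sec] for sec in sections if by_sec[sec].assessable]
    if not usable:
        raise ScoringError(
            "case defines no relevant items in any of the sections "
            f"{tuple(sections)}; score undefined"
        )
    if weights is None:
        return sum(s.f1 for s in usable) / len(usable)
    w = {sec: weights.get(sec, 1.0) for sec in sections}
    if any(v < 0 for v in w.values()):
        raise ScoringError("weights must be non-negative")
    total = sum(w[s.section] for s in usable)
    if total == 0:
        raise ScoringError("weights of assessable sections sum to zero")
    return sum(w[s.section] * s.f1 for s in usable) / total


def overall_score(
    scores: Sequence[SectionScore], weights: Optional[Mapping[str, float]] = None
) -> float:
    """Mean F1 over all assessable sections."""
    return _mean_f1(scores, SECTION_CODES, weights)


def collection_score(
    scores: Sequence[SectionScore], weights: Optional[Mapping[str, float]] = None
) -> float:
    """Mean F1 over the data-gathering sections s, a, p, m."""
    return _mean_f1(scores, COLLECTION_SECTIONS, weights)


def analytical_score(
    scores: Sequence[SectionScore], weights: Optional[Mapping[str, float]] = None
) -> float:
    """Mean F1 over the data-analysis sections h, b, r."""
    return _mean_f1(scores, ANALYTICAL_SECTIONS, weights)


def composite_scores(
    scores: Sequence[SectionScore], weights: Optional[Mapping[str, float]] = None
) -> CompositeScores:
    return CompositeScores(
        overall=overall_score(scores, weights),
        collection=collection_score(scores, weights),
        analytical=analytical_score(scores, weights),
        assessable_sections=tuple(s.section for s in scores if s.assessable),
    )


def competition_ranks(values: Sequence[float]) -> List[int]:
    """Ranks with 1 = highest value; ties share the best rank ("1224")."""
    order = sorted(range(len(values)), key=lambda i: -values[i])
    ranks = [0] * len(values)
    for pos, idx in enumerate(order):
        if pos > 0 and values[idx] == values[order[pos - 1]]:
            ranks[idx] = ranks[order[pos - 1]]
        else:
            ranks[idx] = pos + 1
    return ranks
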