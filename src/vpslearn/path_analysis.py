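"""Critical-diagnostic-act path extraction and cohort path frequencies.

The case author designates a handful of *critical diagnostic acts*
(e.g. S = read the scenario, P = palpate the abdomen, U = request the
ultrasound, D = select the correct diagnosis) and the order in which a
sound work-up performs them — the *desired execution path*.  A
student's path is the sequence of act labels in the order of each act's
**first** execution; acts never performed are simply absent.  Across a
cohort the distinct paths and their frequencies summarize how the class
actually moved through the case (the data behind a flow/Sankey
diagram), and configurable presence/absence queries answer questions
like "how many students reached the diagnosis without a physical
examination?".
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, List, Sequence

import pandas as pd

from .action_log import ActionLog
from .case_model import SimulationCase
from .errors import ScoringError


@dataclass(frozen=True)
class StudentPath:
    student_id: str
    path: str
    matches_desired: bool
    includes_all_acts: bool


def extract_path(case: SimulationCase, log: ActionLog) -> StudentPath:
    """Act labels in first-execution order; non-critical actions are ignored."""
    if not case.critical_acts:
        raise ScoringError(f"case {case.case_id!r} declares no critical acts")
    bound = {
        (act.bound_action.section, act.bound_action.item_id): act.act_id
        for act in case.critical_acts
    }
    seen: List[str] = []
    for rec in log.records:
        act_id = bound.get((rec.section, rec.item_id))
        if act_id is not None and act_id not in seen:
            seen.append(act_id)
    path = "".join(seen)
    return StudentPath(
        student_id=log.student_id,
        path=path,
        matches_desired=path == case.desired_path,
        includes_all_acts=set(path) == {a.act_id for a in case.critical_acts},
    )


def round_percent(fraction: float) -> int:
    """Half-up rounding to integer percent, as printed in reports (3/36 → 8)."""
    return int(Decimal(fraction * 100).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def cohort_path_table(paths: Sequence[StudentPath]) -> pd.DataFrame:
    """Distinct paths with counts and cohort fractions, most frequent first.

    Columns: ``path``, ``count``, ``percent`` (exact fraction of the
    cohort) and ``percent_rounded`` (half-up integer percent for
    human-readable output).  Counts sum to the cohort size.
    """
    if not paths:
        raise ScoringError("empty cohort: no paths to tabulate")
    counts = pd.Series([p.path for p in paths]).value_counts()
    n = len(paths)
    return pd.DataFrame(
        {
            "path": counts.index,
            "count": counts.to_numpy(),
            "percent": counts.to_numpy() / n,
            "percent_rounded": [round_percent(c / n) for c in counts.to_numpy()],
        }
    ).reset_index(drop=True)


def count_paths_matching(
    paths: Iterable[StudentPath],
    present: str = "",
    absent: str = "",
) -> int:
    """Number of students whose path contains every act in ``present`` and
    none in ``absent`` (e.g. reached the diagnosis, ``present="D"``,
    without a physical examination, ``absent="PM"``)."""
    return sum(
        1
        for p in paths
        if all(a in p.path for a in present) and all(a not in p.path for a in absent)
    )


def flow_edges(paths: Sequence[StudentPath]) -> pd.DataFrame:
    """Edge list for a flow diagram: consecutive act transitions with the
    number of students traversing each, width-proportional plotting data.

    The virtual node ``"^"`` marks the start of a path so first acts are
    representable as edges.
    """
    edges: dict[tuple, int] = {}
    for p in paths:
        prev = "^"
        for act in p.path:
            edges[(prev, act)] = edges.get((prev, act), 0) + 1
            prev = act
    rows = sorted(edges.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "source": [k[0] for k, _ in rows],
            "target": [k[1] for k, _ in rows],
            "count": [v for _, v in rows],
        }
    )
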