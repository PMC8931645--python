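"""Shared fixtures: a small hand-built case and helper constructors."""

import pytest

from vpslearn import (
    ActionLog,
    BinaryAnalysisEntry,
    BoundAction,
    CriticalActSpec,
    DiagnosticFactor,
    DiagnosticHypothesis,
    SimulationCase,
    make_log,
    pair_id,
)

ANCHOR_GRID = {
    # (factor, hypothesis) -> reference anchor; 3 factors x 2 hypotheses = 6 pairs
    ("f1", "dx1"): "increase",
    ("f1", "dx2"): "decrease",
    ("f2", "dx1"): "neutral",
    ("f2", "dx2"): "increase",
    ("f3", "dx1"): "increase",
    ("f3", "dx2"): "neutral",
}


@pytest.fixture
def toy_case() -> SimulationCase:
    """Small fully-populated case: 2+5+2+1 gathering items, 2 hypotheses
    (dx1 correct), 6 binary-analysis pairs, 5 critical acts SPMUD."""
    return SimulationCase(
        case_id="toy",
        relevant_items={
            "s": ["s1", "s2"],
            "a": ["a1", "a2", "a3", "a4", "a5"],
            "p": ["p1", "p2"],
            "m": ["m1"],
        },
        factors=[DiagnosticFactor(id=f) for f in ("f1", "f2", "f3")],
        hypotheses=[
            DiagnosticHypothesis(id="dx1", is_correct_final=True),
            DiagnosticHypothesis(id="dx2"),
        ],
        binary_reference=[
            BinaryAnalysisEntry(factor_id=f, hypothesis_id=h, anchor=a)
            for (f, h), a in ANCHOR_GRID.items()
        ],
        critical_acts=[
            CriticalActSpec(act_id="S", bound_action=BoundAction(section="s", item_id="s1")),
            CriticalActSpec(act_id="P", bound_action=BoundAction(section="p", item_id="p1")),
            CriticalActSpec(act_id="M", bound_action=BoundAction(section="p", item_id="p2")),
            CriticalActSpec(act_id="U", bound_action=BoundAction(section="m", item_id="m1")),
            CriticalActSpec(act_id="D", bound_action=BoundAction(section="r", item_id="dx1")),
        ],
        desired_path="SPMUD",
    )


def perfect_actions(case: SimulationCase):
    """Action tuples covering every relevant item once, nothing else, in
    canonical workflow order (scenario ... result)."""
    actions = []
    for sec in ("s", "a", "p"):
        actions += [(sec, it, True) for it in sorted(case.relevant_set(sec))]
    actions += [("h", h, True) for h in sorted(case.relevant_set("h"))]
    actions += [("m", it, True) for it in sorted(case.relevant_set("m"))]
    actions += [
        ("b", pid, True, 1, case.reference_anchor(pid))
        for pid in sorted(case.relevant_set("b"))
    ]
    actions += [("r", d, True) for d in sorted(case.relevant_set("r"))]
    return actions


@pytest.fixture
def perfect_log(toy_case) -> ActionLog:
    return make_log("ideal", "toy", perfect_actions(toy_case))


@pytest.fixture
def empty_log() -> ActionLog:
    return make_log("lazy", "toy", [])
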