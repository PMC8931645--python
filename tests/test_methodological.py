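"""Execution strings, Levenshtein similarity and the workflow score."""

import math
from functools import lru_cache

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpslearn import (
    build_execution_string,
    collapse_runs,
    compute_p1,
    compute_p2,
    compute_p3,
    compute_p4,
    compute_p5,
    levenshtein_distance,
    levenshtein_similarity,
    make_log,
    methodological_score,
)
from vpslearn.methodological import MAX_SCORE, count_revisits

codes = st.text(alphabet="sapmhbr", max_size=12)


# -- execution strings --------------------------------------------------


def test_worked_string_example():
    """3 scenario + 2 anamnesis + 2 physical-exam actions -> raw
    'sssaapp', collapsed 'sap'."""
    log = make_log(
        "st", "c",
        [("s", "x1"), ("s", "x2"), ("s", "x3"), ("a", "q1"), ("a", "q2"),
         ("p", "e1"), ("p", "e2")],
    )
    es = build_execution_string(log)
    assert es.raw == "sssaapp"
    assert es.collapsed == "sap"


def test_empty_log_gives_empty_strings(empty_log):
    es = build_execution_string(empty_log)
    assert es.raw == "" and es.collapsed == ""


def test_alternation_is_not_collapsed():
    log = make_log("st", "c", [("s", "1"), ("a", "2"), ("s", "3"), ("a", "4")])
    assert build_execution_string(log).collapsed == "sasa"


@pytest.mark.parametrize(
    "raw, expected", [("sssaapp", "sap"), ("sap", "sap"), ("aabbaa", "aba"), ("", "")]
)
def test_collapse_runs(raw, expected):
    assert collapse_runs(raw) == expected


@given(codes)
def test_collapse_runs_idempotent_and_never_longer(raw):
    once = collapse_runs(raw)
    assert collapse_runs(once) == once
    assert len(once) <= len(raw)
    assert all(x != y for x, y in zip(once, once[1:]))


def test_critical_acts_mode(toy_case):
    log = make_log(
        "st", "toy",
        [("s", "s1"), ("a", "a1"), ("p", "p1"), ("p", "junk"), ("m", "m1"), ("r", "dx1")],
    )
    assert build_execution_string(log).collapsed == "sapmr"
    # only S(s,s1) P(p,p1) U(m,m1) D(r,dx1) are critical-act executions
    assert build_execution_string(log, mode="critical", case=toy_case).collapsed == "spmr"


# -- Levenshtein --------------------------------------------------------


def oracle_distance(x: str, y: str) -> int:
    """Textbook recursive definition, memoized; independent of the
    iterative implementation under test."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (x[i - 1] != y[j - 1]),
        )

    return rec(len(x), len(y))


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ("sap", "sap", 1.0),
        ("asp", "sap", 1 / 3),   # transposition costs two unit edits
        ("hr", "br", 0.5),
        ("", "", 1.0),
        ("", "sap", 0.0),
    ],
)
def test_similarity_values(x, y, expected):
    assert levenshtein_similarity(x, y) == pytest.approx(expected)


@given(codes, codes)
@settings(max_examples=200)
def test_similarity_symmetric_and_bounded(x, y):
    sim = levenshtein_similarity(x, y)
    assert sim == levenshtein_similarity(y, x)
    assert 0.0 <= sim <= 1.0
    assert levenshtein_distance(x, y) == oracle_distance(x, y)


def test_distance_against_edlib_cross_check():
    edlib = pytest.importorskip("edlib")
    pairs = [("saphmbr", "sapr"), ("sasa", "sap"), ("mbr", "br"), ("hbrh", "shbr")]
    for x, y in pairs:
        assert levenshtein_distance(x, y) == edlib.align(x, y, task="distance")["editDistance"]


# -- the five parameters ------------------------------------------------


@pytest.mark.parametrize(
    "phi, expected",
    [("saphmbr", 1.0), ("sa", 2 / 3), ("", 0.0), ("asp", 1 / 3)],
)
def test_p1_prefix_conformance(phi, expected):
    assert compute_p1(phi) == pytest.approx(expected)


@pytest.mark.parametrize(
    "phi, expected",
    [("saphmbr", 1.0), ("sahr", 0.5), ("", 0.0), ("b", 0.5)],
)
def test_p2_suffix_conformance(phi, expected):
    assert compute_p2(phi) == pytest.approx(expected)


@pytest.mark.parametrize(
    "phi, expected",
    [
        ("saphmbr", 1),  # h before m
        ("sampbhr", 0),  # m before h
        ("sapbhr", 1),   # no test ordered: no violation
        ("sapmbr", 0),   # tests without any hypothesis
        ("", 1),
    ],
)
def test_p3_hypothesis_before_test(phi, expected):
    assert compute_p3(phi) == expected


@pytest.mark.parametrize(
    "phi, expected", [("sapr", 4 / 7), ("saphmbr", 1.0), ("s", 1 / 7), ("", 0.0)]
)
def test_p4_section_coverage(phi, expected):
    assert compute_p4(phi) == pytest.approx(expected)


@pytest.mark.parametrize(
    "phi, revisits, expected",
    [("saphmbr", 0, 1.0), ("sapas", 2, 1 / 3), ("", 0, 1.0), ("sas", 1, 0.5)],
)
def test_p5_revisit_penalty(phi, revisits, expected):
    assert count_revisits(phi) == revisits
    assert compute_p5(phi) == pytest.approx(expected)


# -- the combined score -------------------------------------------------


def test_perfect_linear_workflow_attains_maximum():
    log = make_log("st", "c", [(sec, f"i_{sec}") for sec in "saphmbr"])
    comp = methodological_score(log)
    assert comp.phi == "saphmbr"
    assert (comp.p1, comp.p2, comp.p3, comp.p4, comp.p5) == (1, 1, 1, 1, 1)
    assert comp.score == pytest.approx(math.sqrt(5))
    assert comp.normalized == pytest.approx(1.0)


def test_empty_log_degenerate_components(empty_log):
    comp = methodological_score(empty_log)
    assert (comp.p1, comp.p2, comp.p3, comp.p4, comp.p5) == (0, 0, 1, 0, 1)
    assert comp.score == pytest.approx(math.sqrt(2))


def test_extra_revisit_strictly_lowers_score():
    linear = [(sec, f"i_{sec}") for sec in "saphmbr"]
    revisit = linear + [("a", "q_again"), ("b", "again"), ("r", "i_r")]
    lo = methodological_score(make_log("st", "c", linear))
    hi = methodological_score(make_log("st", "c", revisit))
    assert hi.p5 < lo.p5
    assert hi.score < lo.score


@given(codes)
@settings(max_examples=200)
def test_score_bounded_by_sqrt5(raw):
    log = make_log("st", "c", [(sec, f"i{k}") for k, sec in enumerate(raw)])
    comp = methodological_score(log)
    assert 0.0 <= comp.score <= MAX_SCORE + 1e-12
    assert comp.score**2 == pytest.approx(
        comp.p1**2 + comp.p2**2 + comp.p3**2 + comp.p4**2 + comp.p5**2, abs=1e-12
    )
    at_max = comp.score == pytest.approx(MAX_SCORE)
    all_ones = (comp.p1, comp.p2, comp.p3, comp.p4, comp.p5) == (1, 1, 1, 1, 1)
    assert at_max == all_ones
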