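"""Cohort report, radar data and Spearman validation."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vpslearn import (
    ScoringError,
    cohort_report,
    generate_case,
    generate_cohort,
    make_log,
    radar_data,
    spearman_validation,
    validate_against_external,
    write_report,
)
from conftest import perfect_actions


@pytest.fixture(scope="module")
def synthetic_class():
    case = generate_case(seed=11)
    logs = generate_cohort(case, 20, seed=11)
    return case, logs, cohort_report(case, logs)


def test_identical_perfect_students(toy_case):
    logs = [
        make_log(f"st{i}", "toy", perfect_actions(toy_case)) for i in range(4)
    ]
    report = cohort_report(toy_case, logs)
    assert report.mean_overall == pytest.approx(1.0)
    assert report.sd_overall == pytest.approx(0.0)
    assert (report.histogram_counts > 0).sum() == 1
    assert report.histogram_counts[-1] == 4  # overall exactly 1.0 lands in last bin


def test_mean_and_sample_sd_convention(toy_case):
    """SD uses the n-1 (sample) denominator: a perfect and an inactive
    student have overalls 1 and 0, so mean 0.5 and SD 1/sqrt(2)."""
    logs = [
        make_log("good", "toy", perfect_actions(toy_case)),
        make_log("lazy", "toy", []),
    ]
    report = cohort_report(toy_case, logs)
    assert sorted(report.students["overall"]) == [0.0, 1.0]
    assert report.mean_overall == pytest.approx(0.5)
    assert report.sd_overall == pytest.approx(0.7071067811865476)


def test_histogram_counts_sum_to_cohort_size(synthetic_class):
    _, logs, report = synthetic_class
    assert report.histogram_counts.sum() == len(logs)
    assert len(report.histogram_counts) == 20
    assert report.histogram_edges[1] - report.histogram_edges[0] == pytest.approx(0.05)
    assert report.students["overall"].min() >= report.histogram_edges[0]


def test_mean_within_student_range(synthetic_class):
    _, _, report = synthetic_class
    overalls = report.students["overall"]
    assert overalls.min() <= report.mean_overall <= overalls.max()


def test_report_is_deterministic(synthetic_class):
    case, logs, report = synthetic_class
    again = cohort_report(case, logs)
    pd.testing.assert_frame_equal(report.students, again.students)
    assert np.array_equal(report.histogram_counts, again.histogram_counts)


def test_radar_class_of_one(toy_case):
    logs = [make_log("solo", "toy", perfect_actions(toy_case))]
    report = cohort_report(toy_case, logs)
    radar = radar_data(report, "solo")
    assert list(radar["section"]) == list("sapmhbr")
    assert radar["student_f1"].tolist() == radar["class_mean_f1"].tolist()


def test_radar_class_mean_is_column_mean(synthetic_class):
    _, logs, report = synthetic_class
    radar = radar_data(report, logs[0].student_id)
    expected = report.f1_matrix.mean(axis=0).to_numpy()
    assert np.allclose(radar["class_mean_f1"], expected)
    assert np.allclose(radar["student_f1"], report.f1_matrix.iloc[0].to_numpy())


def test_radar_unknown_student(synthetic_class):
    _, _, report = synthetic_class
    with pytest.raises(ScoringError, match="not in cohort"):
        radar_data(report, "nobody")


# -- Spearman validation ------------------------------------------------


def test_spearman_concordant_and_discordant():
    xs = {f"st{i}": float(i) for i in range(8)}
    up = {f"st{i}": 10.0 + 2 * i for i in range(8)}
    down = {f"st{i}": -float(i) for i in range(8)}
    assert spearman_validation("m", xs, up).rho == pytest.approx(1.0)
    assert spearman_validation("m", xs, down).rho == pytest.approx(-1.0)


def test_spearman_self_correlation_with_ties():
    xs = {f"st{i}": v for i, v in enumerate([3, 1, 1, 2, 5, 5, 5])}
    assert spearman_validation("m", xs, xs).rho == pytest.approx(1.0)


def test_spearman_matches_scipy_on_tied_exam_pattern():
    """Heavily tied external scores (1x25, 6x29, 13x33) against a noisy
    metric: average-rank rho and t-approximation p equal scipy's."""
    rng = np.random.default_rng(3)
    exam = [25.0] + [29.0] * 6 + [33.0] * 13
    ids = [f"st{i}" for i in range(20)]
    metric = dict(zip(ids, rng.random(20)))
    external = dict(zip(ids, exam))
    res = spearman_validation("overall", metric, external)
    rho, p = stats.spearmanr([metric[i] for i in ids], exam)
    assert res.rho == pytest.approx(rho)
    assert res.p_value == pytest.approx(p)
    assert res.n == 20


def test_spearman_pairwise_deletion():
    metric = {f"st{i}": float(i) for i in range(10)}
    external = {f"st{i}": float(i) for i in range(5, 15)}  # only st5..st9 shared
    assert spearman_validation("m", metric, external).n == 5


def test_spearman_needs_three_pairs():
    with pytest.raises(ScoringError, match="at least 3"):
        spearman_validation("m", {"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})


def test_spearman_undefined_when_constant():
    xs = {f"st{i}": 1.0 for i in range(5)}
    ys = {f"st{i}": float(i) for i in range(5)}
    res = spearman_validation("m", xs, ys)
    assert not res.defined
    assert np.isnan(res.rho)


def test_validation_table_layout(synthetic_class):
    _, logs, report = synthetic_class
    rng = np.random.default_rng(7)
    external = {log.student_id: float(rng.integers(20, 34)) for log in logs[:15]}
    table = validate_against_external(report, external)
    assert list(table["metric"]) == ["overall", "collection", "analytical", "methodological"]
    assert (table["n"] == 15).all()
    assert table["rho"].abs().max() <= 1.0


# -- report writing -----------------------------------------------------


def test_write_report_directory(synthetic_class, tmp_path):
    case, logs, report = synthetic_class
    external = {log.student_id: 30.0 + i for i, log in enumerate(logs)}
    write_report(report, tmp_path / "out", external=external)
    out = tmp_path / "out"
    for name in ("students.csv", "sections.csv", "histogram.csv", "radar.csv",
                 "paths.csv", "flows.csv", "validation.csv", "summary.json"):
        assert (out / name).exists(), name
    hist = pd.read_csv(out / "histogram.csv")
    assert hist["count"].sum() == len(logs)
    summary = json.loads((out / "summary.json").read_text())
    assert summary["n_students"] == len(logs)
    assert summary["mean_overall"] == pytest.approx(report.mean_overall)


def test_empty_cohort_is_an_error(toy_case):
    with pytest.raises(ScoringError, match="empty cohort"):
        cohort_report(toy_case, [])
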