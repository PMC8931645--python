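"""Cohort-level analytics and validation against an external score.

Given a case and a class of logs this module computes every per-student
metric (section F1 vector, composites, methodological components,
critical-act path), class summary statistics (mean and sample SD of the
overall score, a 0.05-bin histogram on [0, 1]), radar-chart data
(student vs class-mean F1 per section), competition ranks, and the
Spearman rank correlation between any per-student metric and an
external examination score.

Spearman's rho is computed on average ranks (ties receive the mean of
the ranks they span) as the Pearson correlation of the two rank
vectors; the two-sided p-value uses the t approximation
``t = rho·sqrt((n−2)/(1−rho²))`` with n−2 degrees of freedom, adequate
for the cohort sizes (tens of students) this tool targets.  Students
missing either value are dropped pairwise and the paired n is reported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .action_log import ActionLog
from .case_model import SECTION_CODES, SimulationCase
from .composite_scores import competition_ranks, composite_scores
from .errors import ScoringError
from .methodological import MethodologicalComponents, methodological_score
from .path_analysis import StudentPath, cohort_path_table, extract_path
from .section_metrics import score_all_sections

#: Histogram bin edges: 20 right-open bins of width 0.05 on [0, 1]
#: (the last bin closed so an overall of exactly 1.0 is counted).
HISTOGRAM_EDGES = np.linspace(0.0, 1.0, 21)


@dataclass
class CohortReport:
    """All per-student metrics plus class-level summaries for one case."""

    case_id: str
    students: pd.DataFrame          # one row per student: composites, ranks, phi, path
    f1_matrix: pd.DataFrame         # students x 7 sections, F1 values
    methodological: Dict[str, MethodologicalComponents]
    paths: List[StudentPath]
    mean_overall: float
    sd_overall: float
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray
    section_mean_f1: pd.Series      # class-mean F1 per section (radar baseline)

    @property
    def path_table(self) -> pd.DataFrame:
        return cohort_path_table(self.paths)


def cohort_report(
    case: SimulationCase,
    logs: Sequence[ActionLog],
    phi_mode: str = "all",
    weights: Optional[Mapping[str, float]] = None,
) -> CohortReport:
    """Score every log and assemble the class report.

    Scoring is fully deterministic: the report is a pure function of the
    case and the logs.
    """
    if not logs:
        raise ScoringError("empty cohort: at least one log is required")
    ids = [log.student_id for log in logs]
    if len(set(ids)) != len(ids):
        raise ScoringError("duplicate student_id in cohort")

    rows = []
    f1_rows = []
    methodo: Dict[str, MethodologicalComponents] = {}
    paths: List[StudentPath] = []
    for log in logs:
        sections = score_all_sections(case, log)
        comp = composite_scores(sections, weights)
        meth = methodological_score(log, mode=phi_mode, case=case)
        methodo[log.student_id] = meth
        row = {
            "student_id": log.student_id,
            "overall": comp.overall,
            "collection": comp.collection,
            "analytical": comp.analytical,
            "methodological": meth.score,
            "methodological_normalized": meth.normalized,
            "phi": meth.phi,
            "revisits": meth.revisits,
        }
        if case.critical_acts:
            sp = extract_path(case, log)
            paths.append(sp)
            row["path"] = sp.path
            row["matches_desired"] = sp.matches_desired
            row["includes_all_acts"] = sp.includes_all_acts
        rows.append(row)
        f1_rows.append({s.section: s.f1 for s in sections})

    students = pd.DataFrame(rows)
    for metric in ("overall", "collection", "analytical", "methodological"):
        students[f"rank_{metric}"] = competition_ranks(students[metric].tolist())

    f1_matrix = pd.DataFrame(f1_rows, index=ids, columns=list(SECTION_CODES))
    overalls = students["overall"].to_numpy()
    counts, edges = np.histogram(overalls, bins=HISTOGRAM_EDGES)
    return CohortReport(
        case_id=case.case_id,
        students=students,
        f1_matrix=f1_matrix,
        methodological=methodo,
        paths=paths,
        mean_overall=float(np.mean(overalls)),
        sd_overall=float(np.std(overalls, ddof=1)) if len(overalls) > 1 else 0.0,
        histogram_counts=counts,
        histogram_edges=edges,
        section_mean_f1=f1_matrix.mean(axis=0),
    )


def radar_data(report: CohortReport, student_id: str) -> pd.DataFrame:
    """Student F1 vs class-mean F1 per section, in canonical order.

    The two columns are the two rings of a radar chart.
    """
    if student_id not in report.f1_matrix.index:
        raise ScoringError(f"student {student_id!r} not in cohort")
    return pd.DataFrame(
        {
            "section": list(SECTION_CODES),
            "student_f1": report.f1_matrix.loc[student_id].to_numpy(),
            "class_mean_f1": report.section_mean_f1.to_numpy(),
        }
    )


@dataclass(frozen=True)
class ValidationResult:
    """Spearman correlation of one metric with the external score."""

    metric: str
    rho: float
    p_value: float
    n: int
    defined: bool = True


def spearman_validation(
    metric_name: str,
    scores: Mapping[str, float],
    external: Mapping[str, float],
) -> ValidationResult:
    """Spearman rank correlation between a per-student metric and an
    external score, with pairwise deletion of incomplete students.

    Raises :class:`ScoringError` with fewer than 3 complete pairs.  When
    either variable is constant over the paired students the correlation
    is undefined: the result is flagged with ``defined=False`` and NaN
    values rather than raising.
    """
    ids = sorted(set(scores) & set(external))
    n = len(ids)
    if n < 3:
        raise ScoringError(
            f"need at least 3 students with both values; got {n}"
        )
    x = np.asarray([scores[i] for i in ids], dtype=float)
    y = np.asarray([external[i] for i in ids], dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return ValidationResult(metric_name, float("nan"), float("nan"), n, defined=False)

    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return ValidationResult(metric_name, rho, p, n)


VALIDATION_METRICS = ("overall", "collection", "analytical", "methodological")


def validate_against_external(
    report: CohortReport, external: Mapping[str, float]
) -> pd.DataFrame:
    """Correlate each main metric with the external score: one row per
    metric (overall, collection, analytical, methodological) with rho,
    two-sided p and the paired n."""
    rows = []
    for metric in VALIDATION_METRICS:
        scores = dict(zip(report.students["student_id"], report.students[metric]))
        res = spearman_validation(metric, scores, external)
        rows.append(
            {
                "metric": res.metric,
                "rho": res.rho,
                "p_value": res.p_value,
                "n": res.n,
                "defined": res.defined,
            }
        )
    return pd.DataFrame(rows)


# -- report writers -----------------------------------------------------


def write_report(
    report: CohortReport,
    outdir: str | Path,
    external: Optional[Mapping[str, float]] = None,
) -> None:
    """Write the cohort report as a directory of CSVs plus a JSON summary.

    Files: ``students.csv`` (per-student metrics and ranks),
    ``sections.csv`` (the student x section F1 matrix), ``histogram.csv``,
    ``radar.csv`` (class-mean F1 per section), ``paths.csv`` and
    ``flows.csv`` when critical acts exist, ``validation.csv`` when an
    external score table is supplied, and ``summary.json``.
    """
    from .path_analysis import flow_edges

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.students.to_csv(out / "students.csv", index=False)
    report.f1_matrix.rename_axis("student_id").to_csv(out / "sections.csv")
    pd.DataFrame(
        {
            "bin_left": report.histogram_edges[:-1],
            "bin_right": report.histogram_edges[1:],
            "count": report.histogram_counts,
        }
    ).to_csv(out / "histogram.csv", index=False)
    report.section_mean_f1.rename("class_mean_f1").rename_axis("section").to_csv(
        out / "radar.csv"
    )
    summary = {
        "case_id": report.case_id,
        "n_students": int(len(report.students)),
        "mean_overall": report.mean_overall,
        "sd_overall": report.sd_overall,
    }
    if report.paths:
        report.path_table.to_csv(out / "paths.csv", index=False)
        flow_edges(report.paths).to_csv(out / "flows.csv", index=False)
        summary["n_desired_path"] = int(
            sum(1 for p in report.paths if p.matches_desired)
        )
    if external is not None:
        validate_against_external(report, external).to_csv(
            out / "validation.csv", index=False
        )
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
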