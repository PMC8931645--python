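"""Student action logs.

Every action a student performs in the simulator is appended to a log:
the section it belongs to, the item it targets, whether the author
considers it correct, and (for binary analysis only) an attempt
counter.  Only the *order* of actions matters to any metric, so
timestamps are not part of the schema.

On disk a log is line-delimited JSON: the first line is a header object
with ``student_id`` and ``case_id``, every following line one action
record.  The stored ``relevant`` flag is a cache — when a case is
supplied at read time the flag is recomputed from the case, which is
authoritative.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, List, Optional

import pydantic
from pydantic import BaseModel, Field, field_validator

from .case_model import SECTION_CODES, SimulationCase
from .errors import LogValidationError


class ActionRecord(BaseModel):
    """One logged student action.

    ``attempt`` counts repeated executions of the same (section, item);
    values above 1 are only meaningful — and only allowed — for binary
    analysis, where a student may revise an anchor.  For binary-analysis
    records ``item_id`` is the pair id ``"<factor>::<hypothesis>"`` and
    ``payload`` holds the anchor the student chose.
    """

    seq: int = Field(ge=1)
    section: str
    item_id: str
    relevant: bool = False
    attempt: int = Field(default=1, ge=1)
    payload: Optional[str] = None

    @field_validator("section")
    @classmethod
    def _valid_section(cls, v: str) -> str:
        if v not in SECTION_CODES:
            raise ValueError(f"unknown section code {v!r}; expected one of {SECTION_CODES}")
        return v


class ActionLog(BaseModel):
    """One student's ordered, flagged actions for one case."""

    student_id: str
    case_id: str
    records: List[ActionRecord] = Field(default_factory=list)

    @pydantic.model_validator(mode="after")
    def _check_invariants(self) -> "ActionLog":
        prev = 0
        for rec in self.records:
            if rec.seq <= prev:
                raise ValueError(
                    f"record seq {rec.seq} not strictly increasing (previous {prev})"
                )
            prev = rec.seq
            if rec.attempt > 1 and rec.section != "b":
                raise ValueError(
                    f"record seq {rec.seq}: attempt={rec.attempt} > 1 is only "
                    "permitted in the binary-analysis section"
                )
        return self

    def section_records(self, section: str) -> List[ActionRecord]:
        return [r for r in self.records if r.section == section]


def validate_against_case(log: ActionLog, case: SimulationCase) -> ActionLog:
    """Return a copy of ``log`` with relevance flags recomputed from ``case``.

    The case is the single source of truth for what counts as a correct
    action: an item is relevant iff it belongs to the section's
    reference set, and a binary-analysis entry additionally iff the
    chosen anchor equals the reference anchor.  A warning is emitted for
    every stored flag that disagrees.
    """
    if log.case_id != case.case_id:
        raise LogValidationError(
            f"log case_id {log.case_id!r} does not match case {case.case_id!r}"
        )
    fixed: List[ActionRecord] = []
    n_fixed = 0
    for rec in log.records:
        if rec.section == "b":
            ref = case.reference_anchor(rec.item_id)
            truth = ref is not None and rec.payload == ref
        else:
            truth = rec.item_id in case.relevant_set(rec.section)
        if truth != rec.relevant:
            n_fixed += 1
            rec = rec.model_copy(update={"relevant": truth})
        fixed.append(rec)
    if n_fixed:
        warnings.warn(
            f"log {log.student_id!r}: {n_fixed} stored relevance flag(s) disagreed "
            "with the case and were overwritten",
            stacklevel=2,
        )
    return ActionLog(student_id=log.student_id, case_id=log.case_id, records=fixed)


def read_log(path: str | Path, case: SimulationCase | None = None) -> ActionLog:
    """Read a line-delimited log file; optionally cross-validate with a case.

    Raises :class:`LogValidationError` on any schema violation
    (non-monotone ``seq``, unknown section code, malformed JSON, missing
    header).
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise LogValidationError(f"{path}: empty file (header line required)")
    try:
        header = json.loads(lines[0])
        raw_records = [json.loads(ln) for ln in lines[1:]]
    except json.JSONDecodeError as exc:
        raise LogValidationError(f"{path}: not valid line-delimited JSON: {exc}") from exc
    if not isinstance(header, dict) or "student_id" not in header or "case_id" not in header:
        raise LogValidationError(f"{path}: first line must be a header with student_id and case_id")
    try:
        log = ActionLog(
            student_id=header["student_id"],
            case_id=header["case_id"],
            records=[ActionRecord.model_validate(r) for r in raw_records],
        )
    except pydantic.ValidationError as exc:
        fields = "; ".join(
            "/".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise LogValidationError(f"{path}: invalid log: {fields}") from exc
    if case is not None:
        log = validate_against_case(log, case)
    return log


def write_log(log: ActionLog, path: str | Path) -> None:
    """Serialize a log as header line + one JSON record per line."""
    out = [json.dumps({"student_id": log.student_id, "case_id": log.case_id})]
    for rec in log.records:
        out.append(json.dumps(rec.model_dump(mode="json")))
    Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


def make_log(
    student_id: str,
    case_id: str,
    actions: Iterable[tuple],
) -> ActionLog:
    """Build a log from ``(section, item_id[, relevant[, attempt[, payload]]])`` tuples.

    ``seq`` is assigned from the iteration order.  Convenience for tests
    and fixture construction.
    """
    records = []
    for i, action in enumerate(actions, start=1):
        section, item_id, *rest = action
        relevant = rest[0] if len(rest) > 0 else False
        attempt = rest[1] if len(rest) > 1 else 1
        payload = rest[2] if len(rest) > 2 else None
        records.append(
            ActionRecord(
                seq=i, section=section, item_id=item_id,
                relevant=relevant, attempt=attempt, payload=payload,
            )
        )
    return ActionLog(student_id=student_id, case_id=case_id, records=records)
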