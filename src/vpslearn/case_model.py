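"""Case-definition model: the simulation author's answer key.

A simulated clinical encounter is divided into seven sections, each
identified by a one-character code:

=====  =====================================
code   section
=====  =====================================
``s``  input scenario (diagnostic factors in the presenting text)
``a``  anamnesis (history taking)
``p``  physical examination
``m``  medical tests
``h``  diagnostic hypothesis generation
``b``  binary analysis (factor-hypothesis anchor mapping)
``r``  result (final diagnosis)
=====  =====================================

The :class:`SimulationCase` bundles everything the author specified as
*correct*: the relevant items per data-gathering section, the set of
reasonable diagnostic hypotheses (with the correct final diagnosis
flagged), the binary-analysis reference matrix labelling every
factor-hypothesis pair with one of three anchors, and the critical
diagnostic acts together with their desired execution order.  Every
metric in the package is a pure function of a case and a student log.

Cases are serialized as a single UTF-8 JSON document; the schema is
documented in ``docs/case_schema.md``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Tuple

import pydantic
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import CaseValidationError

#: The seven section codes in canonical reporting order.
SECTION_CODES: Tuple[str, ...] = ("s", "a", "p", "m", "h", "b", "r")

#: Data-gathering sections (the "collection" block).
COLLECTION_SECTIONS: Tuple[str, ...] = ("s", "a", "p", "m")

#: Data-analysis sections (the "analytical" block).
ANALYTICAL_SECTIONS: Tuple[str, ...] = ("h", "b", "r")

#: Section order of a sound diagnostic workflow: hypotheses are raised
#: before medical tests are ordered, and the case closes with binary
#: analysis followed by the final diagnosis.
CANONICAL_EXECUTION_ORDER: Tuple[str, ...] = ("s", "a", "p", "h", "m", "b", "r")

#: The three anchor descriptors of the binary analysis (a 3-point
#: script-concordance scale: does the factor raise, leave unchanged, or
#: lower the probability of the hypothesis?).
ANCHORS: Tuple[str, ...] = ("increase", "neutral", "decrease")

#: Separator used to build a binary-analysis item id from a factor id
#: and a hypothesis id ("<factor>::<hypothesis>").
PAIR_SEP = "::"

_GATHERING_KEYS = ("s", "a", "p", "m")


def pair_id(factor_id: str, hypothesis_id: str) -> str:
    """Item id of the binary-analysis cell for one factor-hypothesis pair."""
    return f"{factor_id}{PAIR_SEP}{hypothesis_id}"


def split_pair_id(item_id: str) -> Tuple[str, str]:
    factor_id, sep, hypothesis_id = item_id.partition(PAIR_SEP)
    if not sep:
        raise CaseValidationError(
            f"binary-analysis item id {item_id!r} is not of the form "
            f"'<factor>{PAIR_SEP}<hypothesis>'"
        )
    return factor_id, hypothesis_id


class DiagnosticFactor(BaseModel):
    """A discrete piece of clinical information (symptom, sign, finding)."""

    id: str
    label: str = ""
    source_section: str = "s"

    @field_validator("source_section")
    @classmethod
    def _valid_section(cls, v: str) -> str:
        if v not in SECTION_CODES:
            raise ValueError(f"unknown section code {v!r}; expected one of {SECTION_CODES}")
        return v

    @field_validator("id")
    @classmethod
    def _no_sep(cls, v: str) -> str:
        if PAIR_SEP in v or not v:
            raise ValueError(f"factor id {v!r} must be non-empty and must not contain {PAIR_SEP!r}")
        return v


class DiagnosticHypothesis(BaseModel):
    """A candidate diagnosis the author considers reasonable for the case."""

    id: str
    label: str = ""
    is_correct_final: bool = False

    @field_validator("id")
    @classmethod
    def _no_sep(cls, v: str) -> str:
        if PAIR_SEP in v or not v:
            raise ValueError(f"hypothesis id {v!r} must be non-empty and must not contain {PAIR_SEP!r}")
        return v


class BinaryAnalysisEntry(BaseModel):
    """Reference anchor for one (diagnostic factor, hypothesis) pair."""

    factor_id: str
    hypothesis_id: str
    anchor: str

    @field_validator("anchor")
    @classmethod
    def _valid_anchor(cls, v: str) -> str:
        if v not in ANCHORS:
            raise ValueError(f"anchor {v!r} not in {ANCHORS}")
        return v


class BoundAction(BaseModel):
    """Concrete action a critical diagnostic act is bound to."""

    section: str
    item_id: str

    @field_validator("section")
    @classmethod
    def _valid_section(cls, v: str) -> str:
        if v not in SECTION_CODES:
            raise ValueError(f"unknown section code {v!r}; expected one of {SECTION_CODES}")
        return v


class CriticalActSpec(BaseModel):
    """An author-designated key action, labelled by one uppercase letter.

    Binding each act to a concrete (section, item) pair makes path
    extraction a pure log lookup with no text matching.
    """

    act_id: str
    description: str = ""
    bound_action: BoundAction

    @field_validator("act_id")
    @classmethod
    def _single_upper(cls, v: str) -> str:
        if len(v) != 1 or not v.isupper():
            raise ValueError(f"act_id {v!r} must be a single uppercase character")
        return v


class SimulationCase(BaseModel):
    """The author-defined reference answer key for one simulated case."""

    case_id: str
    relevant_items: Dict[str, List[str]] = Field(default_factory=dict)
    factors: List[DiagnosticFactor] = Field(default_factory=list)
    hypotheses: List[DiagnosticHypothesis] = Field(default_factory=list)
    binary_reference: List[BinaryAnalysisEntry] = Field(default_factory=list)
    critical_acts: List[CriticalActSpec] = Field(default_factory=list)
    desired_path: str = ""

    # -- validators -----------------------------------------------------

    @field_validator("relevant_items")
    @classmethod
    def _valid_item_sections(cls, v: Dict[str, List[str]]) -> Dict[str, List[str]]:
        for code, items in v.items():
            if code not in _GATHERING_KEYS:
                raise ValueError(
                    f"relevant_items key {code!r} invalid: explicit item lists exist only "
                    f"for the data-gathering sections {_GATHERING_KEYS}; hypothesis, "
                    "binary-analysis and final-diagnosis reference sets are derived from "
                    "'hypotheses' and 'binary_reference'"
                )
            if len(set(items)) != len(items):
                raise ValueError(f"duplicate item ids in relevant_items[{code!r}]")
        return v

    @model_validator(mode="after")
    def _check_invariants(self) -> "SimulationCase":
        for name, objs in (("factors", self.factors), ("hypotheses", self.hypotheses)):
            ids = [o.id for o in objs]
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate ids in {name}")
        if not self.hypotheses:
            raise ValueError("hypotheses: at least one diagnostic hypothesis is required")
        if not any(h.is_correct_final for h in self.hypotheses):
            raise ValueError("hypotheses: at least one must have is_correct_final=true")

        expected = {(f.id, h.id) for f in self.factors for h in self.hypotheses}
        seen = [(e.factor_id, e.hypothesis_id) for e in self.binary_reference]
        if len(set(seen)) != len(seen):
            raise ValueError("binary_reference: duplicate (factor, hypothesis) entry")
        if set(seen) != expected:
            missing = expected - set(seen)
            extra = set(seen) - expected
            raise ValueError(
                "binary_reference must cover every (factor, hypothesis) pair exactly "
                f"once; missing={sorted(missing)} extra={sorted(extra)}"
            )

        act_ids = [a.act_id for a in self.critical_acts]
        if len(set(act_ids)) != len(act_ids):
            raise ValueError("critical_acts: duplicate act_id")
        if len(set(self.desired_path)) != len(self.desired_path):
            raise ValueError("desired_path: each act may appear at most once")
        unknown = set(self.desired_path) - set(act_ids)
        if unknown:
            raise ValueError(f"desired_path references undeclared act ids {sorted(unknown)}")
        for act in self.critical_acts:
            sec, item = act.bound_action.section, act.bound_action.item_id
            if item not in self.relevant_set(sec):
                raise ValueError(
                    f"critical act {act.act_id!r} bound to ({sec!r}, {item!r}), which is "
                    "not a relevant item of that section"
                )
        if all(self.n_relevant(code) == 0 for code in SECTION_CODES):
            raise ValueError("case defines no relevant items in any section")
        return self

    # -- reference-set accessors ---------------------------------------

    def relevant_set(self, section: str) -> FrozenSet[str]:
        """Reference-relevant item ids for ``section``.

        For the gathering sections these are the author's explicit lists;
        for ``h`` every declared hypothesis is relevant (the list *is* the
        set of reasonable hypotheses), for ``r`` the correct final
        diagnoses, and for ``b`` the factor-hypothesis pair ids.
        """
        if section not in SECTION_CODES:
            raise CaseValidationError(f"unknown section code {section!r}")
        if section in _GATHERING_KEYS:
            return frozenset(self.relevant_items.get(section, ()))
        if section == "h":
            return frozenset(h.id for h in self.hypotheses)
        if section == "r":
            return frozenset(h.id for h in self.hypotheses if h.is_correct_final)
        return frozenset(pair_id(e.factor_id, e.hypothesis_id) for e in self.binary_reference)

    def n_relevant(self, section: str) -> int:
        return len(self.relevant_set(section))

    def reference_anchor(self, item_id: str) -> Optional[str]:
        """Reference anchor for a binary-analysis pair id, or None if unknown."""
        return self._anchor_map().get(item_id)

    def _anchor_map(self) -> Dict[str, str]:
        return {
            pair_id(e.factor_id, e.hypothesis_id): e.anchor for e in self.binary_reference
        }

    def act_by_id(self, act_id: str) -> CriticalActSpec:
        for act in self.critical_acts:
            if act.act_id == act_id:
                return act
        raise CaseValidationError(f"unknown critical act {act_id!r}")


def load_case(path: str | Path) -> SimulationCase:
    """Read and validate a case-definition JSON file.

    Raises
    ------
    CaseValidationError
        If the document violates the schema or any case invariant; the
        message names the offending field.
    FileNotFoundError
        If ``path`` does not exist.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CaseValidationError(f"{path}: not valid JSON: {exc}") from exc
    return case_from_dict(data, source=str(path))


def case_from_dict(data: dict, source: str = "<dict>") -> SimulationCase:
    try:
        return SimulationCase.model_validate(data)
    except pydantic.ValidationError as exc:
        fields = "; ".join(
            "/".join(str(loc) for loc in err["loc"]) + ": " + err["msg"]
            for err in exc.errors()
        )
        raise CaseValidationError(f"{source}: invalid case: {fields}") from exc


def save_case(case: SimulationCase, path: str | Path) -> None:
    """Write a case to ``path`` as JSON; ``load_case`` inverts it exactly."""
    Path(path).write_text(
        json.dumps(case.model_dump(mode="json"), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
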