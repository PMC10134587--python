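"""Domain model for the nursing-diagnosis knowledge base and care-plan records.

The knowledge base mirrors the structure of a standardized nursing-diagnosis
taxonomy: each diagnosis lists *defining characteristics* (observable evidence
for an "actual" diagnosis), optional *related factors* (contributors), and
*risk factors* (for "risk"-type diagnoses).  Patients are assessed through a
fixed five-aspect framework; each assessment item belongs to exactly one
aspect.  Indicator tables — scored (assessment item, diagnosis, element)
associations — are attached by one of the inference engines.

All identifiers are case-sensitive exact-match strings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

SCHEMA_VERSION = 1

#: The five aspects of the whole-person psychiatric nursing assessment framework.
ASPECTS = ("physical", "psychological", "intellectual", "social", "spiritual")

GROUPS = ("control", "cdv", "bade")
PHASES = ("pretest", "posttest")
ROLES = ("student", "researcher")


class KBError(Exception):
    """Base class for knowledge-base errors."""


class SchemaError(KBError):
    """Raised when a serialized artifact violates the schema.

    ``pointer`` is the JSON pointer of the first offending node.
    """

    def __init__(self, pointer: str, message: str):
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


class DanglingReferenceError(KBError):
    """An indicator references an (item, element) pair absent from the KB."""


class ElementType(str, Enum):
    DEFINING_CHARACTERISTIC = "defining_characteristic"
    RELATED_FACTOR = "related_factor"
    RISK_FACTOR = "risk_factor"


class DxType(str, Enum):
    ACTUAL = "actual"
    RISK = "risk"


class Level(str, Enum):
    MAJOR = "major"
    MINOR = "minor"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class AssessmentItem:
    item_id: str
    aspect: str
    label: str = ""

    def __post_init__(self):
        if self.aspect not in ASPECTS:
            raise ValueError(f"unknown assessment aspect {self.aspect!r}")


@dataclass(frozen=True)
class DiagnosisElement:
    element_id: str
    element_type: ElementType
    label: str = ""


@dataclass(frozen=True)
class Diagnosis:
    dx_code: str
    label: str
    dx_type: DxType
    elements: tuple[DiagnosisElement, ...]

    def elements_of(self, element_type: ElementType) -> tuple[DiagnosisElement, ...]:
        return tuple(e for e in self.elements if e.element_type == element_type)

    @property
    def defining_characteristics(self) -> tuple[DiagnosisElement, ...]:
        return self.elements_of(ElementType.DEFINING_CHARACTERISTIC)

    @property
    def risk_factors(self) -> tuple[DiagnosisElement, ...]:
        return self.elements_of(ElementType.RISK_FACTOR)

    @property
    def related_factors(self) -> tuple[DiagnosisElement, ...]:
        return self.elements_of(ElementType.RELATED_FACTOR)

    @property
    def evidence_elements(self) -> tuple[DiagnosisElement, ...]:
        """Elements that count toward diagnostic support: defining
        characteristics for actual diagnoses, risk factors for risk diagnoses."""
        if self.dx_type == DxType.RISK:
            return self.risk_factors
        return self.defining_characteristics


#: association = (assessment item id, diagnosis code, element id)
Association = tuple[str, str, str]


@dataclass(frozen=True)
class IndicatorEntry:
    association: Association
    score: float
    level: Level
    engine: str  # "cdv" | "bayes"


@dataclass
class IndicatorTable:
    entries: list[IndicatorEntry]
    engine: str
    params: dict = field(default_factory=dict)

    def displayable(self) -> list[IndicatorEntry]:
        """Entries emitted as guidance; excluded-level scores are retained in
        the table for reproducibility but never displayed."""
        return [e for e in self.entries if e.level != Level.EXCLUDED]

    def by_item(self, item_id: str) -> list[IndicatorEntry]:
        return [e for e in self.entries if e.association[0] == item_id]


@dataclass
class KnowledgeBase:
    diagnoses: list[Diagnosis]
    assessment_items: list[AssessmentItem]
    indicator_table: IndicatorTable | None = None
    provenance: dict = field(default_factory=dict)

    def diagnosis(self, dx_code: str) -> Diagnosis:
        for d in self.diagnoses:
            if d.dx_code == dx_code:
                return d
        raise KeyError(dx_code)

    def has_item(self, item_id: str) -> bool:
        return any(i.item_id == item_id for i in self.assessment_items)

    def resolves(self, association: Association) -> bool:
        """True iff the (item, diagnosis, element) triple exists in the KB.

        The first slot is normally an assessment item; for the defining
        characteristic -> related factor association family it may instead be
        a defining characteristic of the same diagnosis.
        """
        item_id, dx_code, element_id = association
        try:
            dx = self.diagnosis(dx_code)
        except KeyError:
            return False
        if not self.has_item(item_id) and not any(
            e.element_id == item_id and e.element_type == ElementType.DEFINING_CHARACTERISTIC
            for e in dx.elements
        ):
            return False
        return any(e.element_id == element_id for e in dx.elements)

    def with_indicators(self, table: IndicatorTable) -> "KnowledgeBase":
        return replace(self, indicator_table=table)


@dataclass(frozen=True)
class CarePlanRecord:
    """One author's identified elements for one patient-diagnosis.

    ``invalid_elements`` are identified ids that do not belong to the
    diagnosis's taxonomy list; they are retained (never silently dropped)
    because the competency evaluation must count them as non-compliant
    evidence.
    """

    participant_id: str
    patient_id: str
    group: str
    phase: str
    role: str
    dx_code: str
    identified_elements: frozenset[str]
    invalid_elements: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group token {self.group!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase token {self.phase!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role token {self.role!r}")

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.participant_id, self.phase, self.role, self.dx_code)

    def valid_elements(self, kb: KnowledgeBase) -> frozenset[str]:
        """Identified elements that belong to the diagnosis's evidence list."""
        dx = kb.diagnosis(self.dx_code)
        evidence = {e.element_id for e in dx.evidence_elements}
        return frozenset(el for el in self.identified_elements if el in evidence)


# ---------------------------------------------------------------------------
# Serialization


def kb_to_dict(kb: KnowledgeBase) -> dict:
    out: dict = {
        "meta": {"schema_version": SCHEMA_VERSION, "provenance": kb.provenance},
        "assessment_items": [
            {"item_id": i.item_id, "aspect": i.aspect, "label": i.label}
            for i in kb.assessment_items
        ],
        "diagnoses": [
            {
                "dx_code": d.dx_code,
                "label": d.label,
                "dx_type": d.dx_type.value,
                "elements": [
                    {
                        "element_id": e.element_id,
                        "element_type": e.element_type.value,
                        "label": e.label,
                    }
                    for e in d.elements
                ],
            }
            for d in kb.diagnoses
        ],
    }
    if kb.indicator_table is not None:
        t = kb.indicator_table
        out["indicators"] = {
            "engine": t.engine,
            "params": t.params,
            "entries": [
                {
                    "item_id": e.association[0],
                    "dx_code": e.association[1],
                    "element_id": e.association[2],
                    "score": e.score,
                    "level": e.level.value,
                    "engine": e.engine,
                }
                for e in t.entries
            ],
        }
    return out


def _require(obj, key, pointer, typ=None):
    if not isinstance(obj, dict):
        raise SchemaError(pointer, f"expected object, got {type(obj).__name__}")
    if key not in obj:
        raise SchemaError(f"{pointer}/{key}", "missing required key")
    val = obj[key]
    if typ is not None and not isinstance(val, typ):
        raise SchemaError(
            f"{pointer}/{key}",
            f"expected {getattr(typ, '__name__', typ)}, got {type(val).__name__}",
        )
    return val


def kb_from_dict(data: dict) -> KnowledgeBase:
    meta = _require(data, "meta", "", dict)
    version = _require(meta, "schema_version", "/meta", int)
    if version != SCHEMA_VERSION:
        raise SchemaError("/meta/schema_version", f"unsupported version {version}")
    provenance = meta.get("provenance", {})

    raw_items = _require(data, "assessment_items", "", list)
    items: list[AssessmentItem] = []
    for i, raw in enumerate(raw_items):
        ptr = f"/assessment_items/{i}"
        aspect = _require(raw, "aspect", ptr, str)
        if aspect not in ASPECTS:
            raise SchemaError(f"{ptr}/aspect", f"unknown aspect {aspect!r}")
        items.append(
            AssessmentItem(
                item_id=_require(raw, "item_id", ptr, str),
                aspect=aspect,
                label=raw.get("label", ""),
            )
        )

    raw_dx = _require(data, "diagnoses", "", list)
    diagnoses: list[Diagnosis] = []
    for i, raw in enumerate(raw_dx):
        ptr = f"/diagnoses/{i}"
        dx_type = _require(raw, "dx_type", ptr, str)
        if dx_type not in {t.value for t in DxType}:
            raise SchemaError(f"{ptr}/dx_type", f"unknown diagnosis type {dx_type!r}")
        elements = []
        for j, rel in enumerate(_require(raw, "elements", ptr, list)):
            eptr = f"{ptr}/elements/{j}"
            etype = _require(rel, "element_type", eptr, str)
            if etype not in {t.value for t in ElementType}:
                raise SchemaError(f"{eptr}/element_type", f"unknown element type {etype!r}")
            elements.append(
                DiagnosisElement(
                    element_id=_require(rel, "element_id", eptr, str),
                    element_type=ElementType(etype),
                    label=rel.get("label", ""),
                )
            )
        diagnoses.append(
            Diagnosis(
                dx_code=_require(raw, "dx_code", ptr, str),
                label=raw.get("label", ""),
                dx_type=DxType(dx_type),
                elements=tuple(elements),
            )
        )

    kb = KnowledgeBase(diagnoses=diagnoses, assessment_items=items, provenance=provenance)

    if "indicators" in data:
        raw_t = data["indicators"]
        entries = []
        for i, raw in enumerate(_require(raw_t, "entries", "/indicators", list)):
            ptr = f"/indicators/entries/{i}"
            level = _require(raw, "level", ptr, str)
            if level not in {l.value for l in Level}:
                raise SchemaError(f"{ptr}/level", f"unknown level {level!r}")
            assoc = (
                _require(raw, "item_id", ptr, str),
                _require(raw, "dx_code", ptr, str),
                _require(raw, "element_id", ptr, str),
            )
            if not kb.resolves(assoc):
                raise DanglingReferenceError(
                    f"{ptr}: indicator references unknown association {assoc}"
                )
            entries.append(
                IndicatorEntry(
                    association=assoc,
                    score=float(_require(raw, "score", ptr, (int, float))),
                    level=Level(level),
                    engine=raw.get("engine", raw_t.get("engine", "")),
                )
            )
        kb.indicator_table = IndicatorTable(
            entries=entries,
            engine=_require(raw_t, "engine", "/indicators", str),
            params=raw_t.get("params", {}),
        )
    return kb


def load_knowledge_base(path: str | Path) -> KnowledgeBase:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return kb_from_dict(data)


def write_knowledge_base(kb: KnowledgeBase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(kb_to_dict(kb), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Validation


def validate_knowledge_base(kb: KnowledgeBase) -> list[str]:
    """Check every structural invariant; violations are data, not exceptions.

    Returns an empty list iff the knowledge base is internally consistent:
    unique codes/ids, satisfiable >=3-element compliance rule, type-consistent
    element lists, and fully resolving indicator references.
    """
    violations: list[str] = []

    seen_items: set[str] = set()
    for item in kb.assessment_items:
        if item.item_id in seen_items:
            violations.append(f"duplicate assessment item id {item.item_id!r}")
        seen_items.add(item.item_id)

    seen_dx: set[str] = set()
    for dx in kb.diagnoses:
        if dx.dx_code in seen_dx:
            violations.append(f"duplicate diagnosis code {dx.dx_code!r}")
        seen_dx.add(dx.dx_code)

        if not dx.elements:
            violations.append(f"{dx.dx_code}: diagnosis has no elements")
        seen_el: set[str] = set()
        for e in dx.elements:
            if e.element_id in seen_el:
                violations.append(f"{dx.dx_code}: duplicate element id {e.element_id!r}")
            seen_el.add(e.element_id)

        if dx.dx_type == DxType.ACTUAL:
            if not dx.defining_characteristics:
                violations.append(
                    f"{dx.dx_code}: actual diagnosis has no defining characteristics"
                )
            if dx.risk_factors:
                violations.append(
                    f"{dx.dx_code}: actual diagnosis carries risk factors"
                )
        else:
            if not dx.risk_factors:
                violations.append(f"{dx.dx_code}: risk diagnosis has no risk factors")
            if dx.defining_characteristics:
                violations.append(
                    f"{dx.dx_code}: risk diagnosis carries defining characteristics"
                )
        if len(dx.evidence_elements) < 3:
            violations.append(
                f"{dx.dx_code}: compliance rule unsatisfiable "
                f"(only {len(dx.evidence_elements)} evidence elements, need >= 3)"
            )

    if kb.indicator_table is not None:
        seen_assoc: set[tuple] = set()
        for entry in kb.indicator_table.entries:
            if not kb.resolves(entry.association):
                violations.append(
                    f"indicator references unresolved association {entry.association}"
                )
            key = (entry.association, entry.engine)
            if key in seen_assoc:
                violations.append(
                    f"duplicate indicator for association {entry.association}"
                )
            seen_assoc.add(key)
            if not (0.0 <= entry.score <= 1.0):
                violations.append(
                    f"indicator score {entry.score} outside [0, 1] "
                    f"for {entry.association}"
                )
    return violations


# ---------------------------------------------------------------------------
# Care-plan CSV I/O

CARE_PLAN_COLUMNS = [
    "participant_id",
    "patient_id",
    "group",
    "phase",
    "role",
    "dx_code",
    "identified_elements",
]
ELEMENT_SEPARATOR = "|"


def read_care_plans(path: str | Path, kb: KnowledgeBase | None = None) -> list[CarePlanRecord]:
    """Read care-plan records from CSV.

    One record per (participant, phase, role, diagnosis).  Identified element
    ids unknown to the diagnosis (when ``kb`` is given) are retained and
    flagged invalid rather than dropped.  Duplicate keys and unknown
    group/phase/role tokens are errors.
    """
    records: list[CarePlanRecord] = []
    seen: set[tuple] = set()
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CARE_PLAN_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise KBError(f"care-plan CSV missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            raw = row["identified_elements"].strip()
            elements = frozenset(e for e in raw.split(ELEMENT_SEPARATOR) if e) if raw else frozenset()
            invalid: frozenset[str] = frozenset()
            if kb is not None:
                try:
                    dx = kb.diagnosis(row["dx_code"])
                except KeyError:
                    raise KBError(f"line {lineno}: unknown diagnosis {row['dx_code']!r}")
                known = {e.element_id for e in dx.elements}
                invalid = frozenset(e for e in elements if e not in known)
            try:
                rec = CarePlanRecord(
                    participant_id=row["participant_id"],
                    patient_id=row["patient_id"],
                    group=row["group"],
                    phase=row["phase"],
                    role=row["role"],
                    dx_code=row["dx_code"],
                    identified_elements=elements,
                    invalid_elements=invalid,
                )
            except ValueError as exc:
                raise KBError(f"line {lineno}: {exc}") from exc
            if rec.key in seen:
                raise KBError(f"line {lineno}: duplicate care-plan key {rec.key}")
            seen.add(rec.key)
            records.append(rec)
    return records


def write_care_plans(records: Iterable[CarePlanRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CARE_PLAN_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.participant_id,
                    r.patient_id,
                    r.group,
                    r.phase,
                    r.role,
                    r.dx_code,
                    ELEMENT_SEPARATOR.join(sorted(r.identified_elements)),
                ]
            )
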