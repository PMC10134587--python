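"""Decision-making competency evaluation.

Each nursing student's care plan is compared with the expert researcher's
reference plan for the same patient-diagnosis.  The classification compares
*counts* of taxonomy-valid evidence elements (defining characteristics for
actual diagnoses, risk factors for risk diagnoses):

    equal count  -> true positive (TP)
    more         -> false positive (FP)
    fewer        -> false negative (FN)

so TP/FP/FN partition the participants exactly.  Over participants,
PPV = TP/(TP+FP) and sensitivity = TP/(TP+FN).  A strict set-equality mode is
available (TP only when the identified sets coincide); the count mode is the
default because it reproduces the published partition arithmetic.

Compliance means the student's plan cites at least 3 valid evidence elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Literal, Sequence

from .kb import CarePlanRecord, KBError, KnowledgeBase
from .suggest import adequately_supported


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding used by the printed tables (half-up, not banker's)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ParticipantClassification:
    participant_id: str
    phase: str
    group: str
    outcome: Outcome
    compliant: bool
    n_student_valid: int
    n_researcher_valid: int


ClassificationMode = Literal["count", "set"]


def classify_participant(
    student: CarePlanRecord,
    researcher: CarePlanRecord,
    kb: KnowledgeBase,
    mode: ClassificationMode = "count",
) -> ParticipantClassification:
    """Classify one student-researcher plan pair as TP, FP, or FN."""
    if (
        student.participant_id != researcher.participant_id
        or student.patient_id != researcher.patient_id
        or student.dx_code != researcher.dx_code
        or student.phase != researcher.phase
    ):
        raise KBError(
            "student and researcher records must share participant, patient, "
            f"diagnosis, and phase (got {student.key} vs {researcher.key})"
        )
    if student.role != "student" or researcher.role != "researcher":
        raise KBError("records must carry the student and researcher roles")

    student_valid = student.valid_elements(kb)
    researcher_valid = researcher.valid_elements(kb)
    ns, nr = len(student_valid), len(researcher_valid)
    if ns > nr:
        outcome = Outcome.FP
    elif ns < nr:
        outcome = Outcome.FN
    elif mode == "set" and student_valid != researcher_valid:
        # equal counts but different elements: over- and under-identification
        # balance out; strict mode treats this as over-identification
        outcome = Outcome.FP
    else:
        outcome = Outcome.TP
    return ParticipantClassification(
        participant_id=student.participant_id,
        phase=student.phase,
        group=student.group,
        outcome=outcome,
        compliant=adequately_supported(student, kb),
        n_student_valid=ns,
        n_researcher_valid=nr,
    )


def ppv(tp: int, fp: int) -> float:
    """Positive predictive value TP/(TP+FP)."""
    if tp + fp < 1:
        raise ValueError("PPV undefined: TP + FP = 0")
    return tp / (tp + fp)


def sensitivity(tp: int, fn: int) -> float:
    """Sensitivity TP/(TP+FN)."""
    if tp + fn < 1:
        raise ValueError("sensitivity undefined: TP + FN = 0")
    return tp / (tp + fn)


@dataclass
class CompetencyRow:
    group: str
    phase: str
    tp: int = 0
    fp: int = 0
    fn: int = 0
    compliant: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn

    @property
    def ppv(self) -> float:
        return ppv(self.tp, self.fp)

    @property
    def sensitivity(self) -> float:
        return sensitivity(self.tp, self.fn)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "phase": self.phase,
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "compliant": self.compliant,
            "compliance_pct": round_half_up(100 * self.compliant / self.n) if self.n else None,
            "ppv": round_half_up(self.ppv) if self.tp + self.fp else None,
            "sensitivity": round_half_up(self.sensitivity) if self.tp + self.fn else None,
        }


@dataclass
class CompetencyTable:
    rows: dict[tuple[str, str], CompetencyRow] = field(default_factory=dict)

    def row(self, group: str, phase: str) -> CompetencyRow:
        return self.rows[(group, phase)]

    def to_records(self) -> list[dict]:
        return [self.rows[k].to_dict() for k in sorted(self.rows)]


def aggregate_competency(
    classifications: Iterable[ParticipantClassification],
) -> CompetencyTable:
    """Aggregate per-participant classifications into per-(group, phase)
    TP/FP/FN/compliance counts with PPV and sensitivity.

    Raises if a participant is classified twice within one phase.
    """
    table = CompetencyTable()
    seen: set[tuple[str, str]] = set()
    for c in classifications:
        pk = (c.participant_id, c.phase)
        if pk in seen:
            raise KBError(f"participant {c.participant_id!r} classified twice in {c.phase}")
        seen.add(pk)
        row = table.rows.setdefault(
            (c.group, c.phase), CompetencyRow(group=c.group, phase=c.phase)
        )
        if c.outcome == Outcome.TP:
            row.tp += 1
        elif c.outcome == Outcome.FP:
            row.fp += 1
        else:
            row.fn += 1
        row.compliant += int(c.compliant)
    return table


def pair_care_plans(
    records: Sequence[CarePlanRecord],
) -> list[tuple[CarePlanRecord, CarePlanRecord]]:
    """Match each student plan with the researcher reference plan sharing its
    (participant, phase, diagnosis).  Unpaired records are an error."""
    students = {r.key[:3] + (r.dx_code,): r for r in records if r.role == "student"}
    researchers = {
        (r.participant_id, r.phase, "student", r.dx_code): r
        for r in records
        if r.role == "researcher"
    }
    pairs = []
    for key, student in sorted(students.items()):
        if key not in researchers:
            raise KBError(f"no researcher reference plan for {key}")
        pairs.append((student, researchers[key]))
    unmatched = set(researchers) - set(students)
    if unmatched:
        raise KBError(f"researcher plans without student plans: {sorted(unmatched)[:3]}")
    return pairs


def evaluate_care_plans(
    records: Sequence[CarePlanRecord],
    kb: KnowledgeBase,
    mode: ClassificationMode = "count",
) -> tuple[CompetencyTable, list[ParticipantClassification]]:
    """End-to-end evaluation: pair plans, classify each pair, aggregate."""
    classifications = [
        classify_participant(s, r, kb, mode=mode) for s, r in pair_care_plans(records)
    ]
    return aggregate_competency(classifications), classifications
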