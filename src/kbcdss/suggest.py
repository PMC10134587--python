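"""Guidance generation: turn positive assessment findings plus an indicator
table into ranked, per-diagnosis element lists, and test the >=3-element
diagnostic-support rule.

Diagnoses are ranked by (count of distinct major-level elements, then sum of
scores, then diagnosis code) so the strongest-evidenced diagnosis appears
first and ties break deterministically.  A null "control" mode emulates a
care-planning system without guidance: unscored element lists in taxonomy
order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .kb import (
    CarePlanRecord,
    IndicatorTable,
    KBError,
    KnowledgeBase,
    Level,
)

COMPLIANCE_MIN_ELEMENTS = 3


@dataclass(frozen=True)
class AssessmentFinding:
    patient_id: str
    item_id: str
    present: bool


@dataclass
class GuidanceList:
    patient_id: str
    #: dx_code -> ordered list of (element_id, score, level-name)
    per_diagnosis: dict[str, list[tuple[str, float | None, str | None]]]
    #: ordered (dx_code, n_major, score_sum), strongest first
    ranking: list[tuple[str, int, float]]

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "per_diagnosis": {
                dx: [
                    {"element_id": el, "score": score, "level": level}
                    for el, score, level in entries
                ]
                for dx, entries in self.per_diagnosis.items()
            },
            "ranking": [
                {"dx_code": dx, "n_major": n, "score_sum": s} for dx, n, s in self.ranking
            ],
        }


def generate_guidance(
    findings: Iterable[AssessmentFinding],
    table: IndicatorTable,
    kb: KnowledgeBase,
) -> GuidanceList:
    """Collect displayable indicator entries triggered by positive findings.

    Within a diagnosis, elements implicated by several findings are
    deduplicated keeping the maximum score (strongest evidence shown).
    Deterministic: identical inputs yield identical output.
    """
    findings = list(findings)
    for f in findings:
        if not kb.has_item(f.item_id):
            raise KBError(f"finding references unknown assessment item {f.item_id!r}")
    patient_ids = {f.patient_id for f in findings}
    patient_id = sorted(patient_ids)[0] if patient_ids else ""

    positive_items = {f.item_id for f in findings if f.present}
    # dx -> element -> (score, level)
    best: dict[str, dict[str, tuple[float, Level]]] = {}
    for entry in table.displayable():
        item_id, dx_code, element_id = entry.association
        if item_id not in positive_items:
            continue
        per_dx = best.setdefault(dx_code, {})
        if element_id not in per_dx or entry.score > per_dx[element_id][0]:
            per_dx[element_id] = (entry.score, entry.level)

    per_diagnosis: dict[str, list[tuple[str, float | None, str | None]]] = {}
    for dx_code in sorted(best):
        ordered = sorted(
            best[dx_code].items(), key=lambda kv: (-kv[1][0], kv[0])
        )  # score desc, then element id
        per_diagnosis[dx_code] = [
            (el, score, level.value) for el, (score, level) in ordered
        ]
    ranking = _rank(best)
    per_diagnosis = {dx: per_diagnosis[dx] for dx, _, _ in ranking}
    return GuidanceList(patient_id=patient_id, per_diagnosis=per_diagnosis, ranking=ranking)


def _rank(best: dict[str, dict[str, tuple[float, Level]]]) -> list[tuple[str, int, float]]:
    rows = []
    for dx_code, elements in best.items():
        n_major = sum(1 for score, level in elements.values() if level == Level.MAJOR)
        score_sum = sum(score for score, _ in elements.values())
        rows.append((dx_code, n_major, score_sum))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    return rows


def unguided_element_list(kb: KnowledgeBase, dx_code: str) -> list[str]:
    """Control-arm null engine: the diagnosis's elements in taxonomy order,
    with no scores and no ranking (a care-planning system without guidance)."""
    return [e.element_id for e in kb.diagnosis(dx_code).elements]


def adequately_supported(
    plan: CarePlanRecord,
    kb: KnowledgeBase,
    min_elements: int = COMPLIANCE_MIN_ELEMENTS,
) -> bool:
    """Compliance rule: the plan cites >= 3 distinct taxonomy-valid evidence
    elements (defining characteristics for actual diagnoses, risk factors for
    risk diagnoses).  Flagged-invalid elements never count."""
    valid = plan.valid_elements(kb) - plan.invalid_elements
    return len(valid) >= min_elements


# ---------------------------------------------------------------------------
# I/O

FINDINGS_COLUMNS = ["patient_id", "item_id", "present"]


def read_findings(path: str | Path) -> list[AssessmentFinding]:
    out: list[AssessmentFinding] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(FINDINGS_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise KBError(f"findings CSV missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                present = bool(int(row["present"]))
            except ValueError as exc:
                raise KBError(f"line {lineno}: boolean tokens must be 0/1") from exc
            out.append(
                AssessmentFinding(
                    patient_id=row["patient_id"], item_id=row["item_id"], present=present
                )
            )
    return out


def write_guidance_json(guidance: GuidanceList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(guidance.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_guidance_tsv(guidance: GuidanceList, path: str | Path) -> None:
    """Human-readable flat listing, ranking order."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdx_code\telement_id\tscore\tlevel\n")
        for rank, (dx_code, _, _) in enumerate(guidance.ranking, start=1):
            for element_id, score, level in guidance.per_diagnosis[dx_code]:
                score_txt = "" if score is None else f"{score:.2f}"
                fh.write(f"{rank}\t{dx_code}\t{element_id}\t{score_txt}\t{level or ''}\n")
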