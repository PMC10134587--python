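"""Seeded synthetic-data generator.

Emulates every input the decision-support system and its evaluation study
consume: a mock 22-diagnosis knowledge base over the five-aspect assessment
framework (a neutral stand-in taxonomy — no copyrighted diagnosis content),
paired junior/senior rater observation streams with tunable agreement, patient
co-occurrence registries for the Bayesian engine, and three-arm pre/post
cohorts of student and researcher care plans with arm-specific identification
fidelity.

Arm effects are modelled as identification-fidelity shifts: a student
identifies each truly present evidence element with probability ``fidelity``
and adds each absent (but taxonomy-valid) element with probability
``overidentification``.  The researcher's plan is the latent truth restricted
to the taxonomy.  The generator's job is to exercise the evaluator and the
statistics, not to model the guidance screen cognitively.

All randomness flows through ``numpy.random.default_rng`` seeded from the
config, with a distinct child stream per generator, so every artifact is
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bayes import RegistryCounts
from .cdv import RaterObservation
from .kb import (
    ASPECTS,
    GROUPS,
    PHASES,
    AssessmentItem,
    Association,
    CarePlanRecord,
    Diagnosis,
    DiagnosisElement,
    DxType,
    ElementType,
    KnowledgeBase,
)


def _default_fidelity() -> dict:
    # pretest: all arms equal (paper-based plans, no system guidance anywhere);
    # posttest: guidance quality orders the arms CDV > BADE > control
    return {
        "pretest": {"control": 0.55, "cdv": 0.55, "bade": 0.55},
        "posttest": {"control": 0.57, "cdv": 0.88, "bade": 0.75},
    }


def _default_overidentification() -> dict:
    return {
        "pretest": {"control": 0.22, "cdv": 0.22, "bade": 0.22},
        "posttest": {"control": 0.20, "cdv": 0.06, "bade": 0.10},
    }


def _default_cohort_sizes() -> dict:
    return {"control": 206, "cdv": 203, "bade": 198}


@dataclass
class SimulationConfig:
    seed: int = 0
    n_diagnoses: int = 22
    n_aspects: int = 5  # fixed by the assessment framework
    n_items_per_aspect: int = 6
    n_elements_per_diagnosis: int = 6
    risk_fraction: float = 0.2  # fraction of diagnoses that are risk-type
    n_patients: int = 120  # patients behind rater observations / registry
    rater_agreement: float = 0.9  # P(rater reports the latent truth)
    element_prevalence: float = 0.5  # P(element truly present in a patient)
    registry_sensitivity: float = 0.85  # P(assessment + | element present)
    registry_false_positive: float = 0.15  # P(assessment + | element absent)
    truth_element_rate: float = 0.7  # P(evidence element present in a care case)
    cohort_sizes: dict = field(default_factory=_default_cohort_sizes)
    fidelity: dict = field(default_factory=_default_fidelity)
    overidentification: dict = field(default_factory=_default_overidentification)

    def validate(self) -> None:
        if self.n_aspects != len(ASPECTS):
            raise ValueError(f"the assessment framework has exactly {len(ASPECTS)} aspects")
        for name in ("n_diagnoses", "n_items_per_aspect", "n_patients"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_elements_per_diagnosis < 3:
            raise ValueError(
                "n_elements_per_diagnosis < 3 makes the >=3-element compliance "
                "rule unsatisfiable"
            )
        probs = {
            "risk_fraction": self.risk_fraction,
            "rater_agreement": self.rater_agreement,
            "element_prevalence": self.element_prevalence,
            "registry_sensitivity": self.registry_sensitivity,
            "registry_false_positive": self.registry_false_positive,
            "truth_element_rate": self.truth_element_rate,
        }
        for phase in PHASES:
            for group in GROUPS:
                probs[f"fidelity[{phase}][{group}]"] = self.fidelity[phase][group]
                probs[f"overidentification[{phase}][{group}]"] = self.overidentification[
                    phase
                ][group]
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} = {p} outside [0, 1]")
        for group in GROUPS:
            if self.cohort_sizes[group] < 1:
                raise ValueError(f"cohort size for {group} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        cfg = cls(**dict(data))
        cfg.validate()
        return cfg


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def generate_mock_kb(config: SimulationConfig) -> KnowledgeBase:
    """Deterministic mock knowledge base: ``n_diagnoses`` diagnoses (a seeded
    subset risk-type), each with >= 3 evidence elements, and assessment items
    spread evenly across the five aspects."""
    config.validate()
    rng = _rng(config, 0)

    items = [
        AssessmentItem(
            item_id=f"AI-{a * config.n_items_per_aspect + k + 1:03d}",
            aspect=ASPECTS[a],
            label=f"Mock assessment item {k + 1} ({ASPECTS[a]} aspect)",
        )
        for a in range(config.n_aspects)
        for k in range(config.n_items_per_aspect)
    ]

    n_risk = round(config.risk_fraction * config.n_diagnoses)
    risk_idx = set(
        rng.choice(config.n_diagnoses, size=n_risk, replace=False).tolist()
    )
    diagnoses = []
    for i in range(config.n_diagnoses):
        dx_code = f"DX-{i + 1:03d}"
        if i in risk_idx:
            elements = tuple(
                DiagnosisElement(
                    element_id=f"{dx_code}-RF-{j + 1:02d}",
                    element_type=ElementType.RISK_FACTOR,
                    label=f"Mock risk factor {j + 1} of diagnosis {i + 1}",
                )
                for j in range(config.n_elements_per_diagnosis)
            )
            dx_type = DxType.RISK
        else:
            # one related factor when there is room beyond the 3-DC minimum
            n_related = 1 if config.n_elements_per_diagnosis >= 4 else 0
            n_dc = config.n_elements_per_diagnosis - n_related
            elements = tuple(
                DiagnosisElement(
                    element_id=f"{dx_code}-DC-{j + 1:02d}",
                    element_type=ElementType.DEFINING_CHARACTERISTIC,
                    label=f"Mock defining characteristic {j + 1} of diagnosis {i + 1}",
                )
                for j in range(n_dc)
            ) + tuple(
                DiagnosisElement(
                    element_id=f"{dx_code}-REL-{j + 1:02d}",
                    element_type=ElementType.RELATED_FACTOR,
                    label=f"Mock related factor {j + 1} of diagnosis {i + 1}",
                )
                for j in range(n_related)
            )
            dx_type = DxType.ACTUAL
        diagnoses.append(
            Diagnosis(
                dx_code=dx_code,
                label=f"Mock diagnosis {i + 1}",
                dx_type=dx_type,
                elements=elements,
            )
        )
    return KnowledgeBase(
        diagnoses=diagnoses,
        assessment_items=items,
        provenance={"engine": "synthetic", "seed": config.seed, "config": config.to_dict()},
    )


def default_associations(kb: KnowledgeBase) -> list[Association]:
    """Stable assessment-item -> element association map.

    Element ``j`` of diagnosis ``i`` links to item index ``(7 i + 3 j) mod
    n_items`` — a fixed arithmetic rule, so the map never depends on hashing
    or iteration order.
    """
    n_items = len(kb.assessment_items)
    out: list[Association] = []
    for i, dx in enumerate(kb.diagnoses):
        for j, el in enumerate(dx.elements):
            item = kb.assessment_items[(7 * i + 3 * j) % n_items]
            out.append((item.item_id, dx.dx_code, el.element_id))
    return out


def simulate_rater_observations(
    kb: KnowledgeBase, config: SimulationConfig
) -> list[RaterObservation]:
    """Paired junior/senior observations under the latent-truth noise model.

    Per patient and association the latent truth is Bernoulli(prevalence);
    each rater independently reports the truth with probability
    ``rater_agreement`` and its flip otherwise.
    """
    config.validate()
    rng = _rng(config, 1)
    associations = default_associations(kb)
    n, m = config.n_patients, len(associations)
    truth = rng.random((m, n)) < config.element_prevalence
    junior_ok = rng.random((m, n)) < config.rater_agreement
    senior_ok = rng.random((m, n)) < config.rater_agreement
    junior = np.where(junior_ok, truth, ~truth)
    senior = np.where(senior_ok, truth, ~truth)
    return [
        RaterObservation(
            patient_id=f"PT-{p + 1:04d}",
            association=assoc,
            junior_present=bool(junior[a, p]),
            senior_present=bool(senior[a, p]),
        )
        for a, assoc in enumerate(associations)
        for p in range(n)
    ]


def simulate_registry(kb: KnowledgeBase, config: SimulationConfig) -> list[RegistryCounts]:
    """Patient co-occurrence registry for the Bayesian engine: per association,
    a 2x2 table from ``n_patients`` patients with element prevalence
    ``element_prevalence``, assessment sensitivity ``registry_sensitivity``
    and false-positive rate ``registry_false_positive``."""
    config.validate()
    rng = _rng(config, 2)
    out = []
    for assoc in default_associations(kb):
        dc = rng.random(config.n_patients) < config.element_prevalence
        pos = np.where(
            dc,
            rng.random(config.n_patients) < config.registry_sensitivity,
            rng.random(config.n_patients) < config.registry_false_positive,
        )
        out.append(
            RegistryCounts(
                association=assoc,
                n_pos_dc=int((pos & dc).sum()),
                n_neg_dc=int((~pos & dc).sum()),
                n_pos_nondc=int((pos & ~dc).sum()),
                n_neg_nondc=int((~pos & ~dc).sum()),
            )
        )
    return out


def simulate_cohort(kb: KnowledgeBase, config: SimulationConfig) -> list[CarePlanRecord]:
    """Three-arm pre/post cohort of student and researcher care plans.

    One evaluated diagnosis per participant per phase.  The researcher plan is
    the latent truth (each evidence element present with probability
    ``truth_element_rate``, at least one guaranteed); the student keeps each
    true element with the arm/phase fidelity and adds each absent valid
    element at the arm/phase over-identification rate.
    """
    config.validate()
    rng = _rng(config, 3)
    records: list[CarePlanRecord] = []
    participant_no = 0
    for group in GROUPS:
        for _ in range(config.cohort_sizes[group]):
            participant_no += 1
            pid = f"P-{participant_no:04d}"
            patient = f"PT-{participant_no:04d}"
            for phase in PHASES:
                dx = kb.diagnoses[int(rng.integers(len(kb.diagnoses)))]
                evidence = [e.element_id for e in dx.evidence_elements]
                present = rng.random(len(evidence)) < config.truth_element_rate
                if not present.any():
                    present[int(rng.integers(len(evidence)))] = True
                truth = {el for el, p in zip(evidence, present) if p}
                f = config.fidelity[phase][group]
                g = config.overidentification[phase][group]
                kept = {el for el in truth if rng.random() < f}
                added = {el for el in evidence if el not in truth and rng.random() < g}
                records.append(
                    CarePlanRecord(
                        participant_id=pid,
                        patient_id=patient,
                        group=group,
                        phase=phase,
                        role="researcher",
                        dx_code=dx.dx_code,
                        identified_elements=frozenset(truth),
                    )
                )
                records.append(
                    CarePlanRecord(
                        participant_id=pid,
                        patient_id=patient,
                        group=group,
                        phase=phase,
                        role="student",
                        dx_code=dx.dx_code,
                        identified_elements=frozenset(kept | added),
                    )
                )
    return records


def empirical_identification_rates(
    records: Sequence[CarePlanRecord],
) -> dict[tuple[str, str], float]:
    """Per-(group, phase) fraction of researcher-identified (true) elements
    that the paired student also identified — the estimator the parameter-
    recovery check uses to recover the configured fidelities."""
    students = {(r.participant_id, r.phase): r for r in records if r.role == "student"}
    hits: dict[tuple[str, str], list[int]] = {}
    for r in records:
        if r.role != "researcher":
            continue
        student = students[(r.participant_id, r.phase)]
        kept = len(r.identified_elements & student.identified_elements)
        acc = hits.setdefault((r.group, r.phase), [0, 0])
        acc[0] += kept
        acc[1] += len(r.identified_elements)
    return {key: kept / total for key, (kept, total) in hits.items() if total}
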