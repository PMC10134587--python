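"""Clinical Diagnostic Validity (CDV) inference engine.

Builds indicator tables from paired junior/senior nurse observations.  For
each (assessment item, diagnosis, element) association the engine computes
the weighted interrater reliability ratio

    R = [(F1/N + F2/N) / 2] * [A / (A + D)]

where F1 and F2 are the junior and senior positive-observation frequencies,
N the number of patients observed for the association, and A / D the counts
of agreements / disagreements between the two raters.  R >= 0.80 marks a
*major* indicator, 0.50 <= R < 0.80 a *minor* one; lower scores are retained
but never displayed as guidance.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .kb import (
    Association,
    IndicatorEntry,
    IndicatorTable,
    KBError,
    KnowledgeBase,
    Level,
)

MAJOR_THRESHOLD = 0.80
MINOR_THRESHOLD = 0.50

AgreementMode = Literal["both_states", "presence_only"]


@dataclass(frozen=True)
class RaterObservation:
    patient_id: str
    association: Association
    junior_present: bool
    senior_present: bool


@dataclass(frozen=True)
class AgreementTally:
    association: Association
    F1: int  # junior-positive patients
    F2: int  # senior-positive patients
    N: int  # patients observed for this association
    A: int  # agreements
    D: int  # disagreements

    def __post_init__(self):
        if min(self.F1, self.F2, self.N, self.A, self.D) < 0:
            raise ValueError("tally counts must be non-negative")
        if self.F1 > self.N or self.F2 > self.N:
            raise ValueError("F1 and F2 cannot exceed N")
        if self.A + self.D != self.N:
            raise ValueError("A + D must equal N")


def tally_rater_agreement(
    observations: Iterable[RaterObservation],
    agreement_mode: AgreementMode = "both_states",
) -> list[AgreementTally]:
    """Count per-association rater frequencies and (dis)agreements.

    In the default ``both_states`` mode an agreement is a patient for whom the
    two raters coincide on presence *or* absence (the interrater-reliability
    convention); ``presence_only`` counts only joint-presence as agreement.
    Each (patient, association) pair may appear at most once.
    """
    acc: dict[Association, list[int]] = {}
    seen: set[tuple[str, Association]] = set()
    for obs in observations:
        key = (obs.patient_id, obs.association)
        if key in seen:
            raise KBError(f"duplicate observation for {key}")
        seen.add(key)
        f1, f2, n, a = acc.setdefault(obs.association, [0, 0, 0, 0])
        acc[obs.association][0] = f1 + int(obs.junior_present)
        acc[obs.association][1] = f2 + int(obs.senior_present)
        acc[obs.association][2] = n + 1
        if agreement_mode == "both_states":
            agree = obs.junior_present == obs.senior_present
        else:
            agree = obs.junior_present and obs.senior_present
        acc[obs.association][3] = a + int(agree)
    return [
        AgreementTally(association=assoc, F1=f1, F2=f2, N=n, A=a, D=n - a)
        for assoc, (f1, f2, n, a) in sorted(acc.items())
    ]


def cdv_weighted_ratio(F1: int, F2: int, N: int, A: int, D: int) -> float:
    """The CDV weighted interrater reliability ratio R, in [0, 1]."""
    if N < 1 or A + D == 0:
        raise ValueError("weighted ratio undefined for N = 0")
    if A + D != N:
        raise ValueError("A + D must equal N")
    if F1 > N or F2 > N or min(F1, F2, A, D) < 0:
        raise ValueError("invalid tally counts")
    return ((F1 / N + F2 / N) / 2) * (A / (A + D))


def classify_ratio(
    r: float,
    major: float = MAJOR_THRESHOLD,
    minor: float = MINOR_THRESHOLD,
) -> Level:
    """Map a weighted ratio to its display level: >=0.80 major, 0.50-0.80 minor."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"ratio {r} outside [0, 1]")
    if r >= major:
        return Level.MAJOR
    if r >= minor:
        return Level.MINOR
    return Level.EXCLUDED


def build_cdv_indicators(
    observations: Iterable[RaterObservation],
    kb: KnowledgeBase,
    agreement_mode: AgreementMode = "both_states",
    major: float = MAJOR_THRESHOLD,
    minor: float = MINOR_THRESHOLD,
) -> IndicatorTable:
    """Build the CDV indicator table from paired rater observations.

    Excluded-level entries (R < 0.50) are retained in the table so the build
    is reproducible, but they are non-displayable as guidance.
    """
    observations = list(observations)
    for obs in observations:
        if not kb.resolves(obs.association):
            raise KBError(f"observation references unknown association {obs.association}")
    tallies = tally_rater_agreement(observations, agreement_mode=agreement_mode)
    entries = [
        IndicatorEntry(
            association=t.association,
            score=cdv_weighted_ratio(t.F1, t.F2, t.N, t.A, t.D),
            level=classify_ratio(
                cdv_weighted_ratio(t.F1, t.F2, t.N, t.A, t.D), major=major, minor=minor
            ),
            engine="cdv",
        )
        for t in tallies
    ]
    return IndicatorTable(
        entries=entries,
        engine="cdv",
        params={"agreement_mode": agreement_mode, "major": major, "minor": minor},
    )


OBSERVATION_COLUMNS = [
    "patient_id",
    "item_id",
    "dx_code",
    "element_id",
    "junior_present",
    "senior_present",
]


def read_rater_observations(path: str | Path) -> list[RaterObservation]:
    """Read paired-rater observations from CSV (boolean tokens 0/1)."""
    out: list[RaterObservation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(OBSERVATION_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise KBError(f"observation CSV missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                junior = bool(int(row["junior_present"]))
                senior = bool(int(row["senior_present"]))
            except ValueError as exc:
                raise KBError(f"line {lineno}: boolean tokens must be 0/1") from exc
            out.append(
                RaterObservation(
                    patient_id=row["patient_id"],
                    association=(row["item_id"], row["dx_code"], row["element_id"]),
                    junior_present=junior,
                    senior_present=senior,
                )
            )
    return out


def write_rater_observations(observations: Sequence[RaterObservation], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(OBSERVATION_COLUMNS)
        for o in observations:
            writer.writerow(
                [
                    o.patient_id,
                    *o.association,
                    int(o.junior_present),
                    int(o.senior_present),
                ]
            )
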