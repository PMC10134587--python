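"""Bayesian decision-model inference engine.

Scores each (assessment item, diagnosis, element) association with the
posterior probability that the diagnosis element is present given a positive
assessment finding:

    P(DC|+) = P(+|DC) P(DC) / [ P(+|DC) P(DC) + P(+|Non_DC) P(Non_DC) ]

The three probabilities are estimated by relative frequency from a patient
co-occurrence registry — a 2x2 table per association cross-classifying the
assessment finding (+/-) against element presence (DC / Non_DC) — with
optional Laplace-style smoothing.  Three association families (assessment
item -> defining characteristic, defining characteristic -> related factor,
assessment item -> risk factor) share this one registry schema, distinguished
by the element's type in the knowledge base.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .cdv import MAJOR_THRESHOLD, MINOR_THRESHOLD, classify_ratio
from .kb import Association, IndicatorEntry, IndicatorTable, KBError, KnowledgeBase


@dataclass(frozen=True)
class RegistryCounts:
    """Per-association 2x2 co-occurrence counts.

    ``n_pos_dc``: assessment positive and element present, etc.
    """

    association: Association
    n_pos_dc: int
    n_neg_dc: int
    n_pos_nondc: int
    n_neg_nondc: int

    def __post_init__(self):
        cells = (self.n_pos_dc, self.n_neg_dc, self.n_pos_nondc, self.n_neg_nondc)
        if any(c < 0 or c != int(c) for c in cells):
            raise ValueError("registry counts must be non-negative integers")
        if sum(cells) < 1:
            raise ValueError("registry must contain at least one patient")

    @property
    def total(self) -> int:
        return self.n_pos_dc + self.n_neg_dc + self.n_pos_nondc + self.n_neg_nondc


@dataclass(frozen=True)
class ProbabilityTriple:
    p_pos_given_dc: float
    p_dc: float
    p_pos_given_nondc: float

    def __post_init__(self):
        for name in ("p_pos_given_dc", "p_dc", "p_pos_given_nondc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


def estimate_probabilities(counts: RegistryCounts, smoothing: float = 0.0) -> ProbabilityTriple:
    """Relative-frequency estimates of P(+|DC), P(DC), P(+|Non_DC).

    ``smoothing`` adds a symmetric pseudo-count to each binomial cell.  With
    smoothing 0 an empty DC or Non-DC margin makes the conditional undefined
    and raises.
    """
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")
    s = smoothing
    dc_margin = counts.n_pos_dc + counts.n_neg_dc
    nondc_margin = counts.n_pos_nondc + counts.n_neg_nondc
    if s == 0 and (dc_margin == 0 or nondc_margin == 0):
        raise ZeroDivisionError(
            f"empty margin for {counts.association} with smoothing 0 "
            f"(DC margin {dc_margin}, non-DC margin {nondc_margin})"
        )
    return ProbabilityTriple(
        p_pos_given_dc=(counts.n_pos_dc + s) / (dc_margin + 2 * s),
        p_dc=(dc_margin + s) / (counts.total + 2 * s),
        p_pos_given_nondc=(counts.n_pos_nondc + s) / (nondc_margin + 2 * s),
    )


def bayes_posterior(p: ProbabilityTriple) -> float:
    """Posterior P(DC|+) from the probability triple; raises on an impossible
    finding (zero probability under both hypotheses)."""
    numerator = p.p_pos_given_dc * p.p_dc
    denominator = numerator + p.p_pos_given_nondc * (1.0 - p.p_dc)
    if denominator == 0:
        raise ZeroDivisionError(
            "assessment finding has zero probability under both hypotheses"
        )
    return numerator / denominator


def build_bayes_indicators(
    registry: Iterable[RegistryCounts],
    kb: KnowledgeBase,
    smoothing: float = 0.0,
    major: float = MAJOR_THRESHOLD,
    minor: float = MINOR_THRESHOLD,
) -> IndicatorTable:
    """Build the Bayesian indicator table from a co-occurrence registry.

    Display thresholds default to the CDV bands (major >= 0.80, minor
    0.50-0.80) for parity between the two engines.
    """
    entries = []
    for counts in registry:
        if not kb.resolves(counts.association):
            raise KBError(f"registry references unknown association {counts.association}")
        score = bayes_posterior(estimate_probabilities(counts, smoothing=smoothing))
        entries.append(
            IndicatorEntry(
                association=counts.association,
                score=score,
                level=classify_ratio(score, major=major, minor=minor),
                engine="bayes",
            )
        )
    entries.sort(key=lambda e: e.association)
    return IndicatorTable(
        entries=entries,
        engine="bayes",
        params={"smoothing": smoothing, "major": major, "minor": minor},
    )


REGISTRY_COLUMNS = [
    "item_id",
    "dx_code",
    "element_id",
    "n_pos_dc",
    "n_neg_dc",
    "n_pos_nondc",
    "n_neg_nondc",
]


def read_registry(path: str | Path) -> list[RegistryCounts]:
    out: list[RegistryCounts] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(REGISTRY_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise KBError(f"registry CSV missing columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                out.append(
                    RegistryCounts(
                        association=(row["item_id"], row["dx_code"], row["element_id"]),
                        n_pos_dc=int(row["n_pos_dc"]),
                        n_neg_dc=int(row["n_neg_dc"]),
                        n_pos_nondc=int(row["n_pos_nondc"]),
                        n_neg_nondc=int(row["n_neg_nondc"]),
                    )
                )
            except ValueError as exc:
                raise KBError(f"line {lineno}: {exc}") from exc
    return out


def write_registry(registry: Sequence[RegistryCounts], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(REGISTRY_COLUMNS)
        for r in registry:
            writer.writerow(
                [*r.association, r.n_pos_dc, r.n_neg_dc, r.n_pos_nondc, r.n_neg_nondc]
            )
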