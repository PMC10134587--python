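"""Recompute the published competency results from the shipped count tables.

The package ships the study's printed pre/post count tables (per-arm TP, FP,
FN and compliance counts plus the published PPV, sensitivity, percentages and
chi-square statistics).  ``run_study_reproduction`` re-derives every derived
quantity from the raw counts through this package's own routines and diffs
them against the printed values at the tables' 2-decimal display precision —
a tamper-evident check that the evaluator and the chi-square implementation
reproduce the published arithmetic.

ANOVA F statistics re-derived from printed (n, mean, SD) summaries carry the
summaries' own rounding error, so they are compared at a relative 0.5%
tolerance rather than at 2 decimals.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

from .competency import ppv, round_half_up, sensitivity
from .group_stats import GroupSummary, anova_from_summary, pearson_chi_square

OUTCOMES = ("compliance", "false_positive", "false_negative", "true_positive")
ANOVA_RELATIVE_TOLERANCE = 0.005


def load_fixture(name: str, fixtures_dir: str | Path | None = None) -> dict:
    """Load a packaged count-table fixture (or one from ``fixtures_dir``)."""
    if fixtures_dir is not None:
        with open(Path(fixtures_dir) / name, encoding="utf-8") as fh:
            return json.load(fh)
    with resources.files("kbcdss.data").joinpath(name).open(encoding="utf-8") as fh:
        return json.load(fh)


def _diff(name: str, computed: float, printed: float, report: dict, tol: float = 0.0):
    entry = {
        "computed": computed,
        "printed": printed,
        "match": bool(abs(computed - printed) <= tol),
    }
    report["cells"][name] = entry
    if not entry["match"]:
        report["mismatches"].append(name)


def reproduce_table(fixture: dict) -> dict:
    """Recompute one count table's derived statistics and diff against print."""
    groups = fixture["groups"]
    ns = fixture["n"]
    counts = fixture["counts"]
    printed = fixture["printed"]
    report: dict = {"phase": fixture.get("phase"), "cells": {}, "mismatches": []}

    tp, fp, fn = (
        {g: counts["true_positive"][g] for g in groups},
        {g: counts["false_positive"][g] for g in groups},
        {g: counts["false_negative"][g] for g in groups},
    )

    # partition: TP + FP + FN must exhaust each arm
    for g in groups:
        report["cells"][f"partition/{g}"] = {
            "computed": tp[g] + fp[g] + fn[g],
            "printed": ns[g],
            "match": tp[g] + fp[g] + fn[g] == ns[g],
        }
        if not report["cells"][f"partition/{g}"]["match"]:
            report["mismatches"].append(f"partition/{g}")

    for g in groups:
        if g in printed["ppv"]:
            _diff(f"ppv/{g}", round_half_up(ppv(tp[g], fp[g])), printed["ppv"][g], report)
        if g in printed["sensitivity"]:
            _diff(
                f"sensitivity/{g}",
                round_half_up(sensitivity(tp[g], fn[g])),
                printed["sensitivity"][g],
                report,
            )
    if "total" in printed.get("ppv", {}):
        _diff(
            "ppv/total",
            round_half_up(ppv(sum(tp.values()), sum(fp.values()))),
            printed["ppv"]["total"],
            report,
        )
    if "total" in printed.get("sensitivity", {}):
        _diff(
            "sensitivity/total",
            round_half_up(sensitivity(sum(tp.values()), sum(fn.values()))),
            printed["sensitivity"]["total"],
            report,
        )

    for outcome in OUTCOMES:
        row = [counts[outcome][g] for g in groups]
        table = [row, [ns[g] - c for g, c in zip(groups, row)]]
        _diff(
            f"chi_square/{outcome}",
            round_half_up(pearson_chi_square(table).statistic),
            printed["chi_square"][outcome],
            report,
        )
        for g in groups:
            _diff(
                f"percentage/{outcome}/{g}",
                round_half_up(100 * counts[outcome][g] / ns[g]),
                printed["percentages"][outcome][g],
                report,
            )

    if "age_summary" in fixture:
        summaries = [
            GroupSummary(n=int(v[0]), mean=v[1], sd=v[2], label=g)
            for g, v in fixture["age_summary"].items()
        ]
        f = anova_from_summary(summaries).statistic
        _diff(
            "anova_f/age",
            f,
            fixture["printed_age_f"],
            report,
            tol=ANOVA_RELATIVE_TOLERANCE * fixture["printed_age_f"],
        )

    report["all_match"] = not report["mismatches"]
    return report


def run_study_reproduction(fixtures_dir: str | Path | None = None) -> dict:
    """Reproduce both shipped count tables; returns the combined diff report."""
    report = {
        "pretest": reproduce_table(load_fixture("table1_counts.json", fixtures_dir)),
        "posttest": reproduce_table(load_fixture("table4_counts.json", fixtures_dir)),
    }
    report["all_match"] = report["pretest"]["all_match"] and report["posttest"]["all_match"]
    return report
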