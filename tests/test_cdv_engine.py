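"""CDV engine: weighted-ratio arithmetic, tallying, classification bands,
and brute-force equivalence on exhaustively enumerated rater patterns."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from kbcdss.cdv import (
    AgreementTally,
    RaterObservation,
    build_cdv_indicators,
    cdv_weighted_ratio,
    classify_ratio,
    tally_rater_agreement,
)
from kbcdss.kb import KBError, Level

ASSOC = ("AI-001", "DX-001", "DX-001-DC-01")


def obs(patterns):
    """Build one observation per patient from (junior, senior) boolean pairs."""
    return [
        RaterObservation(f"PT-{i}", ASSOC, junior_present=j, senior_present=s)
        for i, (j, s) in enumerate(patterns)
    ]


class TestTally:
    def test_perfect_agreement(self):
        (t,) = tally_rater_agreement(obs([(True, True)] * 10))
        assert (t.F1, t.F2, t.N, t.A, t.D) == (10, 10, 10, 10, 0)

    def test_hand_enumerated_mixed_pattern(self):
        # junior positive on 8, senior on those 8 plus one more, one patient
        # negative for both: agreements = 8 joint-present + 1 joint-absent
        patterns = [(True, True)] * 8 + [(False, True), (False, False)]
        (t,) = tally_rater_agreement(obs(patterns))
        assert (t.F1, t.F2, t.N, t.A, t.D) == (8, 9, 10, 9, 1)

    def test_empty_input(self):
        assert tally_rater_agreement([]) == []

    def test_duplicate_patient_association_rejected(self):
        rows = obs([(True, True)]) * 2
        with pytest.raises(KBError, match="duplicate"):
            tally_rater_agreement(rows)

    def test_presence_only_mode(self):
        patterns = [(True, True), (False, False), (True, False)]
        (t,) = tally_rater_agreement(obs(patterns), agreement_mode="presence_only")
        assert (t.A, t.D) == (1, 2)  # joint absence no longer counts

    def test_tally_invariants_enforced(self):
        with pytest.raises(ValueError):
            AgreementTally(ASSOC, F1=5, F2=0, N=4, A=4, D=0)
        with pytest.raises(ValueError):
            AgreementTally(ASSOC, F1=2, F2=2, N=4, A=2, D=1)


class TestWeightedRatio:
    @pytest.mark.parametrize(
        "tally, expected",
        [
            ((10, 10, 10, 10, 0), 1.0),
            ((0, 0, 5, 5, 0), 0.0),
            ((8, 9, 10, 8, 2), 0.68),
        ],
    )
    def test_examples(self, tally, expected):
        assert cdv_weighted_ratio(*tally) == pytest.approx(expected)

    def test_undefined_for_no_patients(self):
        with pytest.raises(ValueError):
            cdv_weighted_ratio(0, 0, 0, 0, 0)

    def test_frequency_above_n_rejected(self):
        with pytest.raises(ValueError):
            cdv_weighted_ratio(6, 2, 5, 5, 0)

    @given(
        n=st.integers(1, 30),
        data=st.data(),
    )
    def test_monotone_in_agreement_and_frequencies(self, n, data):
        f1 = data.draw(st.integers(0, n))
        f2 = data.draw(st.integers(0, n))
        a = data.draw(st.integers(0, n - 1))
        r_low = cdv_weighted_ratio(f1, f2, n, a, n - a)
        r_high = cdv_weighted_ratio(f1, f2, n, a + 1, n - a - 1)
        assert r_high > r_low or (f1 == f2 == 0)
        if f1 < n:
            assert cdv_weighted_ratio(f1 + 1, f2, n, a + 1, n - a - 1) > cdv_weighted_ratio(
                f1, f2, n, a + 1, n - a - 1
            ) or a + 1 == 0

    @given(n=st.integers(1, 30), data=st.data())
    def test_bound_and_unity_condition(self, n, data):
        f1 = data.draw(st.integers(0, n))
        f2 = data.draw(st.integers(0, n))
        a = data.draw(st.integers(0, n))
        r = cdv_weighted_ratio(f1, f2, n, a, n - a)
        assert r <= min(1.0, (f1 + f2) / (2 * n)) + 1e-12
        if r == 1.0:
            assert f1 == f2 == n and a == n


class TestClassify:
    @pytest.mark.parametrize(
        "r, level",
        [
            (0.80, Level.MAJOR),
            (0.95, Level.MAJOR),
            (0.50, Level.MINOR),
            (0.79, Level.MINOR),
            (0.49, Level.EXCLUDED),
            (0.0, Level.EXCLUDED),
        ],
    )
    def test_bands(self, r, level):
        assert classify_ratio(r) == level

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_ratio(1.2)


class TestBuildIndicators:
    def test_composition_example_presence_only(self, tiny_kb):
        # junior positive on 8, senior on those 8 plus one more, one joint
        # absence: presence-only agreement gives the (8, 9, 10, 8, 2) tally,
        # hence R = ((0.8 + 0.9)/2) * 0.8 = 0.68, a minor indicator
        patterns = [(True, True)] * 8 + [(False, True), (False, False)]
        rows = [
            RaterObservation(f"PT-{i}", ("AI-001", "DX-001", "DX-001-DC-01"), j, s)
            for i, (j, s) in enumerate(patterns)
        ]
        table = build_cdv_indicators(rows, tiny_kb, agreement_mode="presence_only")
        (entry,) = table.entries
        assert entry.score == pytest.approx(0.68)
        assert entry.level == Level.MINOR
        assert table.displayable() == [entry]

    def test_all_agreement_all_major(self, tiny_kb):
        rows = [
            RaterObservation(f"PT-{i}", ("AI-001", "DX-001", f"DX-001-DC-0{k}"), True, True)
            for i in range(5)
            for k in (1, 2)
        ]
        table = build_cdv_indicators(rows, tiny_kb)
        assert len(table.entries) == 2
        assert all(e.level == Level.MAJOR for e in table.entries)

    def test_empty_observations(self, tiny_kb):
        assert build_cdv_indicators([], tiny_kb).entries == []

    def test_unresolved_association_rejected(self, tiny_kb):
        rows = [RaterObservation("PT-1", ("AI-999", "DX-001", "DX-001-DC-01"), True, True)]
        with pytest.raises(KBError, match="unknown association"):
            build_cdv_indicators(rows, tiny_kb)

    def test_excluded_entries_retained_but_not_displayable(self, tiny_kb):
        rows = obs([(True, False), (False, True)] * 2)
        table = build_cdv_indicators(
            [
                RaterObservation(o.patient_id, ("AI-001", "DX-001", "DX-001-DC-01"),
                                 o.junior_present, o.senior_present)
                for o in rows
            ],
            tiny_kb,
        )
        assert len(table.entries) == 1
        assert table.entries[0].level == Level.EXCLUDED
        assert table.displayable() == []


def test_exhaustive_brute_force_recount():
    """For every rater pattern on N <= 4 patients, the tally + formula path
    agrees with a direct recount of the defining arithmetic."""
    for n in range(1, 5):
        for junior in itertools.product([False, True], repeat=n):
            for senior in itertools.product([False, True], repeat=n):
                rows = obs(list(zip(junior, senior)))
                (t,) = tally_rater_agreement(rows)
                r = cdv_weighted_ratio(t.F1, t.F2, t.N, t.A, t.D)
                # independent brute-force recount from the raw pattern
                f1, f2 = sum(junior), sum(senior)
                a = sum(j == s for j, s in zip(junior, senior))
                expected = ((f1 / n + f2 / n) / 2) * (a / n)
                assert r == pytest.approx(expected, abs=1e-12)
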