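"""Token-level edit distance, NLSI, medians, motif counting, extraction.

The Levenshtein implementation is checked against two independent oracles:
breadth-first search over single-token edits (exact for short sequences) and
the edlib alignment library with tokens mapped to single characters.
"""

from collections import deque

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cetasong.annotations import (
    AnnotatedEvent,
    EventTable,
    TokenSequence,
    load_response_fixture,
    tokenize_label_string,
)
from cetasong.sequences import (
    count_motif,
    extract_responses,
    generalized_median,
    levenshtein,
    nlsi,
    round_index,
    set_median,
    summarize_indices,
)


def tok(s):
    return tokenize_label_string(s)


def bfs_edit_distance(a, b, alphabet):
    """Independent oracle: breadth-first search over single-token edits."""
    a, b = tuple(a), tuple(b)
    if a == b:
        return 0
    seen = {a}
    frontier = deque([(a, 0)])
    while frontier:
        seq, d = frontier.popleft()
        for nxt in _edits(seq, alphabet):
            if nxt == b:
                return d + 1
            if nxt not in seen and abs(len(nxt) - len(b)) <= 6:
                seen.add(nxt)
                frontier.append((nxt, d + 1))
    raise AssertionError("unreachable for finite sequences")


def _edits(seq, alphabet):
    for i in range(len(seq)):
        yield seq[:i] + seq[i + 1 :]
        for t in alphabet:
            if t != seq[i]:
                yield seq[:i] + (t,) + seq[i + 1 :]
    for i in range(len(seq) + 1):
        for t in alphabet:
            yield seq[:i] + (t,) + seq[i:]


def edlib_distance(a, b):
    """Cross-check oracle: map tokens to single characters, align with edlib."""
    symbols = sorted(set(a) | set(b))
    charmap = {s: chr(0x100 + i) for i, s in enumerate(symbols)}
    sa = "".join(charmap[t] for t in a)
    sb = "".join(charmap[t] for t in b)
    if not sa and not sb:
        return 0
    return edlib.align(sa, sb)["editDistance"]


TOKENS = ["C", "C2", "D", "B", "J", "P2"]
seq_strategy = st.lists(st.sampled_from(TOKENS), max_size=6).map(tuple)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("BCCDD", "BCCDFCCDFC2DEC2", 8),
            ("", "", 0),
            ("C2C2D", "C2C2D", 0),
            ("", "C2C2DC2", 4),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein(tok(a), tok(b)) == expected

    @given(
        st.lists(st.sampled_from(TOKENS[:4]), max_size=4).map(tuple),
        st.lists(st.sampled_from(TOKENS[:4]), max_size=4).map(tuple),
    )
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_matches_bfs_oracle_on_short_sequences(self, a, b):
        assert levenshtein(a, b) == bfs_edit_distance(a, b, TOKENS[:4])

    @given(seq_strategy, seq_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_matches_edlib_oracle(self, a, b):
        assert levenshtein(a, b) == edlib_distance(a, b)

    @given(seq_strategy, seq_strategy, seq_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_metric_axioms(self, a, b, c):
        dab = levenshtein(a, b)
        assert (dab == 0) == (a == b)
        assert dab == levenshtein(b, a)
        assert dab <= levenshtein(a, c) + levenshtein(c, b)

    def test_token_level_not_character_level(self):
        # character-level distance of "C2C2D" vs "CCD" would be 2 deletions;
        # token-level sees two substitutions C2->C
        assert levenshtein(tok("C2C2D"), tok("CCD")) == 2
        assert levenshtein(tok("C2"), tok("C")) == 1


class TestNlsi:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("C2C2DC2", "C2D", 0.5),
            ("IC2D", "C2C2CDC2C2D", 0.71),
            ("JD", "DJDJDJDJDJDJDJPPPPP2", 0.89),
            ("BCCDD", "BCCDFCCDFC2DEC2", 0.62),
        ],
    )
    def test_printed_session_values(self, a, b, expected):
        assert round_index(nlsi(tok(a), tok(b))) == expected

    @given(seq_strategy, seq_strategy)
    @settings(derandomize=True, max_examples=200)
    def test_bounded_in_unit_interval(self, a, b):
        if not a and not b:
            return
        v = nlsi(a, b)
        assert 0.0 <= v <= 1.0
        if levenshtein(a, b) == max(len(a), len(b)):
            assert v == 1.0

    def test_identical_sequences_score_zero(self):
        assert nlsi(tok("C2C2D"), tok("C2C2D")) == 0.0

    def test_both_empty_flagged(self):
        with pytest.raises(ValueError):
            nlsi((), ())


class TestSummaries:
    def test_printed_range_for_four_responses(self):
        seqs = [tok(s) for s in ("BCC", "EBCCD", "C2C2DC2", "C2DC2C2D")]
        s = summarize_indices(seqs, "P1")
        assert round_index(s.min, 1) == 0.4
        assert s.max == 1.0
        assert s.formatted() == "0.4–1"

    def test_single_sequence_not_computable(self):
        s = summarize_indices([tok("CDDMCCD")], "OC2")
        assert not s.computable
        assert s.formatted() == "NC"
        with pytest.raises(ValueError):
            _ = s.min

    def test_duplicated_sequence_gives_min_zero(self):
        s = summarize_indices([tok("C2D"), tok("C2D"), tok("CCD")])
        assert s.min == 0.0


class TestMedians:
    PP1 = [tok(s) for s in ("MCCD", "CCD", "C2C2C2D", "C2C2C2D", "C2DC2C2D", "C2C2DC2")]

    def test_set_median_of_six_printed_responses(self):
        res = set_median(self.PP1)
        assert str(res.median) == "C2C2C2D"
        assert res.total_distance == 9

    def test_set_median_total_matches_pairwise_sum(self):
        res = set_median(self.PP1)
        assert res.total_distance == sum(levenshtein(res.median, s) for s in self.PP1)

    def test_singleton_set(self):
        res = set_median([tok("C2D")])
        assert str(res.median) == "C2D" and res.total_distance == 0

    def test_generalized_never_worse_than_set_median(self):
        fix = load_response_fixture()
        for stim, entry in fix.items():
            sm = set_median(entry["sequences"])
            gm = generalized_median(entry["sequences"])
            assert gm.total_distance <= sm.total_distance, stim

    def test_generalized_median_beats_or_ties_printed_median(self):
        # the printed representative for the four P1 responses has total
        # distance 10; hill-climbing must do at least as well
        fix = load_response_fixture()
        seqs = fix["P1"]["sequences"]
        printed = fix["P1"]["printed_median"]
        printed_total = sum(levenshtein(printed, s) for s in seqs)
        assert printed_total == 10
        assert generalized_median(seqs).total_distance <= printed_total

    def test_identical_sequences_yield_that_sequence(self):
        res = generalized_median([tok("C2D"), tok("C2D")])
        assert str(res.median) == "C2D" and res.total_distance == 0


class TestMotifs:
    def test_phrase_cores_in_printed_responses(self):
        seqs = TestMedians.PP1
        _, n_ccd = count_motif(seqs, tok("CCD"))
        _, n_c2c2d = count_motif(seqs, tok("C2C2D"))
        assert n_ccd == 2
        assert n_c2c2d == 4

    def test_overlapping_count(self):
        counts, n = count_motif([tok("CCCC")], tok("CC"), overlapping=True)
        assert counts == [3] and n == 1

    def test_non_overlapping_count(self):
        counts, _ = count_motif([tok("CCCC")], tok("CC"), overlapping=False)
        assert counts == [2]

    def test_absent_motif(self):
        counts, n = count_motif(TestMedians.PP1, tok("RRR"))
        assert n == 0 and all(c == 0 for c in counts)


class TestExtractResponses:
    def _table(self):
        evs = [
            AnnotatedEvent(0.0, 0.5, "P1", source="cse"),
            AnnotatedEvent(1.0, 1.4, "C2"),
            AnnotatedEvent(2.0, 2.4, "C2"),
            AnnotatedEvent(3.0, 3.4, "D"),
            AnnotatedEvent(10.0, 10.5, "P5A", source="cse"),
            AnnotatedEvent(11.0, 11.4, "J"),
        ]
        return EventTable(evs)

    def test_windows_by_construction(self):
        resp = extract_responses(self._table())
        assert [str(s) for s in resp["P1"]] == ["C2C2D"]
        assert [str(s) for s in resp["P5A"]] == ["J"]

    def test_trailing_stimulus_gets_empty_response(self):
        evs = list(self._table()) + [AnnotatedEvent(20.0, 20.5, "OC2", source="cse")]
        resp = extract_responses(EventTable(evs))
        assert resp["OC2"] == [TokenSequence()]

    def test_counts_match_occurrences(self, small_scenario):
        from cetasong.synth import generate_session

        _, table = generate_session(small_scenario)
        resp = extract_responses(table)
        n_cse = sum(1 for e in table if e.source == "cse")
        assert sum(len(v) for v in resp.values()) == n_cse

    def test_fixture_counts_match_printed_occurrences(self):
        fix = load_response_fixture()
        assert len(fix["P5DOF"]["sequences"]) == 12
        assert len(fix["PP1"]["sequences"]) == 6
        assert len(fix["P1"]["sequences"]) == 4
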