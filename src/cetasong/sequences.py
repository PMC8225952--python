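"""Stimulus–response pattern analysis of song-unit sequences.

After each played stimulus (a concrete sound element, CSE), the whale emits a
sequence of song units. This module quantifies how repeatable those response
sequences are:

* token-level Levenshtein distance between unit sequences (a "change" is the
  insertion, deletion, or substitution of one *unit*, never a character);
* the normalized Levenshtein similarity index (NLSI): distance divided by the
  longer sequence's token count, so 0 means identical and 1 means maximally
  different;
* per-stimulus summaries (all pairwise NLSI values, min and max);
* representative sequences — the set median (a member of the set minimizing
  total distance) and a generalized median found by hill-climbing over
  single-token edits;
* contiguous motif counting (e.g. the "C2C2D" phrase core).

Normalization is by the LONGER sequence's token length; this is the convention
that makes the index land in [0, 1] for every pair, and reporting rounds
half-up to two decimals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from .annotations import EventTable, TokenSequence

__all__ = [
    "levenshtein",
    "nlsi",
    "round_index",
    "extract_responses",
    "summarize_indices",
    "set_median",
    "generalized_median",
    "count_motif",
    "IndexSummary",
    "MedianResult",
    "analyze_responses",
]


def levenshtein(a: Sequence[str], b: Sequence[str]) -> int:
    """Minimum number of single-token edits transforming ``a`` into ``b``.

    Classic dynamic program over tokens, O(|a|·|b|) time, O(min) memory.
    """
    if len(a) < len(b):
        a, b = b, a
    # b is the shorter sequence; prev holds one DP row
    prev = list(range(len(b) + 1))
    for i, ta in enumerate(a, start=1):
        curr = [i]
        for j, tb in enumerate(b, start=1):
            cost = 0 if ta == tb else 1
            curr.append(min(prev[j] + 1, curr[-1] + 1, prev[j - 1] + cost))
        prev = curr
    return prev[-1]


def nlsi(a: Sequence[str], b: Sequence[str]) -> float:
    """Normalized Levenshtein similarity index in [0, 1].

    Edit distance divided by the longer sequence's token count. Two identical
    sequences score 0; sequences sharing no structure score 1.

    Raises
    ------
    ValueError
        If both sequences are empty (the index is undefined).
    """
    n = max(len(a), len(b))
    if n == 0:
        raise ValueError("NLSI undefined for two empty sequences")
    return levenshtein(a, b) / n


def round_index(x: float, ndigits: int = 2) -> float:
    """Round an index half-up to ``ndigits`` decimals (reporting convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def extract_responses(table: EventTable) -> dict[str, list[TokenSequence]]:
    """Collect, per stimulus label, the unit sequence following each occurrence.

    The response window of a CSE occurrence runs from strictly after that
    CSE's start to the next CSE's start (or the end of the session). Units are
    ordered by onset; empty responses are retained as empty sequences, so the
    number of sequences for a stimulus always equals its occurrence count.
    """
    events = list(table)
    cse_ix = [i for i, e in enumerate(events) if e.source == "cse"]
    if not cse_ix:
        raise ValueError("event table contains no CSE events")
    responses: dict[str, list[TokenSequence]] = {}
    for pos, i in enumerate(cse_ix):
        start = events[i].onset_s
        end = events[cse_ix[pos + 1]].onset_s if pos + 1 < len(cse_ix) else float("inf")
        units = [
            e.label
            for e in events
            if e.source == "unit" and start < e.onset_s < end
        ]
        responses.setdefault(events[i].label, []).append(TokenSequence(units))
    return responses


@dataclass(frozen=True)
class IndexSummary:
    """Pairwise NLSI summary for one stimulus's response sequences."""

    stimulus: str
    n_sequences: int
    pairwise: tuple[float, ...]     # all unordered-pair NLSI values
    computable: bool                # False when fewer than 2 sequences

    @property
    def min(self) -> float:
        if not self.computable:
            raise ValueError(f"{self.stimulus}: index not computable (n < 2)")
        return min(self.pairwise)

    @property
    def max(self) -> float:
        if not self.computable:
            raise ValueError(f"{self.stimulus}: index not computable (n < 2)")
        return max(self.pairwise)

    def formatted(self, ndigits: int = 2) -> str:
        """Render as printed in session reports: "NC", one value, or a range."""
        if not self.computable:
            return "NC"
        lo, hi = round_index(self.min, ndigits), round_index(self.max, ndigits)
        if lo == hi:
            return _trim(lo)
        return f"{_trim(lo)}–{_trim(hi)}"


def _trim(x: float) -> str:
    s = f"{x:.2f}".rstrip("0").rstrip(".")
    return s if s else "0"


def summarize_indices(
    seqs: Sequence[TokenSequence], stimulus: str = ""
) -> IndexSummary:
    """All unordered-pair NLSI values for a stimulus's responses.

    A single response gives nothing to compare: the summary is flagged
    not-computable ("NC" in reports).
    """
    if len(seqs) < 1:
        raise ValueError("need at least one sequence")
    pairs = tuple(
        nlsi(a, b) for a, b in itertools.combinations(seqs, 2)
    )
    return IndexSummary(
        stimulus=stimulus,
        n_sequences=len(seqs),
        pairwise=pairs,
        computable=len(seqs) >= 2,
    )


@dataclass(frozen=True)
class MedianResult:
    """A representative sequence and its total distance to the input set."""

    median: TokenSequence
    total_distance: int
    method: str  # "set_median" | "generalized"


def _total_distance(cand: Sequence[str], seqs: Sequence[TokenSequence]) -> int:
    return sum(levenshtein(cand, s) for s in seqs)


def set_median(seqs: Sequence[TokenSequence]) -> MedianResult:
    """The input member minimizing total Levenshtein distance to all members.

    Ties break toward the shorter sequence, then lexicographic token order,
    so the result is independent of input order.
    """
    if not seqs:
        raise ValueError("need at least one sequence")
    best = min(
        seqs, key=lambda s: (_total_distance(s, seqs), len(s), tuple(s))
    )
    return MedianResult(
        median=TokenSequence(best),
        total_distance=_total_distance(best, seqs),
        method="set_median",
    )


def generalized_median(
    seqs: Sequence[TokenSequence], max_iters: int = 1000
) -> MedianResult:
    """Approximate generalized median by greedy hill-climbing.

    Starts from the set median and explores the single-token edit
    neighborhood (substitutions, insertions, deletions over the observed
    alphabet), accepting any strict improvement in total distance until a
    local optimum or ``max_iters``. The result is therefore never worse than
    the set median, but exact optimality is not guaranteed (exact search is
    exponential in sequence length).
    """
    start = set_median(seqs)
    alphabet = sorted({t for s in seqs for t in s})
    current = list(start.median)
    best_total = start.total_distance
    for _ in range(max_iters):
        improved = False
        for cand in _edit_neighbors(current, alphabet):
            total = _total_distance(cand, seqs)
            if total < best_total:
                current, best_total = list(cand), total
                improved = True
                break
        if not improved:
            break
    return MedianResult(
        median=TokenSequence(current),
        total_distance=best_total,
        method="generalized",
    )


def _edit_neighbors(seq: list[str], alphabet: list[str]):
    for i in range(len(seq)):
        # deletion
        yield seq[:i] + seq[i + 1 :]
        # substitution
        for t in alphabet:
            if t != seq[i]:
                yield seq[:i] + [t] + seq[i + 1 :]
    for i in range(len(seq) + 1):
        for t in alphabet:
            yield seq[:i] + [t] + seq[i:]


def count_motif(
    seqs: Sequence[TokenSequence],
    motif: Sequence[str],
    overlapping: bool = True,
) -> tuple[list[int], int]:
    """Count contiguous occurrences of a token motif in each sequence.

    Returns per-sequence counts and the number of sequences containing the
    motif at least once. Matching is over tokens, so the motif (C, C, D) does
    NOT match inside (C2, C2, D).
    """
    motif = tuple(motif)
    if not motif:
        raise ValueError("motif must be non-empty")
    m = len(motif)
    counts = []
    for s in seqs:
        c, i = 0, 0
        while i + m <= len(s):
            if tuple(s[i : i + m]) == motif:
                c += 1
                i += 1 if overlapping else m
            else:
                i += 1
        counts.append(c)
    return counts, sum(1 for c in counts if c > 0)


def analyze_responses(
    responses: Mapping[str, Sequence[TokenSequence]],
    motifs: Sequence[Sequence[str]] = (),
    median_max_iters: int = 200,
) -> dict[str, dict]:
    """Full per-stimulus report: sequences, indices, medians, motif counts.

    The returned mapping is JSON-serializable (sequences rendered as
    concatenated label strings) and is the payload behind the session-report
    CSV/JSON outputs.
    """
    report: dict[str, dict] = {}
    for stimulus, seqs in responses.items():
        summary = summarize_indices(seqs, stimulus)
        sm = set_median(seqs)
        gm = generalized_median(seqs, max_iters=median_max_iters)
        entry: dict = {
            "sequences": [str(s) for s in seqs],
            "n_sequences": len(seqs),
            "index": summary.formatted(),
            "pairwise_indices": [round_index(v) for v in summary.pairwise],
            "set_median": str(sm.median),
            "set_median_total": sm.total_distance,
            "generalized_median": str(gm.median),
            "generalized_median_total": gm.total_distance,
        }
        entry["motifs"] = {
            "".join(m): {
                "counts": count_motif(seqs, m)[0],
                "n_containing": count_motif(seqs, m)[1],
            }
            for m in motifs
        }
        report[stimulus] = entry
    return report
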