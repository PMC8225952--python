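"""Annotated acoustic events, annotation-table I/O, and unit-label tokenization.

A playback session is described by a table of timed, labeled events. Each
event is either a whale song unit (a harmonic or pulsed vocalization bounded
by silences) or a played stimulus — a "concrete sound element" (CSE), i.e. a
studio-prepared sound object. Unit categories are named by a capital letter,
with a trailing number for sub-classes that differ mainly in duration
("C2", "C3" are sub-classes of "C"). CSE labels such as "P5DOF" are atomic
category names and are never tokenized.

Times are seconds from the start of the session file, half-open
``[onset, offset)``. Overlapping events are allowed but must not share an
onset: distinct start times are what disambiguate overlaps in annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "AnnotatedEvent",
    "EventTable",
    "TokenSequence",
    "tokenize_label_string",
    "read_event_table",
    "write_event_table",
    "slice_audio",
    "load_occurrence_fixture",
    "load_response_fixture",
    "LabelParseError",
    "TableFormatError",
]

CONTOURS = ("flat", "upsweep", "downsweep", "convex", "concave", "modulated")
SOURCES = ("unit", "cse")
SOUND_TYPES = ("tonal", "pulsed")

_TOKEN_RE = re.compile(r"[A-Z][0-9]*")


class LabelParseError(ValueError):
    """A label string does not follow the letter+optional-digits grammar."""


class TableFormatError(ValueError):
    """An annotation table file is malformed; message names the row."""


class TokenSequence(tuple):
    """An ordered sequence of unit tokens, e.g. ``(C2, C2, D)``.

    A token is one uppercase Latin letter followed by optional digits. The
    sequence is the substrate of all edit-distance work; distances operate on
    tokens, never characters ("C2" is a single symbol).
    """

    def __new__(cls, tokens: Iterable[str] = ()):
        toks = tuple(tokens)
        for t in toks:
            if not _TOKEN_RE.fullmatch(t):
                raise LabelParseError(f"invalid unit token {t!r}")
        return super().__new__(cls, toks)

    def __str__(self) -> str:
        return "".join(self)

    def __repr__(self) -> str:
        return f"TokenSequence({'+'.join(self) or ''!r})"


def tokenize_label_string(s: str) -> TokenSequence:
    """Split a concatenated unit-label string into tokens.

    Greedy longest match of letter+digits, so digits always attach to the
    preceding letter: ``"P3P2PC3"`` → ``(P3, P2, P, C3)``. Joining the tokens
    reproduces the input exactly.

    Raises
    ------
    LabelParseError
        If the string contains anything but uppercase letters and digits, or
        starts with a digit; the message reports the offending position.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if m is None:
            raise LabelParseError(
                f"cannot tokenize {s!r}: unexpected character {s[pos]!r} at position {pos}"
            )
        tokens.append(m.group())
        pos = m.end()
    return TokenSequence(tokens)


@dataclass(frozen=True)
class AnnotatedEvent:
    """One timed acoustic event: a song unit or a played CSE."""

    onset_s: float
    offset_s: float
    label: str
    source: str = "unit"          # unit | cse
    sound_type: str = "tonal"     # tonal | pulsed
    contour: str | None = None    # one of CONTOURS, or None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("event label must be non-empty")
        if not (self.onset_s < self.offset_s):
            raise ValueError(
                f"event {self.label!r}: onset {self.onset_s} must precede offset {self.offset_s}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"source must be one of {SOURCES}, got {self.source!r}")
        if self.sound_type not in SOUND_TYPES:
            raise ValueError(f"sound_type must be one of {SOUND_TYPES}, got {self.sound_type!r}")
        if self.contour is not None and self.contour not in CONTOURS:
            raise ValueError(f"contour must be one of {CONTOURS} or None, got {self.contour!r}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


class EventTable:
    """An ordered collection of :class:`AnnotatedEvent`, sorted by onset.

    Overlaps are permitted, but two events may not start at the same time —
    the start time is what disambiguates overlapping unit/CSE annotations.
    """

    def __init__(self, events: Iterable[AnnotatedEvent] = ()):
        evs = sorted(events, key=lambda e: (e.onset_s, e.offset_s, e.label))
        for a, b in zip(evs, evs[1:]):
            if a.onset_s == b.onset_s:
                raise ValueError(
                    f"events {a.label!r} and {b.label!r} share onset {a.onset_s}; "
                    "overlapping events must differ in start time"
                )
        self._events: tuple[AnnotatedEvent, ...] = tuple(evs)

    def __iter__(self) -> Iterator[AnnotatedEvent]:
        return iter(self._events)

    def __len__(self) -> int:
        return len(self._events)

    def __getitem__(self, i):
        return self._events[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, EventTable) and self._events == other._events

    def __repr__(self) -> str:
        return f"EventTable(n={len(self)})"

    @property
    def events(self) -> tuple[AnnotatedEvent, ...]:
        return self._events

    def filter(self, source: str) -> "EventTable":
        return EventTable(e for e in self if e.source == source)

    def labels(self, source: str | None = None) -> list[str]:
        return [e.label for e in self if source is None or e.source == source]


_COLUMNS = ("onset_s", "offset_s", "label", "source", "sound_type", "contour")


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write an annotation table as TSV, rows sorted by onset.

    Floats are written with :func:`repr` so a read/write round trip is
    byte-stable.
    """
    lines = ["\t".join(_COLUMNS)]
    for e in table:
        lines.append(
            "\t".join(
                [
                    repr(float(e.onset_s)),
                    repr(float(e.offset_s)),
                    e.label,
                    e.source,
                    e.sound_type,
                    e.contour if e.contour is not None else "",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_event_table(path: str | Path) -> EventTable:
    """Read an annotation TSV into an :class:`EventTable`.

    Raises
    ------
    TableFormatError
        On a missing column, a non-numeric time, or onset ≥ offset; the
        message names the offending row.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TableFormatError(f"{path}: empty annotation file")
    header = lines[0].split("\t")
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise TableFormatError(f"{path}: missing column(s) {missing}")
    idx = {c: header.index(c) for c in _COLUMNS}
    events = []
    for row_no, ln in enumerate(lines[1:], start=1):
        cells = ln.split("\t")
        if len(cells) < len(header):
            cells += [""] * (len(header) - len(cells))
        try:
            onset = float(cells[idx["onset_s"]])
            offset = float(cells[idx["offset_s"]])
        except ValueError as exc:
            raise TableFormatError(f"{path} row {row_no}: non-numeric time ({exc})") from exc
        contour = cells[idx["contour"]] or None
        try:
            events.append(
                AnnotatedEvent(
                    onset_s=onset,
                    offset_s=offset,
                    label=cells[idx["label"]],
                    source=cells[idx["source"]],
                    sound_type=cells[idx["sound_type"]],
                    contour=contour,
                )
            )
        except ValueError as exc:
            raise TableFormatError(f"{path} row {row_no}: {exc}") from exc
    return EventTable(events)


def slice_audio(
    waveform: np.ndarray, sample_rate: float, event: AnnotatedEvent
) -> np.ndarray:
    """Extract the samples of one event from a session waveform.

    The segment spans ``[onset, offset)`` and has
    ``round((offset - onset) * sample_rate)`` samples.
    """
    start = int(round(event.onset_s * sample_rate))
    n = int(round((event.offset_s - event.onset_s) * sample_rate))
    if start < 0 or start + n > len(waveform):
        raise IndexError(
            f"event {event.label!r} [{event.onset_s}, {event.offset_s}) outside "
            f"audio of {len(waveform) / sample_rate:.3f} s"
        )
    return waveform[start : start + n]


# ---------------------------------------------------------------------------
# Packaged fixtures: the printed occurrence counts and stimulus→response
# strings of the 2018 La Réunion interaction session.

def _fixture_text(name: str) -> str:
    return resources.files("cetasong").joinpath("data", name).read_text()


def load_occurrence_fixture() -> dict[str, dict[str, int]]:
    """Occurrence counts per category of the annotated interaction session.

    Returns ``{"unit": {label: count}, "cse": {label: count}}`` — 21 unit
    categories (267 occurrences) and 15 CSE categories (40 occurrences).
    """
    out: dict[str, dict[str, int]] = {"unit": {}, "cse": {}}
    lines = _fixture_text("session2018_occurrences.tsv").splitlines()
    for ln in lines[1:]:
        if not ln.strip():
            continue
        label, source, occ = ln.split("\t")
        out[source][label] = int(occ)
    return out


def load_response_fixture() -> dict[str, dict]:
    """Stimulus → response sequences of the interaction session.

    Returns ``{stimulus: {"sequences": [TokenSequence, ...],
    "printed_median": TokenSequence | None}}``. Sequences are tokenized from
    the concatenated label strings as annotated.
    """
    out: dict[str, dict] = {}
    for ln in _fixture_text("session2018_responses.tsv").splitlines():
        if not ln.strip():
            continue
        parts = ln.split("\t")
        stimulus = parts[0]
        seqs = [tokenize_label_string(s) for s in parts[1].split(",")]
        median = tokenize_label_string(parts[2]) if len(parts) > 2 and parts[2] else None
        out[stimulus] = {"sequences": seqs, "printed_median": median}
    return out
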