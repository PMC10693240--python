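"""Event tables, validation, and session assembly.

The analysis starts from annotated acoustic events: calls (the broadcast
exemplar and the subject whale's vocalizations), non-vocal behavior events
(respiratory blows, surfacings) and behaviorally defined phase intervals
supplied by independent observers.  This module reads and writes the
tab-delimited tables those annotations live in — either the Raven
selection-table dialect or a minimal TSV — and assembles them into a
validated, time-ordered :class:`Session`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Source",
    "Day",
    "BehaviorKind",
    "PhaseLabel",
    "UNPHASED",
    "CallEvent",
    "BehaviorEvent",
    "PhaseInterval",
    "Session",
    "Dialect",
    "FormatError",
    "read_selection_table",
    "write_selection_table",
    "read_behavior_table",
    "write_behavior_table",
    "read_phase_table",
    "write_phase_table",
    "assign_phase",
    "assemble_session",
]


class Source(str, Enum):
    """Who produced a call: the playback system or the focal animal."""

    EXEMPLAR = "EXEMPLAR"
    SUBJECT = "SUBJECT"


class Day(str, Enum):
    """Recording day type: passive control recording vs playback trial."""

    CONTROL = "CONTROL"
    PLAYBACK = "PLAYBACK"


class BehaviorKind(str, Enum):
    BLOW_NEUTRAL = "BLOW_NEUTRAL"
    BLOW_WHEEZY = "BLOW_WHEEZY"
    SURFACING = "SURFACING"
    OTHER = "OTHER"


class PhaseLabel(str, Enum):
    ENGAGEMENT = "ENGAGEMENT"
    AGITATION = "AGITATION"
    DISENGAGEMENT = "DISENGAGEMENT"
    CONTROL = "CONTROL"


#: Sentinel phase for events not covered by any phase interval.
UNPHASED = "UNPHASED"


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


def _check_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class CallEvent:
    """A single vocalization or broadcast.

    Times are seconds from session start with millisecond-or-better
    resolution; ``amplitude_db`` is an optional relative level in dB
    (typically negative, relative to full scale).
    """

    event_id: str
    source: Source
    onset_s: float
    offset_s: float
    amplitude_db: float | None = None
    session_day: Day = Day.PLAYBACK

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        object.__setattr__(self, "session_day", Day(self.session_day))
        onset = _check_finite("onset_s", self.onset_s)
        offset = _check_finite("offset_s", self.offset_s)
        if onset < 0:
            raise ValueError(f"onset_s must be >= 0, got {onset}")
        if offset < onset:
            raise ValueError(
                f"offset_s ({offset}) must be >= onset_s ({onset}) for {self.event_id}"
            )
        object.__setattr__(self, "onset_s", onset)
        object.__setattr__(self, "offset_s", offset)
        if self.amplitude_db is not None:
            object.__setattr__(
                self, "amplitude_db", _check_finite("amplitude_db", self.amplitude_db)
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class BehaviorEvent:
    """A timestamped non-vocal event (blow subtype, surfacing)."""

    time_s: float
    kind: BehaviorKind
    note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", BehaviorKind(self.kind))
        t = _check_finite("time_s", self.time_s)
        if t < 0:
            raise ValueError(f"time_s must be >= 0, got {t}")
        object.__setattr__(self, "time_s", t)


@dataclass(frozen=True)
class PhaseInterval:
    """A half-open phase interval [start_s, end_s)."""

    label: PhaseLabel
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "label", PhaseLabel(self.label))
        start = _check_finite("start_s", self.start_s)
        end = _check_finite("end_s", self.end_s)
        if not start < end:
            raise ValueError(f"start_s ({start}) must be < end_s ({end})")
        object.__setattr__(self, "start_s", start)
        object.__setattr__(self, "end_s", end)

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


def _validate_phases(phases: Sequence[PhaseInterval]) -> list[PhaseInterval]:
    ordered = sorted(phases, key=lambda p: p.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"phase intervals overlap: {a.label.value} [{a.start_s}, {a.end_s}) and "
                f"{b.label.value} [{b.start_s}, {b.end_s})"
            )
    return ordered


def assign_phase(
    event_time: float, phases: Sequence[PhaseInterval]
) -> PhaseLabel | str:
    """Return the label of the unique interval containing ``event_time``.

    Intervals are half-open ``[start_s, end_s)`` so every time maps to at
    most one label; times outside all intervals map to :data:`UNPHASED`
    (a value, not an error).
    """
    for p in phases:
        if p.contains(event_time):
            return p.label
    return UNPHASED


@dataclass
class Session:
    """A validated, time-ordered recording session.

    Calls are sorted by onset; phases are non-overlapping; calls whose
    onset falls outside every phase interval are retained but report
    :data:`UNPHASED` from :meth:`phase_of`.
    """

    calls: list[CallEvent]
    behaviors: list[BehaviorEvent] = field(default_factory=list)
    phases: list[PhaseInterval] = field(default_factory=list)
    day: Day = Day.PLAYBACK

    def __post_init__(self) -> None:
        self.day = Day(self.day)
        self.calls = sorted(self.calls, key=lambda c: (c.onset_s, c.offset_s))
        self.behaviors = sorted(self.behaviors, key=lambda b: b.time_s)
        self.phases = _validate_phases(self.phases)

    def phase_of(self, t: float) -> PhaseLabel | str:
        return assign_phase(t, self.phases)

    def calls_from(self, source: Source) -> list[CallEvent]:
        source = Source(source)
        return [c for c in self.calls if c.source is source]

    @property
    def duration_s(self) -> float:
        times = [c.offset_s for c in self.calls] + [b.time_s for b in self.behaviors]
        times += [p.end_s for p in self.phases]
        return max(times, default=0.0)


def assemble_session(
    calls: Iterable[CallEvent],
    behaviors: Iterable[BehaviorEvent] = (),
    phases: Iterable[PhaseInterval] = (),
    day: Day = Day.PLAYBACK,
) -> Session:
    """Merge individually valid components into a validated Session."""
    return Session(
        calls=list(calls), behaviors=list(behaviors), phases=list(phases), day=Day(day)
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

class Dialect(str, Enum):
    RAVEN = "RAVEN"
    SIMPLE_TSV = "SIMPLE_TSV"


RAVEN_BEGIN = "Begin Time (s)"
RAVEN_END = "End Time (s)"
DEFAULT_SOURCE_COLUMN = "Source"
DEFAULT_AMPLITUDE_COLUMN = "Peak Power Density (dB)"

_SIMPLE_COLUMNS = ["event_id", "source", "onset_s", "offset_s", "amplitude_db"]


def _parse_time(value, column: str, row_index: int) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"row {row_index}: non-numeric value {value!r} in column {column!r}"
        ) from None
    if not math.isfinite(out):
        raise FormatError(f"row {row_index}: non-finite value in column {column!r}")
    return out


def _map_source(value, row_index: int) -> Source:
    try:
        return Source(str(value).strip().upper())
    except ValueError:
        raise FormatError(
            f"row {row_index}: unknown source {value!r} "
            f"(expected EXEMPLAR or SUBJECT, case-insensitive)"
        ) from None


def read_selection_table(
    path: str | Path,
    dialect: Dialect = Dialect.RAVEN,
    *,
    source_column: str = DEFAULT_SOURCE_COLUMN,
    amplitude_column: str = DEFAULT_AMPLITUDE_COLUMN,
    day: Day = Day.PLAYBACK,
) -> list[CallEvent]:
    """Read call events from a tab-delimited selection table.

    The RAVEN dialect is the Raven selection-table export: a header row with
    at least ``"Begin Time (s)"`` and ``"End Time (s)"`` columns, the call
    source in a user-named annotation column (``source_column``) and an
    optional amplitude measurement column.  SIMPLE_TSV is this package's
    minimal export (``event_id, source, onset_s, offset_s, amplitude_db``).
    Rows need not be time-ordered in the file; the result is sorted by onset.
    """
    path = Path(path)
    dialect = Dialect(dialect)
    df = pd.read_csv(path, sep="\t", dtype=str)

    if dialect is Dialect.RAVEN:
        required = [RAVEN_BEGIN, RAVEN_END, source_column]
        for col in required:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path.name}")
        events = []
        for i, row in df.iterrows():
            onset = _parse_time(row[RAVEN_BEGIN], RAVEN_BEGIN, i)
            offset = _parse_time(row[RAVEN_END], RAVEN_END, i)
            amp = None
            if amplitude_column in df.columns and pd.notna(row[amplitude_column]):
                amp = _parse_time(row[amplitude_column], amplitude_column, i)
            event_id = str(row["Selection"]) if "Selection" in df.columns else str(i + 1)
            events.append(
                CallEvent(
                    event_id=event_id,
                    source=_map_source(row[source_column], i),
                    onset_s=onset,
                    offset_s=offset,
                    amplitude_db=amp,
                    session_day=day,
                )
            )
    else:
        for col in _SIMPLE_COLUMNS[:4]:
            if col not in df.columns:
                raise FormatError(f"missing required column {col!r} in {path.name}")
        events = []
        for i, row in df.iterrows():
            amp = None
            if "amplitude_db" in df.columns and pd.notna(row["amplitude_db"]):
                amp = _parse_time(row["amplitude_db"], "amplitude_db", i)
            events.append(
                CallEvent(
                    event_id=str(row["event_id"]),
                    source=_map_source(row["source"], i),
                    onset_s=_parse_time(row["onset_s"], "onset_s", i),
                    offset_s=_parse_time(row["offset_s"], "offset_s", i),
                    amplitude_db=amp,
                    session_day=day,
                )
            )

    return sorted(events, key=lambda c: (c.onset_s, c.offset_s))


def write_selection_table(
    calls: Sequence[CallEvent],
    path: str | Path,
    dialect: Dialect = Dialect.SIMPLE_TSV,
    *,
    source_column: str = DEFAULT_SOURCE_COLUMN,
    amplitude_column: str = DEFAULT_AMPLITUDE_COLUMN,
) -> None:
    """Write call events as a tab-delimited selection table."""
    dialect = Dialect(dialect)
    if dialect is Dialect.RAVEN:
        df = pd.DataFrame(
            {
                "Selection": [c.event_id for c in calls],
                RAVEN_BEGIN: [c.onset_s for c in calls],
                RAVEN_END: [c.offset_s for c in calls],
                source_column: [c.source.value for c in calls],
                amplitude_column: [c.amplitude_db for c in calls],
            }
        )
    else:
        df = pd.DataFrame(
            {
                "event_id": [c.event_id for c in calls],
                "source": [c.source.value for c in calls],
                "onset_s": [c.onset_s for c in calls],
                "offset_s": [c.offset_s for c in calls],
                "amplitude_db": [c.amplitude_db for c in calls],
            }
        )
    df.to_csv(path, sep="\t", index=False)


def read_behavior_table(path: str | Path) -> list[BehaviorEvent]:
    """Read a behavior-event TSV with columns time_s, kind, note."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("time_s", "kind"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {Path(path).name}")
    out = []
    for i, row in df.iterrows():
        note = str(row["note"]) if "note" in df.columns and pd.notna(row["note"]) else ""
        try:
            kind = BehaviorKind(str(row["kind"]).strip().upper())
        except ValueError:
            raise FormatError(f"row {i}: unknown behavior kind {row['kind']!r}") from None
        out.append(
            BehaviorEvent(time_s=_parse_time(row["time_s"], "time_s", i), kind=kind, note=note)
        )
    return sorted(out, key=lambda b: b.time_s)


def write_behavior_table(behaviors: Sequence[BehaviorEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": [b.time_s for b in behaviors],
            "kind": [b.kind.value for b in behaviors],
            "note": [b.note for b in behaviors],
        }
    ).to_csv(path, sep="\t", index=False)


def read_phase_table(path: str | Path) -> list[PhaseInterval]:
    """Read a phase-interval TSV with columns label, start_s, end_s."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("label", "start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r} in {Path(path).name}")
    out = []
    for i, row in df.iterrows():
        try:
            label = PhaseLabel(str(row["label"]).strip().upper())
        except ValueError:
            raise FormatError(f"row {i}: unknown phase label {row['label']!r}") from None
        out.append(
            PhaseInterval(
                label=label,
                start_s=_parse_time(row["start_s"], "start_s", i),
                end_s=_parse_time(row["end_s"], "end_s", i),
            )
        )
    return _validate_phases(out)


def write_phase_table(phases: Sequence[PhaseInterval], path: str | Path) -> None:
    pd.DataFrame(
        {
            "label": [p.label.value for p in phases],
            "start_s": [p.start_s for p in phases],
            "end_s": [p.end_s for p in phases],
        }
    ).to_csv(path, sep="\t", index=False)
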