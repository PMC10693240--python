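"""Inter-call latencies and counter-call classification.

The latency between two calls is the time from the preceding call's offset
to the subsequent call's onset (the inter-call interval).  A subject call is
a *counter call* when it directly answers an exemplar broadcast: the most
recent prior call is an exemplar and no respiratory blow or surfacing occurs
between that exemplar's offset and the subject call's onset — breathing at
the surface disrupts the ease of calling and breaks the direct exchange.

These per-pair records pool into the phase- and day-stratified latency
dataset on which the latency GLM contrasts are fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .events import (
    UNPHASED,
    BehaviorKind,
    CallEvent,
    Day,
    PhaseLabel,
    Session,
    Source,
)

__all__ = [
    "LatencyRecord",
    "INTERVENING_KINDS",
    "compute_latencies",
    "classify_counter_calls",
    "latency_dataset",
    "latency_dataset_to_tsv",
]

logger = logging.getLogger(__name__)

#: Behavior kinds that break a direct exemplar->subject exchange.
INTERVENING_KINDS = frozenset(
    {BehaviorKind.BLOW_NEUTRAL, BehaviorKind.BLOW_WHEEZY, BehaviorKind.SURFACING}
)


@dataclass(frozen=True)
class LatencyRecord:
    """Latency between two consecutive same-source calls.

    ``phase`` is the phase of the terminating call's onset (the response is
    the event being explained).  ``is_counter_call`` is meaningful only for
    subject-to-subject records; it flags whether the terminating subject
    call directly answered an exemplar.
    """

    from_event: str
    to_event: str
    latency_s: float
    phase: PhaseLabel | str
    day: Day
    is_counter_call: bool | None = None

    def __post_init__(self) -> None:
        if self.latency_s < 0:
            raise ValueError(f"latency_s must be >= 0, got {self.latency_s}")


def compute_latencies(
    session: Session, source: Source
) -> tuple[list[LatencyRecord], int]:
    """One latency record per consecutive same-source call pair.

    Returns the records in time order plus the number of pairs dropped for
    overlap (negative computed latency indicates an annotation error; such
    pairs are excluded with a warning rather than clamped to zero).
    """
    source = Source(source)
    calls = session.calls_from(source)
    records: list[LatencyRecord] = []
    n_warnings = 0
    for prev, nxt in zip(calls, calls[1:]):
        latency = nxt.onset_s - prev.offset_s
        if latency < 0:
            n_warnings += 1
            logger.warning(
                "overlapping %s calls %s -> %s (latency %.3f s); record excluded",
                source.value,
                prev.event_id,
                nxt.event_id,
                latency,
            )
            continue
        records.append(
            LatencyRecord(
                from_event=prev.event_id,
                to_event=nxt.event_id,
                latency_s=latency,
                phase=session.phase_of(nxt.onset_s),
                day=session.day,
            )
        )
    return records, n_warnings


def _is_counter_call(call: CallEvent, session: Session) -> bool:
    """Direct-exchange test for one subject call.

    True iff the most recent prior call is an exemplar and no blow or
    surfacing falls in the open interval (exemplar offset, call onset).
    """
    prior = [c for c in session.calls if c.onset_s < call.onset_s]
    if not prior:
        return False
    last = max(prior, key=lambda c: c.onset_s)
    if last.source is not Source.EXEMPLAR:
        return False
    return not any(
        b.kind in INTERVENING_KINDS and last.offset_s < b.time_s < call.onset_s
        for b in session.behaviors
    )


def classify_counter_calls(
    session: Session, *, strict: bool = False
) -> tuple[list[LatencyRecord], int]:
    """Subject-to-subject latency records with the counter-call flag set.

    The flag is attached to the record *terminating* at each subject call.
    An intervening exemplar between two subject calls does not remove the
    latency record itself; it only determines counter-call status via the
    most-recent-prior-call rule.  Under ``strict=True`` a record whose
    terminating call was an answer attempt broken by a blow (an exemplar
    intervenes but the call is not a counter call) carries
    ``is_counter_call=None`` so it drops out of the counter contrast
    entirely instead of counting as non-counter.
    """
    records, n_warnings = compute_latencies(session, Source.SUBJECT)
    by_id = {c.event_id: c for c in session.calls}
    flagged = []
    for r in records:
        is_cc: bool | None = _is_counter_call(by_id[r.to_event], session)
        if strict and not is_cc:
            intervening_exemplar = any(
                c.source is Source.EXEMPLAR
                and by_id[r.from_event].offset_s < c.onset_s < by_id[r.to_event].onset_s
                for c in session.calls
            )
            if intervening_exemplar:
                is_cc = None
        flagged.append(
            LatencyRecord(
                from_event=r.from_event,
                to_event=r.to_event,
                latency_s=r.latency_s,
                phase=r.phase,
                day=r.day,
                is_counter_call=is_cc,
            )
        )
    return flagged, n_warnings


def latency_dataset(sessions: Iterable[Session], *, strict: bool = False) -> pd.DataFrame:
    """Pooled analysis-ready latency table across sessions.

    Subject-to-subject records from every session, with counter-call flags;
    control-day records carry phase CONTROL.  Columns: ``latency_s, phase,
    day, is_counter_call, from_event, to_event``.
    """
    rows = []
    for session in sessions:
        records, _ = classify_counter_calls(session, strict=strict)
        for r in records:
            phase = r.phase
            if session.day is Day.CONTROL:
                phase = PhaseLabel.CONTROL
            rows.append(
                {
                    "latency_s": r.latency_s,
                    "phase": phase.value if isinstance(phase, PhaseLabel) else phase,
                    "day": r.day.value,
                    "is_counter_call": r.is_counter_call,
                    "from_event": r.from_event,
                    "to_event": r.to_event,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["latency_s", "phase", "day", "is_counter_call", "from_event", "to_event"],
    )


def latency_dataset_to_tsv(dataset: pd.DataFrame, path) -> None:
    dataset.to_csv(path, sep="\t", index=False)
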