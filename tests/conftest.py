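from __future__ import annotations

import numpy as np
import pytest

from antiphon.events import (
    BehaviorEvent,
    BehaviorKind,
    CallEvent,
    Day,
    PhaseInterval,
    PhaseLabel,
    Session,
    Source,
)


def make_call(
    event_id: str,
    source: Source,
    onset: float,
    offset: float,
    amplitude: float | None = None,
    day: Day = Day.PLAYBACK,
) -> CallEvent:
    return CallEvent(
        event_id=event_id,
        source=source,
        onset_s=onset,
        offset_s=offset,
        amplitude_db=amplitude,
        session_day=day,
    )


def timeline_session(
    spec: list[tuple[str, float, float]],
    behaviors: list[tuple[float, BehaviorKind]] = (),
    phases: list[PhaseInterval] = (),
    day: Day = Day.PLAYBACK,
) -> Session:
    """Build a session from a compact (source-letter, onset, offset) list."""
    calls = []
    for i, (src, on, off) in enumerate(spec):
        source = Source.EXEMPLAR if src.upper().startswith("E") else Source.SUBJECT
        calls.append(make_call(f"{src}{i}", source, on, off, day=day))
    return Session(
        calls=calls,
        behaviors=[BehaviorEvent(time_s=t, kind=k) for t, k in behaviors],
        phases=list(phases),
        day=day,
    )


def random_small_session(rng: np.random.Generator) -> Session:
    """A random short mixed timeline for oracle cross-checks."""
    n_calls = int(rng.integers(2, 9))
    calls = []
    t = float(rng.uniform(0, 5))
    for i in range(n_calls):
        dur = float(rng.uniform(0.2, 2.0))
        source = Source.EXEMPLAR if rng.random() < 0.5 else Source.SUBJECT
        calls.append(make_call(f"c{i}", source, t, t + dur))
        t += dur + float(rng.uniform(0.0, 8.0))
    behaviors = []
    kinds = [k.value for k in BehaviorKind]
    for _ in range(int(rng.integers(0, 5))):
        kind = BehaviorKind(str(rng.choice(kinds)))
        behaviors.append(BehaviorEvent(time_s=float(rng.uniform(0, t)), kind=kind))
    return Session(calls=calls, behaviors=behaviors, phases=[], day=Day.PLAYBACK)


@pytest.fixture
def three_phases() -> list[PhaseInterval]:
    return [
        PhaseInterval(label=PhaseLabel.ENGAGEMENT, start_s=0.0, end_s=60.0),
        PhaseInterval(label=PhaseLabel.AGITATION, start_s=60.0, end_s=300.0),
        PhaseInterval(label=PhaseLabel.DISENGAGEMENT, start_s=300.0, end_s=600.0),
    ]
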