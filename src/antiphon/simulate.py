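"""Synthetic playback sessions with known ground truth.

No field recordings ship with this package, so testability rests on a
generator that reproduces the statistical structure the analysis assumes: a
roughly alternating exemplar/subject call timeline over a ~20-minute
playback window, three behavioral phases with phase-dependent response
probability and latency, probabilistic latency coupling (the subject
mimicking the operator's most recent broadcast latency — a coupled
oscillator), scheduled respiratory blows that break direct exchanges, a
call-amplitude decline toward disengagement, and a short, sparse control-day
call sequence.

Every random draw is recorded in a :class:`GroundTruth` object so that
parameter-recovery tests can compare what the analysis estimates against
what the generator actually did.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .events import (
    BehaviorEvent,
    BehaviorKind,
    CallEvent,
    Day,
    PhaseInterval,
    PhaseLabel,
    Session,
    Source,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_playback_session",
    "simulate_control_session",
    "scenario_library",
]

_PHASE_ORDER = (PhaseLabel.ENGAGEMENT, PhaseLabel.AGITATION, PhaseLabel.DISENGAGEMENT)

MIRROR_SUBJECT = "MIRROR_SUBJECT"
FIXED_MEAN = "FIXED_MEAN"


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of a synthetic playback session.

    Per-phase tuples are ordered (engagement, agitation, disengagement).
    Defaults describe a 20-minute exchange: three broadcasts before the
    subject's first answer, short and strongly coupled response latencies
    during engagement, longer and weakly coupled latencies through
    agitation and disengagement, seven scheduled blows/surfacings, and a
    stepwise amplitude decline toward departure.  The control day is a
    short passive sequence of six calls with long, phase-free latencies.
    """

    seed: int = 0
    session_duration_s: float = 1200.0
    #: the operator stops broadcasting shortly after disengagement begins,
    #: before the subject's final calls
    broadcast_cease_s: float = 960.0
    n_initial_broadcasts: int = 3
    phase_bounds_s: tuple[float, ...] = (0.0, 420.0, 900.0, 1200.0)
    response_probability: tuple[float, ...] = (0.95, 0.85, 0.5)
    latency_mean_s: tuple[float, ...] = (8.0, 14.0, 25.0)
    latency_shape: tuple[float, ...] = (4.0, 4.0, 4.0)
    coupling_prob: tuple[float, ...] = (0.8, 0.3, 0.1)
    coupling_noise_sd: tuple[float, ...] = (0.05, 0.05, 0.05)
    broadcast_latency_policy: str = MIRROR_SUBJECT
    operator_mean_latency_s: float = 10.0
    operator_noise_sd: float = 1.0
    blows: tuple[tuple[float, str], ...] = (
        (30.0, "BLOW_NEUTRAL"),
        (120.0, "BLOW_NEUTRAL"),
        (480.0, "BLOW_WHEEZY"),
        (600.0, "BLOW_WHEEZY"),
        (780.0, "BLOW_WHEEZY"),
        (950.0, "BLOW_NEUTRAL"),
        (1100.0, "BLOW_NEUTRAL"),
    )
    #: extra response delay per blow/surfacing intervening before the answer
    #: (breathing at the surface disrupts the ease of calling)
    blow_delay_s: float = 15.0
    #: spontaneous subject calls in succession after the exchange winds down
    #: (not answers to any broadcast); their latencies follow the unprompted
    #: calling distribution, i.e. the control-day latency parameters
    n_trailing_calls: int = 3
    amplitude_base_db: float = -25.0
    amplitude_phase_effect_db: tuple[float, ...] = (0.0, -6.0, -12.0)
    amplitude_noise_sd_db: float = 2.0
    #: spontaneous (non-exchange) calling is slow: the control-day mean sits
    #: above the subject-to-subject latencies of every playback phase, which
    #: run near twice the response latency (operator gap plus answer)
    control_n_calls: int = 6
    control_latency_mean_s: float = 60.0
    control_latency_sd_s: float = 10.0
    call_duration_mean_s: float = 1.0
    call_duration_sd_s: float = 0.15

    def __post_init__(self) -> None:
        if self.broadcast_latency_policy not in (MIRROR_SUBJECT, FIXED_MEAN):
            raise ValueError(
                f"broadcast_latency_policy must be {MIRROR_SUBJECT} or {FIXED_MEAN}"
            )
        bounds = self.phase_bounds_s
        if len(bounds) != 4 or any(b >= a for a, b in zip(bounds[1:], bounds)):
            raise ValueError("phase_bounds_s must be 4 strictly increasing boundaries")
        if bounds[0] < 0 or bounds[-1] > self.session_duration_s:
            raise ValueError("phase bounds must lie within the session duration")
        for name in ("response_probability", "coupling_prob"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(not 0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} must be 3 probabilities in [0, 1]")
        for name in ("latency_mean_s", "latency_shape"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(v <= 0 for v in vals):
                raise ValueError(f"{name} must be 3 positive values")
        if len(self.coupling_noise_sd) != 3 or any(v < 0 for v in self.coupling_noise_sd):
            raise ValueError("coupling_noise_sd must be 3 nonnegative values")
        if len(self.amplitude_phase_effect_db) != 3:
            raise ValueError("amplitude_phase_effect_db must have 3 values")
        if self.operator_mean_latency_s <= 0 or self.call_duration_mean_s <= 0:
            raise ValueError("operator and call-duration means must be positive")
        if self.control_n_calls < 1 or self.control_latency_mean_s <= 0:
            raise ValueError("control day needs >=1 call and a positive mean latency")
        if self.blow_delay_s < 0:
            raise ValueError("blow_delay_s must be >= 0")
        if self.n_trailing_calls < 0:
            raise ValueError("n_trailing_calls must be >= 0")
        if not 0 < self.broadcast_cease_s <= self.session_duration_s:
            raise ValueError("broadcast_cease_s must lie within the session duration")
        for t, kind in self.blows:
            BehaviorKind(kind)
            if t < 0 or t > self.session_duration_s:
                raise ValueError(f"blow time {t} outside the session")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blows"] = [list(b) for b in self.blows]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in (
            "phase_bounds_s",
            "response_probability",
            "latency_mean_s",
            "latency_shape",
            "coupling_prob",
            "coupling_noise_sd",
            "amplitude_phase_effect_db",
        ):
            if key in d:
                d[key] = tuple(d[key])
        if "blows" in d:
            d["blows"] = tuple((float(t), str(k)) for t, k in d["blows"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Everything the generator actually drew, for recovery tests."""

    config: SimConfig
    #: one record per subject call: event_id, phase, coupled, response_latency_s,
    #: answered_exemplar, amplitude_db, blow_suppressed
    responses: list[dict] = field(default_factory=list)
    #: operator latency preceding each broadcast, in broadcast order
    operator_latencies: list[float] = field(default_factory=list)
    #: exemplars the subject did not answer
    unanswered_exemplars: list[str] = field(default_factory=list)
    #: unprompted succession-tail calls: event_id, phase, latency_s
    spontaneous: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "responses": self.responses,
            "operator_latencies": self.operator_latencies,
            "unanswered_exemplars": self.unanswered_exemplars,
            "spontaneous": self.spontaneous,
        }


def _phases(config: SimConfig) -> list[PhaseInterval]:
    b = config.phase_bounds_s
    return [
        PhaseInterval(label=lab, start_s=b[i], end_s=b[i + 1])
        for i, lab in enumerate(_PHASE_ORDER)
    ]


def _phase_index(t: float, config: SimConfig) -> int:
    b = config.phase_bounds_s
    for i in range(3):
        if b[i] <= t < b[i + 1]:
            return i
    return 2 if t >= b[-1] else 0  # clamp outside-bounds times to nearest phase


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, floor: float = 1e-3) -> float:
    return max(floor, float(rng.normal(mean, sd))) if sd > 0 else max(floor, mean)


def simulate_playback_session(config: SimConfig) -> tuple[Session, GroundTruth]:
    """Generate one playback session plus its ground truth.

    Timeline: the operator broadcasts ``n_initial_broadcasts`` exemplars at
    policy-mean intervals, then alternates with the subject.  Each broadcast
    is answered with the phase's response probability; an answer latency is
    either *coupled* (with the phase's coupling probability the subject
    reproduces the operator's preceding latency up to multiplicative
    Gaussian noise) or drawn fresh from the phase's Gamma distribution.
    The operator's next broadcast follows the policy: MIRROR_SUBJECT copies
    the subject's last response latency plus Gaussian noise, FIXED_MEAN uses
    a constant mean plus noise.  Scheduled blows are inserted as behavior
    events; a blow landing inside a response window delays the answer by
    ``blow_delay_s`` (surfacing to breathe interrupts calling) and
    suppresses that call's counter-call status.  Broadcasts are confined to
    the session window; the subject's final answer may extend slightly past
    it, as a real exchange's last response would.  Subject amplitudes are
    the base level plus the phase effect plus Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    calls: list[CallEvent] = []
    truth = GroundTruth(config=config)

    def duration() -> float:
        return _positive_normal(rng, config.call_duration_mean_s, config.call_duration_sd_s, 0.05)

    def operator_gap(last_response_latency: float | None) -> float:
        if config.broadcast_latency_policy == MIRROR_SUBJECT and last_response_latency is not None:
            return _positive_normal(rng, last_response_latency, config.operator_noise_sd, 0.1)
        return _positive_normal(rng, config.operator_mean_latency_s, config.operator_noise_sd, 0.1)

    n_exemplar = 0
    n_subject = 0
    last_response_latency: float | None = None
    last_operator_latency: float | None = None
    # first broadcast after one policy-mean gap from session start
    gap = operator_gap(None)
    t = gap

    while True:
        dur = duration()
        if t + dur > config.broadcast_cease_s:
            break
        n_exemplar += 1
        ex = CallEvent(
            event_id=f"E{n_exemplar:03d}",
            source=Source.EXEMPLAR,
            onset_s=t,
            offset_s=t + dur,
            session_day=Day.PLAYBACK,
        )
        calls.append(ex)
        last_operator_latency = gap
        truth.operator_latencies.append(gap)

        phase_i = _phase_index(ex.onset_s, config)
        answers = (
            n_exemplar > config.n_initial_broadcasts
            and rng.random() < config.response_probability[phase_i]
        )
        if answers:
            coupled = rng.random() < config.coupling_prob[phase_i]
            if coupled:
                eps = (
                    rng.normal(0.0, config.coupling_noise_sd[phase_i])
                    if config.coupling_noise_sd[phase_i] > 0
                    else 0.0
                )
                latency = max(0.05, last_operator_latency * (1.0 + eps))
            else:
                k = config.latency_shape[phase_i]
                latency = float(rng.gamma(k, config.latency_mean_s[phase_i] / k))
            base_latency = latency
            # each blow/surfacing falling inside the response window delays
            # the answer; the delay can expose further scheduled blows
            seen_blows: set[float] = set()
            while True:
                onset = ex.offset_s + latency
                new = [
                    bt
                    for bt, _ in config.blows
                    if ex.offset_s < bt < onset and bt not in seen_blows
                ]
                if not new:
                    break
                seen_blows.update(new)
                latency += config.blow_delay_s * len(new)
            onset = ex.offset_s + latency
            sdur = duration()
            n_subject += 1
            resp_phase = _phase_index(onset, config)
            amp = (
                config.amplitude_base_db
                + config.amplitude_phase_effect_db[resp_phase]
                + (rng.normal(0.0, config.amplitude_noise_sd_db) if config.amplitude_noise_sd_db > 0 else 0.0)
            )
            sub = CallEvent(
                event_id=f"T{n_subject:03d}",
                source=Source.SUBJECT,
                onset_s=onset,
                offset_s=onset + sdur,
                amplitude_db=amp,
                session_day=Day.PLAYBACK,
            )
            calls.append(sub)
            truth.responses.append(
                {
                    "event_id": sub.event_id,
                    "phase": _PHASE_ORDER[resp_phase].value,
                    # phase whose parameters generated the draw (the
                    # exemplar's phase); onset may fall in the next phase
                    "param_phase": _PHASE_ORDER[phase_i].value,
                    "coupled": bool(coupled),
                    "response_latency_s": float(latency),
                    "base_latency_s": float(base_latency),
                    "answered_exemplar": ex.event_id,
                    "amplitude_db": float(amp),
                    "blow_suppressed": bool(seen_blows),
                }
            )
            last_response_latency = latency
            gap = operator_gap(last_response_latency)
            t = sub.offset_s + gap
        else:
            truth.unanswered_exemplars.append(ex.event_id)
            gap = operator_gap(last_response_latency)
            t = ex.offset_s + gap

    # succession tail: after broadcasts cease the subject produces a few
    # unprompted calls whose latencies follow the spontaneous-calling
    # (control-day) distribution before falling silent
    def spontaneous_latency() -> float:
        if config.control_latency_sd_s <= 0:
            return config.control_latency_mean_s
        lat = float(rng.normal(config.control_latency_mean_s, config.control_latency_sd_s))
        while lat <= 0:
            lat = float(rng.normal(config.control_latency_mean_s, config.control_latency_sd_s))
        return lat

    if calls:
        t_tail = calls[-1].offset_s
        for _ in range(config.n_trailing_calls):
            lat = spontaneous_latency()
            onset = t_tail + lat
            sdur = duration()
            n_subject += 1
            resp_phase = _phase_index(onset, config)
            amp = (
                config.amplitude_base_db
                + config.amplitude_phase_effect_db[resp_phase]
                + (
                    rng.normal(0.0, config.amplitude_noise_sd_db)
                    if config.amplitude_noise_sd_db > 0
                    else 0.0
                )
            )
            sub = CallEvent(
                event_id=f"T{n_subject:03d}",
                source=Source.SUBJECT,
                onset_s=onset,
                offset_s=onset + sdur,
                amplitude_db=amp,
                session_day=Day.PLAYBACK,
            )
            calls.append(sub)
            truth.spontaneous.append(
                {
                    "event_id": sub.event_id,
                    "phase": _PHASE_ORDER[resp_phase].value,
                    "latency_s": float(lat),
                }
            )
            t_tail = sub.offset_s

    behaviors = [
        BehaviorEvent(time_s=bt, kind=BehaviorKind(kind)) for bt, kind in config.blows
    ]
    session = Session(
        calls=calls, behaviors=behaviors, phases=_phases(config), day=Day.PLAYBACK
    )
    return session, truth


def simulate_control_session(config: SimConfig) -> Session:
    """A sparse control-day sequence: subject calls only, no exemplars.

    ``control_n_calls`` calls separated by Normal latencies truncated at
    zero, under a single CONTROL phase interval.
    """
    rng = np.random.default_rng([int(config.seed), 0xC0])
    calls: list[CallEvent] = []
    t = 30.0
    for i in range(config.control_n_calls):
        dur = _positive_normal(rng, config.call_duration_mean_s, config.call_duration_sd_s, 0.05)
        calls.append(
            CallEvent(
                event_id=f"C{i + 1:03d}",
                source=Source.SUBJECT,
                onset_s=t,
                offset_s=t + dur,
                session_day=Day.CONTROL,
            )
        )
        if config.control_latency_sd_s > 0:
            lat = float(rng.normal(config.control_latency_mean_s, config.control_latency_sd_s))
            while lat <= 0:
                lat = float(rng.normal(config.control_latency_mean_s, config.control_latency_sd_s))
        else:
            lat = config.control_latency_mean_s
        t = t + dur + lat
    end = calls[-1].offset_s + 1.0
    session = Session(
        calls=calls,
        behaviors=[],
        phases=[PhaseInterval(label=PhaseLabel.CONTROL, start_s=0.0, end_s=end)],
        day=Day.CONTROL,
    )
    return session


def scenario_library() -> dict[str, SimConfig]:
    """Named presets spanning the interesting corners of the design.

    ``paper_like``: three phases with the shortest, most strongly coupled
    latencies during engagement, intermediate latencies with wheezy blows
    during agitation, and long latencies plus an amplitude decline at
    disengagement.  ``null``: all phases statistically identical with zero
    coupling (for type-I-error calibration).  ``perfect_oscillator``:
    deterministic mimicry — every response pair standardizes to 50:50.
    """
    paper_like = SimConfig()
    # the phase-structured blow schedule is removed so the three phase
    # labels are fully exchangeable under the null
    null = replace(
        paper_like,
        response_probability=(0.8, 0.8, 0.8),
        latency_mean_s=(14.0, 14.0, 14.0),
        latency_shape=(4.0, 4.0, 4.0),
        coupling_prob=(0.0, 0.0, 0.0),
        amplitude_phase_effect_db=(0.0, 0.0, 0.0),
        blows=(),
        blow_delay_s=0.0,
        n_trailing_calls=0,
        broadcast_cease_s=1200.0,
        # a fixed-mean operator equal to the response mean makes successive
        # latency records independent and identically distributed across the
        # whole session (mirroring would autocorrelate them, and phase labels
        # are contiguous time blocks, so exchangeability would fail even with
        # identical phase parameters)
        broadcast_latency_policy=FIXED_MEAN,
        operator_mean_latency_s=14.0,
    )
    perfect = replace(
        paper_like,
        response_probability=(1.0, 1.0, 1.0),
        coupling_prob=(1.0, 1.0, 1.0),
        coupling_noise_sd=(0.0, 0.0, 0.0),
        broadcast_latency_policy=FIXED_MEAN,
        operator_noise_sd=0.0,
        amplitude_noise_sd_db=0.0,
        blow_delay_s=0.0,
        n_trailing_calls=0,
    )
    return {"paper_like": paper_like, "null": null, "perfect_oscillator": perfect}
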