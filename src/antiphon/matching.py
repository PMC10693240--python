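"""Latency-ratio matching between exemplar and subject response times.

To ask whether the subject entrained to the playback's timing (the
coupled-oscillator / antisynchrony reading of turn-taking), each answered
call is turned into a *response pair*: the latency into the call versus the
latency out of it.  For an exemplar-to-subject (E-T) pair, the first latency
is how long the playback operator waited after the subject's previous call
before broadcasting, and the second is how long the subject took to answer
that broadcast; a T-E pair is the mirror construction.  The two latencies
are standardized to percentage shares of their total so that pairs can be
compared regardless of absolute duration: a perfect temporal match is a
50:50 split, and a pair counts as *matched* when its split lies between
41:59 and 50:50 (inclusive).  The absolute difference between the two
shares, in percentage points, is the threshold-free *discrepancy* metric
(0 for a perfect match).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .events import Day, PhaseLabel, Session, Source, UNPHASED

__all__ = [
    "MATCH_SHARE_THRESHOLD",
    "PairKind",
    "ResponsePair",
    "ratio_shares",
    "extract_response_pairs",
    "match_rate_by_phase",
    "discrepancy_dataset",
    "pairs_to_tsv",
]

logger = logging.getLogger(__name__)

#: Smallest minority share (percent) that still counts as a match (41:59).
MATCH_SHARE_THRESHOLD = 41.0


class PairKind:
    E_T = "E_T"
    T_E = "T_E"


def ratio_shares(first_latency_s: float, second_latency_s: float) -> tuple[float, float]:
    """Standardized percentage shares (small, large) of a latency pair.

    Shares sum to 100 and are invariant to scaling both latencies by any
    positive constant.
    """
    if first_latency_s <= 0 or second_latency_s <= 0:
        raise ValueError("latencies must be positive")
    total = first_latency_s + second_latency_s
    # round-off guard: an exactly equal pair must standardize to 50, not 50+eps
    small = min(50.0, 100.0 * min(first_latency_s, second_latency_s) / total)
    return small, 100.0 - small


@dataclass(frozen=True)
class ResponsePair:
    """An E-T or T-E response-time pair with its standardized ratio metrics."""

    kind: str
    first_latency_s: float
    second_latency_s: float
    phase: PhaseLabel | str = UNPHASED

    def __post_init__(self) -> None:
        if self.kind not in (PairKind.E_T, PairKind.T_E):
            raise ValueError(f"kind must be E_T or T_E, got {self.kind!r}")
        if self.first_latency_s <= 0 or self.second_latency_s <= 0:
            raise ValueError("response-pair latencies must be > 0")

    @property
    def share_small(self) -> float:
        """Percent share of the smaller latency, in [0, 50]."""
        return ratio_shares(self.first_latency_s, self.second_latency_s)[0]

    @property
    def discrepancy_pp(self) -> float:
        """Absolute difference between the two shares, in percentage points."""
        return 100.0 - 2.0 * self.share_small

    @property
    def matched(self) -> bool:
        """True when the split lies between 41:59 and 50:50 (inclusive).

        The band edge is inclusive, so a hair of floating-point grace keeps
        pairs that standardize to exactly 41:59 inside the band.
        """
        return self.share_small >= MATCH_SHARE_THRESHOLD - 1e-9


def extract_response_pairs(
    session: Session, kind: str, *, strategy: str = "response_time"
) -> tuple[list[ResponsePair], int]:
    """Extract E-T or T-E response pairs from a playback session.

    The default ``response_time`` strategy compares the latency *into* a
    call with the latency *out of* it.  For E_T, every exemplar whose next
    call is a subject call yields a pair: first latency from the subject
    call preceding the exemplar (offset) to the exemplar (onset), second
    latency from the exemplar (offset) to the answering subject call
    (onset).  Both sub-intervals must be free of intervening calls, which
    the consecutive-triple construction guarantees.  T_E is the mirror.

    The alternative ``same_source`` strategy pairs each same-source
    inter-call interval with the other source's immediately following
    interval; it is provided for sensitivity analysis only.

    Returns the pairs plus the count dropped for non-positive latencies.
    """
    if session.day is Day.CONTROL:
        raise ValueError("response pairs require a PLAYBACK session (no exemplars on a control day)")
    if kind not in (PairKind.E_T, PairKind.T_E):
        raise ValueError(f"kind must be E_T or T_E, got {kind!r}")
    mid_source = Source.EXEMPLAR if kind == PairKind.E_T else Source.SUBJECT
    outer_source = Source.SUBJECT if kind == PairKind.E_T else Source.EXEMPLAR

    if strategy == "response_time":
        pairs, dropped = _pairs_response_time(session, kind, mid_source, outer_source)
    elif strategy == "same_source":
        pairs, dropped = _pairs_same_source(session, kind, mid_source, outer_source)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if dropped:
        logger.warning("%d %s pair(s) dropped for non-positive latency", dropped, kind)
    return pairs, dropped


def _pairs_response_time(
    session: Session, kind: str, mid_source: Source, outer_source: Source
) -> tuple[list[ResponsePair], int]:
    calls = session.calls
    pairs: list[ResponsePair] = []
    dropped = 0
    for prev, mid, nxt in zip(calls, calls[1:], calls[2:]):
        if mid.source is not mid_source:
            continue
        if prev.source is not outer_source or nxt.source is not outer_source:
            continue
        first = mid.onset_s - prev.offset_s
        second = nxt.onset_s - mid.offset_s
        if first <= 0 or second <= 0:
            dropped += 1
            continue
        pairs.append(
            ResponsePair(
                kind=kind,
                first_latency_s=first,
                second_latency_s=second,
                phase=session.phase_of(nxt.onset_s),
            )
        )
    return pairs, dropped


def _pairs_same_source(
    session: Session, kind: str, mid_source: Source, outer_source: Source
) -> tuple[list[ResponsePair], int]:
    # Pair each mid-source inter-call interval with the outer source's
    # immediately following interval (sensitivity-analysis reading).
    from .turn_taking import compute_latencies

    mid_recs, _ = compute_latencies(session, mid_source)
    outer_recs, _ = compute_latencies(session, outer_source)
    by_id = {c.event_id: c for c in session.calls}
    pairs: list[ResponsePair] = []
    dropped = 0
    for m in mid_recs:
        m_end = by_id[m.to_event].onset_s
        following = [
            o for o in outer_recs if by_id[o.to_event].onset_s > m_end
        ]
        if not following:
            continue
        o = min(following, key=lambda r: by_id[r.to_event].onset_s)
        if m.latency_s <= 0 or o.latency_s <= 0:
            dropped += 1
            continue
        pairs.append(
            ResponsePair(
                kind=kind,
                first_latency_s=m.latency_s,
                second_latency_s=o.latency_s,
                phase=session.phase_of(by_id[o.to_event].onset_s),
            )
        )
    return pairs, dropped


def match_rate_by_phase(
    pairs: Sequence[ResponsePair], *, min_pairs: int = 2
) -> pd.DataFrame:
    """Per-phase match counts: (phase, n_pairs, n_matched, n_unmatched, sufficient).

    Phases with fewer than ``min_pairs`` pairs are flagged insufficient and
    should be excluded from inference (a phase with a single pair cannot
    inform a matching contrast).  Phases with zero pairs are absent.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    rows: dict[str, dict] = {}
    for p in pairs:
        phase = p.phase.value if isinstance(p.phase, PhaseLabel) else str(p.phase)
        row = rows.setdefault(
            phase, {"phase": phase, "n_pairs": 0, "n_matched": 0, "n_unmatched": 0}
        )
        row["n_pairs"] += 1
        row["n_matched" if p.matched else "n_unmatched"] += 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["phase"]))
    df["sufficient"] = df["n_pairs"] >= min_pairs
    return df


def discrepancy_dataset(pairs: Sequence[ResponsePair]) -> pd.DataFrame:
    """One row per pair: exact discrepancy plus an integer-rounded copy.

    The rounded column feeds the count-family (negative binomial)
    regression; the exact value is retained alongside.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    return pd.DataFrame(
        {
            "discrepancy_pp": [p.discrepancy_pp for p in pairs],
            "discrepancy_pp_int": [int(round(p.discrepancy_pp)) for p in pairs],
            "phase": [
                p.phase.value if isinstance(p.phase, PhaseLabel) else str(p.phase)
                for p in pairs
            ],
            "kind": [p.kind for p in pairs],
        }
    )


def pairs_to_tsv(pairs: Iterable[ResponsePair], path) -> None:
    pairs = list(pairs)
    pd.DataFrame(
        {
            "kind": [p.kind for p in pairs],
            "phase": [
                p.phase.value if isinstance(p.phase, PhaseLabel) else str(p.phase)
                for p in pairs
            ],
            "first_latency_s": [p.first_latency_s for p in pairs],
            "second_latency_s": [p.second_latency_s for p in pairs],
            "share_small": [p.share_small for p in pairs],
            "discrepancy_pp": [p.discrepancy_pp for p in pairs],
            "matched": [p.matched for p in pairs],
        }
    ).to_csv(path, sep="\t", index=False)
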