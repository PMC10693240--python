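"""Independent reference implementations used to cross-check the package.

These deliberately use naive O(n^2) scans over the raw event lists rather
than the package's data structures, so that agreement is informative.
"""

from __future__ import annotations

from antiphon.events import BehaviorKind, Session, Source

_BREAKING = {BehaviorKind.BLOW_NEUTRAL, BehaviorKind.BLOW_WHEEZY, BehaviorKind.SURFACING}


def brute_force_counter_flags(session: Session) -> dict[str, bool]:
    """Counter-call status of every subject call by exhaustive timeline scan."""
    flags: dict[str, bool] = {}
    for call in session.calls:
        if call.source is not Source.SUBJECT:
            continue
        prior = None
        for other in session.calls:
            if other.onset_s < call.onset_s:
                if prior is None or other.onset_s > prior.onset_s:
                    prior = other
        if prior is None or prior.source is not Source.EXEMPLAR:
            flags[call.event_id] = False
            continue
        blocked = False
        for b in session.behaviors:
            if b.kind in _BREAKING and prior.offset_s < b.time_s < call.onset_s:
                blocked = True
        flags[call.event_id] = not blocked
    return flags
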