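"""Detection of showing events from coded dog behavior.

A showing is a (directional, attention-getting) pair of dog events that
either overlap in time or alternate with a gap of at most ``window``
seconds (default 2.0 s, inclusive bound; the order of the two components
does not matter).  Every qualifying pair counts once — a long state event
such as staying near a box can enter several showings with different
attention events.  A pair qualifying both ways is reported once as
``overlap``, the stronger relation.

``detect_showings`` is the production path (sorted sweep over attention
events); ``brute_force_detect`` is a deliberately literal quadratic
all-pairs scan kept as an independent oracle for equivalence testing.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from .codes import ATTENTION_CODES, DIRECTIONAL_CODES, classify_showing_type
from .events import BehaviorEvent, EventLog

__all__ = ["Showing", "intervals_qualify", "detect_showings", "brute_force_detect"]

DEFAULT_WINDOW: float = 2.0

_TIME_TOL = 1e-9  # absorbs float slop at the inclusive gap bound


@dataclass(frozen=True)
class Showing:
    """One detected showing: a qualifying (directional, attention) event pair."""

    directional_code: str
    attention_code: str
    type_id: int
    referent: int
    mode: str  # "overlap" | "alternation"
    anchor: float  # onset of the earlier component
    source_ids: tuple[int, int]  # indices of (directional, attention) events

    def sort_key(self) -> tuple:
        return (self.anchor, self.type_id, self.referent, self.source_ids)


def intervals_qualify(
    d: tuple[float, float],
    a: tuple[float, float],
    window: float = DEFAULT_WINDOW,
) -> str:
    """Classify the temporal relation of two half-open intervals.

    Returns ``"overlap"`` if they intersect, ``"alternation"`` if the gap
    from the earlier offset to the later onset is at most *window*
    (inclusive), else ``"none"``.  Symmetric in its two interval arguments.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    (d0, d1), (a0, a1) = d, a
    if d1 < d0 or a1 < a0:
        raise ValueError("invalid interval: offset before onset")
    if d0 < a1 and a0 < d1:
        return "overlap"
    gap = max(a0 - d1, d0 - a1)
    if gap <= window + _TIME_TOL:
        return "alternation"
    return "none"


def _make_showing(d: BehaviorEvent, a: BehaviorEvent, mode: str,
                  d_id: int, a_id: int) -> Showing:
    return Showing(
        directional_code=d.code,
        attention_code=a.code,
        type_id=classify_showing_type(d.code, a.code),
        referent=d.referent,
        mode=mode,
        anchor=min(d.onset, a.onset),
        source_ids=(d_id, a_id),
    )


def _split_components(log: EventLog) -> tuple[list, list]:
    """Analyzable dog events split into (directional, attention), with ids.

    Ids are indices into the analyzable dog-event sequence so that the two
    detectors assign identical identities.
    """
    directional, attention = [], []
    dog = [e for e in log.analyzable_events() if e.actor == "dog"]
    for i, e in enumerate(dog):
        if e.code in DIRECTIONAL_CODES:
            directional.append((i, e))
        elif e.code in ATTENTION_CODES:
            attention.append((i, e))
    return directional, attention


def detect_showings(log: EventLog, window: float = DEFAULT_WINDOW) -> list[Showing]:
    """Detect all showings in one event log.

    Owner events are ignored; dog events are clipped at a ``retrieve``
    onset.  Output is in canonical order (anchor, type_id, referent,
    source ids) and deterministic.
    """
    if window < 0:
        raise ValueError(f"window must be non-negative, got {window}")
    directional, attention = _split_components(log)
    if not directional or not attention:
        return []
    # sweep: attention events sorted by onset; for each directional event,
    # only attention onsets in [d.onset - window - max_a_dur, d.offset + window]
    # can qualify, so bisect the upper edge and scan down with an early stop.
    attention.sort(key=lambda ia: ia[1].onset)
    a_onsets = [a.onset for _, a in attention]
    max_a_dur = max(a.duration for _, a in attention)
    out: list[Showing] = []
    for d_id, d in directional:
        hi = bisect_right(a_onsets, d.offset + window + _TIME_TOL)
        lo_bound = d.onset - window - max_a_dur - _TIME_TOL
        for k in range(hi - 1, -1, -1):
            a_id, a = attention[k]
            if a.onset < lo_bound:
                break
            mode = intervals_qualify((d.onset, d.offset), (a.onset, a.offset), window)
            if mode != "none":
                out.append(_make_showing(d, a, mode, d_id, a_id))
    out.sort(key=Showing.sort_key)
    return out


def brute_force_detect(log: EventLog, window: float = DEFAULT_WINDOW) -> list[Showing]:
    """Literal quadratic all-pairs reference detector (test oracle only)."""
    directional, attention = _split_components(log)
    out: list[Showing] = []
    for d_id, d in directional:
        for a_id, a in attention:
            mode = intervals_qualify((d.onset, d.offset), (a.onset, a.offset), window)
            if mode != "none":
                out.append(_make_showing(d, a, mode, d_id, a_id))
    out.sort(key=Showing.sort_key)
    return out


def showings_to_records(log: EventLog, showings: list[Showing]) -> list[dict]:
    """Rows for the long showings table (one per detected showing)."""
    c = log.context
    return [
        {
            "pair": c.pair_id, "session": c.session, "condition": c.condition,
            "trial": c.trial, "phase": log.phase, "type_id": s.type_id,
            "directional": s.directional_code, "attention": s.attention_code,
            "referent": s.referent, "mode": s.mode, "anchor": round(s.anchor, 2),
        }
        for s in showings
    ]
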