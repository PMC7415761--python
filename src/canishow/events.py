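"""Domain containers for coded behavioral events.

Times are seconds from phase start on a 0.20 s grid.  Intervals are
half-open ``[onset, offset)`` so that abutting events (offset of one equals
onset of the next) do not overlap, matching frame-based coding.  A point
event occupies a single frame: ``offset = onset + 0.20``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .codes import BOX_REFERENT_CODES, GRID, RETRIEVE_CODE, VALID_CODES

__all__ = [
    "BehaviorEvent",
    "TrialContext",
    "EventLog",
    "EventValidationError",
    "snap_to_grid",
    "is_on_grid",
]


class EventValidationError(ValueError):
    """An event or log violates the coding conventions."""


def is_on_grid(t: float, resolution: float = GRID, tol: float = 1e-6) -> bool:
    """True if *t* is an integer multiple of *resolution* (within float slop)."""
    frames = round(t / resolution)
    return abs(t - frames * resolution) <= tol


def snap_to_grid(t: float, resolution: float = GRID) -> float:
    """Snap *t* (seconds, >= 0) to the nearest grid multiple; ties round half up.

    Idempotent: ``snap(snap(t)) == snap(t)``.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    # epsilon guards against 0.5-boundary values landing just below .5 in
    # binary float (e.g. 0.50 / 0.20 = 2.4999...)
    frames = math.floor(t / resolution + 0.5 + 1e-9)
    return round(frames * resolution, 10)


@dataclass(frozen=True)
class BehaviorEvent:
    """One coded behavior occurrence.

    Parameters
    ----------
    actor : {"dog", "owner"}
    code : behavior code from the ethogram (see :mod:`canishow.codes`).
    referent : box id 1-4 for box-directed codes, else ``None``.
    onset, offset : seconds from phase start, half-open interval, on the
        0.20 s grid; ``offset > onset``.
    annotation : optional free text (e.g. the owner sub-behavior that was
        collapsed into the composite ``owner_behavior`` code).
    """

    actor: str
    code: str
    referent: int | None
    onset: float
    offset: float
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.actor not in VALID_CODES:
            raise EventValidationError(f"unknown actor {self.actor!r}")
        if self.code not in VALID_CODES[self.actor]:
            raise EventValidationError(
                f"unknown code {self.code!r} for actor {self.actor!r}"
            )
        if self.onset < 0:
            raise EventValidationError(f"onset must be >= 0, got {self.onset}")
        if not self.offset > self.onset:
            raise EventValidationError(
                f"offset must exceed onset (half-open interval): "
                f"[{self.onset}, {self.offset})"
            )
        for name, t in (("onset", self.onset), ("offset", self.offset)):
            if not is_on_grid(t):
                raise EventValidationError(
                    f"{name} {t} is not on the {GRID} s grid"
                )
        if self.code in BOX_REFERENT_CODES:
            if self.referent not in (1, 2, 3, 4):
                raise EventValidationError(
                    f"box-directed code {self.code!r} needs referent in 1..4, "
                    f"got {self.referent!r}"
                )
        elif self.referent is not None:
            raise EventValidationError(
                f"code {self.code!r} must not carry a box referent "
                f"(got {self.referent!r})"
            )

    @property
    def duration(self) -> float:
        return round(self.offset - self.onset, 10)

    def sort_key(self) -> tuple:
        return (self.onset, self.offset, self.actor, self.code, self.referent or 0)

    def overlaps(self, other: "BehaviorEvent") -> bool:
        return self.onset < other.offset and other.onset < self.offset


@dataclass(frozen=True)
class TrialContext:
    """Metadata for one pair x session x trial.

    ``choice_phase1`` of 0 means the owner marked no box on the
    questionnaire; it is scored as an incorrect choice.  If the dog
    retrieved the toy itself in phase 1, both choices are set to the
    retrieved box (the location was then unambiguous to the owner).
    """

    pair_id: str
    session: int
    condition: str
    trial: int
    target_box: int | None = None
    choice_phase1: int | None = None
    choice_phase2: int | None = None
    dog_retrieved: bool = False
    phase_durations: dict[int, float] = field(default_factory=lambda: {1: 60.0, 2: 60.0})

    def __post_init__(self) -> None:
        if self.session not in (1, 2):
            raise EventValidationError(f"session must be 1 or 2, got {self.session}")
        if self.condition not in ("close", "far"):
            raise EventValidationError(
                f"condition must be 'close' or 'far', got {self.condition!r}"
            )
        if not 1 <= self.trial <= 4:
            raise EventValidationError(f"trial must be in 1..4, got {self.trial}")
        if self.target_box is not None and self.target_box not in (1, 2, 3, 4):
            raise EventValidationError(f"target_box must be 1..4, got {self.target_box}")
        if self.choice_phase1 is not None and self.choice_phase1 not in range(5):
            raise EventValidationError(
                f"choice_phase1 must be 0..4, got {self.choice_phase1}"
            )
        if self.choice_phase2 is not None and self.choice_phase2 not in (1, 2, 3, 4):
            raise EventValidationError(
                f"choice_phase2 must be 1..4, got {self.choice_phase2}"
            )

    def choice(self, phase: int) -> int | None:
        """Phase-matched choice: questionnaire mark (phase 1) or opened box."""
        if phase == 1:
            return self.choice_phase1
        if phase == 2:
            return self.choice_phase2
        raise ValueError(f"phase must be 1 or 2, got {phase}")

    @property
    def key(self) -> tuple:
        return (self.pair_id, self.session, self.trial)


@dataclass
class EventLog:
    """All events of one pair within one phase of one trial.

    Events are kept in canonical order (onset, then offset, then actor/code);
    construction sorts, and :meth:`add` re-sorts.
    """

    context: TrialContext
    phase: int
    events: list[BehaviorEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise EventValidationError(f"phase must be 1 or 2, got {self.phase}")
        self.events = sorted(self.events, key=BehaviorEvent.sort_key)

    @property
    def phase_duration(self) -> float:
        return self.context.phase_durations.get(self.phase, 60.0)

    @property
    def key(self) -> tuple:
        return (*self.context.key, self.phase)

    def add(self, event: BehaviorEvent) -> None:
        self.events.append(event)
        self.events.sort(key=BehaviorEvent.sort_key)

    def dog_events(self) -> list[BehaviorEvent]:
        return [e for e in self.events if e.actor == "dog"]

    def owner_events(self) -> list[BehaviorEvent]:
        return [e for e in self.events if e.actor == "owner"]

    def retrieve_onset(self) -> float | None:
        """Onset of the first ``retrieve`` event, if any."""
        onsets = [e.onset for e in self.events if e.code == RETRIEVE_CODE]
        return min(onsets) if onsets else None

    def analyzable_events(self) -> list[BehaviorEvent]:
        """Events clipped to the analyzable window.

        A ``retrieve`` terminates the window at its onset: later events are
        dropped, straddling events are truncated, and the retrieve event
        itself is excluded.
        """
        cut = self.retrieve_onset()
        if cut is None:
            return [e for e in self.events if e.code != RETRIEVE_CODE]
        out: list[BehaviorEvent] = []
        for e in self.events:
            if e.code == RETRIEVE_CODE or e.onset >= cut:
                continue
            if e.offset > cut:
                e = replace(e, offset=cut)
            out.append(e)
        return out
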