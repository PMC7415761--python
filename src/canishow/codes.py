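"""Behavior-code vocabulary for the showing paradigm.

A *showing* combines a directional component (a dog behavior referencing
one of the four hiding boxes) with an attention-getting component (a dog
behavior directed at the owner), either overlapping in time or alternating
within a short window.  The 5 x 3 grid of component combinations yields 15
showing types, numbered row-major with the directional component as the
outer index: type 1 is gaze-at-box + gaze-at-owner (classic gaze
alternation), type 15 is open-box + vocalize.
"""

from __future__ import annotations

#: Coding-grid resolution in seconds; all event times are multiples of this.
GRID: float = 0.20

DIRECTIONAL_CODES: tuple[str, ...] = (
    "gaze_box",
    "move_box",
    "near_box",
    "jump_box",
    "open_box",
)

ATTENTION_CODES: tuple[str, ...] = (
    "gaze_owner",
    "move_owner",
    "vocalize",
)

#: Dog behaviors that reference a box and therefore carry a referent 1-4.
BOX_REFERENT_CODES: frozenset[str] = frozenset(DIRECTIONAL_CODES)

#: Terminal event: the dog retrieves the toy itself; the trial outcome is
#: fixed from that moment, so the analyzable window ends at its onset.
RETRIEVE_CODE: str = "retrieve"

DOG_CODES: tuple[str, ...] = DIRECTIONAL_CODES + ATTENTION_CODES + (RETRIEVE_CODE,)

#: All owner behaviors are collapsed into one composite code; the original
#: sub-behavior (pointing, talking, name-calling, ...) may be carried in the
#: event's free-text annotation.
OWNER_CODES: tuple[str, ...] = ("owner_behavior",)

VALID_CODES: dict[str, tuple[str, ...]] = {"dog": DOG_CODES, "owner": OWNER_CODES}

#: type_id -> (directional_code, attention_code), row-major over the 5 x 3 grid.
TYPE_COMPONENTS: dict[int, tuple[str, str]] = {
    3 * i + j + 1: (d, a)
    for i, d in enumerate(DIRECTIONAL_CODES)
    for j, a in enumerate(ATTENTION_CODES)
}

_COMPONENTS_TO_TYPE: dict[tuple[str, str], int] = {
    v: k for k, v in TYPE_COMPONENTS.items()
}

#: Effort classes.  Low effort is the single least effortful strategy, gaze
#: alternation (type 1).  High effort is every pairing of the most effortful
#: directional component, jumping/standing upright (types 10-12), plus the
#: second most effortful strategy, move-towards-box + move-towards-owner
#: (type 5), added because many dogs never jump at all.
LOW_EFFORT_TYPES: frozenset[int] = frozenset({1})
HIGH_EFFORT_TYPES: frozenset[int] = frozenset({5, 10, 11, 12})


def classify_showing_type(directional_code: str, attention_code: str) -> int:
    """Map a (directional, attention) component pair to its type id 1-15.

    Raises ``ValueError`` if either code is outside its component set
    (including swapped arguments).
    """
    if directional_code not in DIRECTIONAL_CODES:
        raise ValueError(
            f"{directional_code!r} is not a directional component "
            f"(expected one of {DIRECTIONAL_CODES})"
        )
    if attention_code not in ATTENTION_CODES:
        raise ValueError(
            f"{attention_code!r} is not an attention-getting component "
            f"(expected one of {ATTENTION_CODES})"
        )
    return _COMPONENTS_TO_TYPE[(directional_code, attention_code)]


def showing_type_components(type_id: int) -> tuple[str, str]:
    """Inverse of :func:`classify_showing_type`."""
    try:
        return TYPE_COMPONENTS[type_id]
    except KeyError:
        raise ValueError(f"type_id must be in 1..15, got {type_id!r}") from None


def classify_effort(type_id: int) -> str:
    """Classify a showing type as ``'low'``, ``'high'`` or ``'other'`` effort."""
    if type_id not in TYPE_COMPONENTS:
        raise ValueError(f"type_id must be in 1..15, got {type_id!r}")
    if type_id in LOW_EFFORT_TYPES:
        return "low"
    if type_id in HIGH_EFFORT_TYPES:
        return "high"
    return "other"
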