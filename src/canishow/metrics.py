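"""Derived quantities: observation rows, type summaries, effort, reliability.

The unit of analysis is the observation cell — one pair x session x trial x
phase.  Per cell we count showings by type, score the proportion directed
at the target box (correct showing), the effort ratio (high-effort showings
over high + low), the owner-behavior frequency, and whether the owner's
phase choice hit the target (success).

Ratios over an empty denominator are *missing*, not zero: a cell with no
showings carries no evidence about showing accuracy, and such rows are
excluded from the models downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .codes import TYPE_COMPONENTS, classify_effort, showing_type_components
from .detector import Showing
from .events import EventLog, TrialContext

__all__ = [
    "ObservationRow",
    "classify_effort",
    "effort_score",
    "score_showings",
    "observations_to_frame",
    "summarize_types",
    "intercoder_reliability",
    "cicchetti_band",
]


@dataclass
class ObservationRow:
    """Scores for one pair x session x trial x phase cell."""

    pair_id: str
    session: int
    condition: str
    trial: int
    phase: int
    counts_by_type: tuple[int, ...]  # 15 entries, index = type_id - 1
    n_showings: int
    n_correct_showings: int
    prop_correct_showing: float | None
    n_low_effort: int
    n_high_effort: int
    effort: float | None
    owner_behavior_count: int
    choice: int | None
    success: bool

    def __post_init__(self) -> None:
        assert len(self.counts_by_type) == 15
        assert sum(self.counts_by_type) == self.n_showings
        assert self.n_correct_showings <= self.n_showings


def effort_score(showings: list[Showing]) -> float | None:
    """High-effort showings over high + low; ``None`` if neither occurs."""
    n_high = sum(1 for s in showings if classify_effort(s.type_id) == "high")
    n_low = sum(1 for s in showings if classify_effort(s.type_id) == "low")
    if n_high + n_low == 0:
        return None
    return n_high / (n_high + n_low)


def score_showings(
    showings: list[Showing],
    context: TrialContext,
    phase: int,
    owner_behavior_count: int = 0,
) -> ObservationRow:
    """Build the observation row for one cell.

    Success is scored against the phase-matched choice: the questionnaire
    mark in phase 1 (0 = no mark, always incorrect) and the opened box in
    phase 2.
    """
    choice = context.choice(phase)
    if choice is None:
        raise ValueError(
            f"pair {context.pair_id} s{context.session} t{context.trial}: "
            f"phase {phase} choice is missing; cannot score success"
        )
    counts = [0] * 15
    n_correct = 0
    for s in showings:
        counts[s.type_id - 1] += 1
        if context.target_box is not None and s.referent == context.target_box:
            n_correct += 1
    n = len(showings)
    n_low = sum(counts[t - 1] for t in TYPE_COMPONENTS if classify_effort(t) == "low")
    n_high = sum(counts[t - 1] for t in TYPE_COMPONENTS if classify_effort(t) == "high")
    return ObservationRow(
        pair_id=context.pair_id,
        session=context.session,
        condition=context.condition,
        trial=context.trial,
        phase=phase,
        counts_by_type=tuple(counts),
        n_showings=n,
        n_correct_showings=n_correct,
        prop_correct_showing=(n_correct / n) if n > 0 else None,
        n_low_effort=n_low,
        n_high_effort=n_high,
        effort=(n_high / (n_high + n_low)) if (n_high + n_low) > 0 else None,
        owner_behavior_count=owner_behavior_count,
        choice=choice,
        success=(context.target_box is not None and choice == context.target_box),
    )


def count_owner_behaviors(log: EventLog) -> int:
    """Frequency of the composite owner behavior within the analyzable window."""
    return sum(1 for e in log.analyzable_events() if e.actor == "owner")


def observations_to_frame(rows: list[ObservationRow]) -> pd.DataFrame:
    """Tidy table of observation rows (missing ratios become NaN)."""
    recs = []
    for r in rows:
        rec = {
            "pair": r.pair_id, "session": r.session, "condition": r.condition,
            "trial": r.trial, "phase": r.phase, "n_showings": r.n_showings,
            "n_correct_showings": r.n_correct_showings,
            "prop_correct_showing": (np.nan if r.prop_correct_showing is None
                                     else r.prop_correct_showing),
            "n_low_effort": r.n_low_effort, "n_high_effort": r.n_high_effort,
            "effort": np.nan if r.effort is None else r.effort,
            "owner_behavior_count": r.owner_behavior_count,
            "choice": r.choice, "success": int(r.success),
        }
        for t in range(1, 16):
            rec[f"type_{t}"] = r.counts_by_type[t - 1]
        recs.append(rec)
    return pd.DataFrame(recs)


def summarize_types(
    cells: list[tuple[TrialContext, int, list[Showing]]],
    *,
    choice_rate_phase: str = "matched",
) -> pd.DataFrame:
    """Per-type mean frequency, accuracy and choice rate.

    *cells* is one entry per observation cell: (context, phase, showings).
    Mean frequency is the average count per cell (cells with zero showings
    included).  Accuracy is the share of a type's showings directed at the
    target box; choice rate the share directed at the box the owner chose.
    ``choice_rate_phase`` selects the phase-matched choice (default) or
    ``"phase2"`` (the opened box for both phases).  Types that never occur
    get NaN accuracy/choice rate and ``occurs=False`` (a "never exhibited"
    flag, rendered as a dash in formatted output).
    """
    if choice_rate_phase not in ("matched", "phase2"):
        raise ValueError(f"choice_rate_phase must be 'matched' or 'phase2', "
                         f"got {choice_rate_phase!r}")
    n_cells = len(cells)
    counts = np.zeros(15, dtype=int)
    at_target = np.zeros(15, dtype=int)
    at_choice = np.zeros(15, dtype=int)
    for context, phase, showings in cells:
        choice = (context.choice(phase) if choice_rate_phase == "matched"
                  else context.choice_phase2)
        for s in showings:
            i = s.type_id - 1
            counts[i] += 1
            if context.target_box is not None and s.referent == context.target_box:
                at_target[i] += 1
            if choice is not None and s.referent == choice:
                at_choice[i] += 1
    recs = []
    for t in range(1, 16):
        i = t - 1
        d_code, a_code = showing_type_components(t)
        occurs = counts[i] > 0
        recs.append({
            "type_id": t, "directional": d_code, "attention": a_code,
            "mean_frequency": counts[i] / n_cells if n_cells else np.nan,
            "accuracy": at_target[i] / counts[i] if occurs else np.nan,
            "choice_rate": at_choice[i] / counts[i] if occurs else np.nan,
            "n_showings": int(counts[i]), "occurs": occurs,
        })
    return pd.DataFrame(recs)


def format_type_summary(summary: pd.DataFrame) -> str:
    """Render the 5 x 3 x 3 grid (frequency / accuracy / choice rate)."""
    directional_order = ["gaze_box", "move_box", "near_box", "jump_box", "open_box"]
    attention_order = ["gaze_owner", "move_owner", "vocalize"]
    blocks = []
    for measure in ("mean_frequency", "accuracy", "choice_rate"):
        lines = [measure.replace("_", " ").capitalize()]
        header = f"{'':24s}" + "".join(f"{a:>12s}" for a in attention_order)
        lines.append(header)
        for d in directional_order:
            cells = []
            for a in attention_order:
                row = summary[(summary.directional == d) & (summary.attention == a)]
                v = row.iloc[0][measure]
                occurs = bool(row.iloc[0]["occurs"])
                cells.append(f"{v:12.2f}" if occurs or measure == "mean_frequency"
                             else f"{'-':>12s}")
            lines.append(f"{d:24s}" + "".join(cells))
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks)


def build_observation_table(
    logs: list[EventLog],
    window: float = 2.0,
) -> tuple[pd.DataFrame, list[tuple[TrialContext, int, list[Showing]]]]:
    """Detect and score every log into the observation table.

    Returns the tidy per-cell table (one row per pair x session x trial x
    phase) plus the raw (context, phase, showings) cells for type summaries
    and the accuracy-time series.
    """
    from .detector import detect_showings

    rows: list[ObservationRow] = []
    cells: list[tuple[TrialContext, int, list[Showing]]] = []
    for log in logs:
        showings = detect_showings(log, window)
        rows.append(score_showings(showings, log.context, log.phase,
                                   count_owner_behaviors(log)))
        cells.append((log.context, log.phase, showings))
    return observations_to_frame(rows), cells


def showing_accuracy_series(
    cells: list[tuple[TrialContext, int, list[Showing]]],
) -> tuple[np.ndarray, np.ndarray]:
    """Per-showing accuracy flags and anchor seconds within the trial.

    Phase-2 anchors are offset by the phase-1 duration so the clock runs
    over the whole trial.
    """
    flags, seconds = [], []
    for context, phase, showings in cells:
        offset = context.phase_durations.get(1, 60.0) if phase == 2 else 0.0
        for s in showings:
            flags.append(1.0 if (context.target_box is not None
                                 and s.referent == context.target_box) else 0.0)
            seconds.append(s.anchor + offset)
    return np.asarray(flags), np.asarray(seconds)


def cicchetti_band(rho: float) -> str:
    """Conventional reliability band for a correlation-based agreement index.

    Cut points 0.40 / 0.60 / 0.75: below 0.40 poor, 0.40-0.59 fair,
    0.60-0.74 good, 0.75 and above excellent.
    """
    if math.isnan(rho):
        return "undefined"
    if rho < 0.40:
        return "poor"
    if rho < 0.60:
        return "fair"
    if rho < 0.75:
        return "good"
    return "excellent"


def intercoder_reliability(coder_a: pd.DataFrame, coder_b: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank agreement between two coders' per-video behavior totals.

    Inputs are aligned video x behavior tables (same index and columns).
    Returns per behavior: rho, p, the Cicchetti band, and a ``defined`` flag
    (False when either coder's column is constant, where rank correlation
    is undefined).
    """
    if list(coder_a.columns) != list(coder_b.columns) or len(coder_a) != len(coder_b):
        raise ValueError("coder tables must share shape and columns")
    if not (coder_a.index == coder_b.index).all():
        raise ValueError("coder tables must be aligned on the same videos")
    recs = []
    for col in coder_a.columns:
        x, y = coder_a[col].to_numpy(float), coder_b[col].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rho, p, defined = np.nan, np.nan, False
        else:
            rho, p = sps.spearmanr(x, y)
            defined = True
        recs.append({"behavior": col, "rho": rho, "p": p,
                     "band": cicchetti_band(rho if defined else float("nan")),
                     "defined": defined})
    return pd.DataFrame(recs)
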