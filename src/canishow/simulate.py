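"""Synthetic dyadic event-log generator.

Emulates the statistical structure of a hidden-object showing study: 30
dog-owner pairs, 2 sessions (one condition each, order counterbalanced) x 4
trials x 2 phases of 60 s, 4 hiding boxes with each box target twice per
pair and never twice in consecutive trials.

Event streams are homogeneous Poisson onsets per behavior code with
exponential durations snapped to the 0.20 s coding grid (minimum one
frame).  Box-directed events point at the trial's target box with
probability ``p_correct`` and otherwise uniformly at one of the other three
boxes.  The owner's choice is generated so that success follows a logistic
model on the *realized* correct-showing proportion of the generated log
(plus a pair-level random intercept), which makes the success GLMM's
estimand exactly the generator slope ``beta_correct``.

Default rates are loosely anchored to the observed mean per-phase showing
frequencies of the paradigm (gazing/moving/staying-near showings frequent,
jumping and box-opening rare); they are conditions of the study emulation,
not tuning knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .codes import BOX_REFERENT_CODES, GRID
from .detector import DEFAULT_WINDOW, Showing, brute_force_detect, detect_showings
from .events import BehaviorEvent, EventLog, TrialContext

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_phase_log",
    "simulate_dataset",
    "simulate_effort_rows",
    "make_worked_fixture",
]

#: events per minute, per behavior code
DEFAULT_RATES: dict[str, float] = {
    "gaze_box": 6.0,
    "move_box": 2.5,
    "near_box": 3.0,
    "jump_box": 0.4,
    "open_box": 0.05,
    "gaze_owner": 5.0,
    "move_owner": 2.5,
    "vocalize": 0.8,
    "owner_behavior": 4.0,
}

#: mean event duration in seconds (exponential, grid-snapped, >= one frame)
DEFAULT_DURATION_MEANS: dict[str, float] = {
    "gaze_box": 1.0,
    "move_box": 1.5,
    "near_box": 6.0,
    "jump_box": 1.5,
    "open_box": 1.0,
    "gaze_owner": 1.0,
    "move_owner": 1.5,
    "vocalize": 0.6,
    "owner_behavior": 1.5,
}

#: mild condition shifts mirroring the reported direction of condition
#: differences (gazes/moves up in far, near-box and vocalizing up in close)
DEFAULT_CONDITION_MULTIPLIERS: dict[str, dict[str, float]] = {
    "far": {"gaze_box": 1.10, "move_box": 1.15, "move_owner": 1.15},
    "close": {"near_box": 1.10, "vocalize": 1.30},
}


@dataclass
class SimConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    n_pairs: int = 30
    sessions: int = 2
    trials_per_session: int = 4
    phases: int = 2
    phase_duration: float = 60.0
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    duration_means: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DURATION_MEANS))
    condition_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in
                                 DEFAULT_CONDITION_MULTIPLIERS.items()})
    p_correct: float = 0.35
    beta0: float = -2.2
    beta_correct: float = 6.8
    sigma_pair: float = 0.5
    p_no_mark: float = 0.02  # phase-1 failures occasionally left blank (choice 0)
    detector_window: float = DEFAULT_WINDOW
    seed: int | None = None

    def validate(self) -> None:
        if any(r < 0 for r in self.rates.values()):
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must be in [0, 1]")
        if not 0.0 <= self.p_no_mark <= 1.0:
            raise ValueError("p_no_mark must be in [0, 1]")
        if self.phase_duration <= 0:
            raise ValueError("phase_duration must be positive")
        if self.sigma_pair < 0:
            raise ValueError("sigma_pair must be non-negative")


@dataclass
class GroundTruth:
    """Generator truth stored alongside outputs for recovery tests."""

    config: SimConfig
    per_observation: pd.DataFrame  # pair, session, condition, trial, phase,
    #                                prop_correct, success_prob, u_pair, success
    u_pair: dict[str, float] = field(default_factory=dict)


#: state-like behaviors: two simultaneous occurrences of the same state at
#: the same referent cannot be coded, so overlapping draws are resolved
_STATE_LIKE_CODES = frozenset({"near_box", "gaze_box", "owner_behavior"})


def _resolve_state_overlaps(onset_frames, dur_frames, referents):
    """Drop same-frame duplicates and truncate a state event at the next
    onset of the same (code, referent) state."""
    keep_on, keep_dur, keep_ref = [], [], []
    for ref in np.unique(referents):
        mask = referents == ref
        order = np.argsort(onset_frames[mask], kind="stable")
        ons, durs = onset_frames[mask][order], dur_frames[mask][order]
        last_onset = -1
        for j in range(len(ons)):
            if ons[j] == last_onset:
                continue  # duplicate onset frame: one state occurrence
            last_onset = ons[j]
            d = durs[j]
            if j + 1 < len(ons):
                d = min(d, ons[j + 1] - ons[j])
            keep_on.append(ons[j])
            keep_dur.append(max(d, 1))
            keep_ref.append(ref)
    return (np.asarray(keep_on, dtype=int), np.asarray(keep_dur, dtype=int),
            np.asarray(keep_ref, dtype=int))


def _rate_for(config: SimConfig, code: str, condition: str) -> float:
    mult = config.condition_multipliers.get(condition, {}).get(code, 1.0)
    return config.rates.get(code, 0.0) * mult


def simulate_phase_log(
    config: SimConfig,
    context: TrialContext,
    phase: int,
    rng: np.random.Generator,
) -> EventLog:
    """Draw one phase's event log.

    Poisson event counts per code at the condition-adjusted rate, uniform
    grid onsets, exponential grid-snapped durations clipped to the phase
    window, target-biased box referents.
    """
    config.validate()
    duration = context.phase_durations.get(phase, config.phase_duration)
    n_frames = int(round(duration / GRID))
    events: list[BehaviorEvent] = []
    for code in sorted(config.rates):
        rate = _rate_for(config, code, context.condition)
        if rate <= 0:
            continue
        n = rng.poisson(rate / 60.0 * duration)
        if n == 0:
            continue
        actor = "owner" if code == "owner_behavior" else "dog"
        onset_frames = rng.integers(0, n_frames, size=n)
        dur_frames = np.maximum(
            1, np.round(rng.exponential(config.duration_means[code], size=n)
                        / GRID).astype(int))
        referents = np.zeros(n, dtype=int)
        if code in BOX_REFERENT_CODES:
            if context.target_box is None:
                raise ValueError("context needs a target_box to simulate")
            correct = rng.random(n) < config.p_correct
            others = np.array([b for b in (1, 2, 3, 4)
                               if b != context.target_box])
            referents = np.where(correct, context.target_box,
                                 others[rng.integers(0, 3, size=n)])
        if code in _STATE_LIKE_CODES:
            onset_frames, dur_frames, referents = _resolve_state_overlaps(
                onset_frames, dur_frames, referents)
        for of, df_, ref in zip(onset_frames, dur_frames, referents):
            onset = round(of * GRID, 10)
            offset = round(min((of + df_) * GRID, duration), 10)
            referent = int(ref) if code in BOX_REFERENT_CODES else None
            events.append(BehaviorEvent(actor=actor, code=code,
                                        referent=referent,
                                        onset=onset, offset=offset))
    return EventLog(context=context, phase=phase, events=events)


def _session_targets(rng: np.random.Generator) -> list[int]:
    """A random permutation of the four boxes: each box once per session,
    hence twice per pair over two sessions, never repeated consecutively."""
    return list(rng.permutation([1, 2, 3, 4]) )


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def simulate_dataset(
    config: SimConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[EventLog], dict[tuple, TrialContext], GroundTruth]:
    """Generate a full balanced dataset plus ground truth.

    Returns event logs (one per pair x session x trial x phase), the trial
    contexts keyed by (pair, session, trial) with generated choices filled
    in, and the :class:`GroundTruth` table.

    The owner's choice per phase is drawn so that success (choice = target)
    is Bernoulli with probability ``sigmoid(beta0 + beta_correct * prop +
    u_pair)`` where *prop* is the realized correct-showing proportion of
    that cell's detected showings; a cell with no showings falls back to
    the intercept + random effect alone (such rows are missing for the
    models anyway).  Failures pick a uniform wrong box, except a small
    fraction of phase-1 failures left blank on the questionnaire (choice 0).
    """
    if config is None:
        config = SimConfig()
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))

    logs: list[EventLog] = []
    contexts: dict[tuple, TrialContext] = {}
    gt_rows: list[dict] = []
    u_pairs: dict[str, float] = {}

    for i in range(config.n_pairs):
        pair_id = f"pair{i + 1:02d}"
        u = float(rng.normal(0.0, config.sigma_pair))
        u_pairs[pair_id] = u
        # counterbalanced condition order
        order = ("close", "far") if i % 2 == 0 else ("far", "close")
        for session in range(1, config.sessions + 1):
            condition = order[session - 1]
            targets = _session_targets(rng)
            for trial in range(1, config.trials_per_session + 1):
                ctx = TrialContext(
                    pair_id=pair_id, session=session, condition=condition,
                    trial=trial, target_box=targets[trial - 1],
                    phase_durations={p: config.phase_duration
                                     for p in range(1, config.phases + 1)},
                )
                phase_logs, choices = [], {}
                for phase in range(1, config.phases + 1):
                    log = simulate_phase_log(config, ctx, phase, rng)
                    showings = detect_showings(log, config.detector_window)
                    n = len(showings)
                    prop = (sum(1 for s in showings
                                if s.referent == ctx.target_box) / n
                            if n else None)
                    eta = config.beta0 + u + (config.beta_correct * prop
                                              if prop is not None else 0.0)
                    p_succ = _sigmoid(eta)
                    success = rng.random() < p_succ
                    if success:
                        choice = ctx.target_box
                    elif phase == 1 and rng.random() < config.p_no_mark:
                        choice = 0
                    else:
                        others = [b for b in (1, 2, 3, 4) if b != ctx.target_box]
                        choice = others[rng.integers(0, 3)]
                    choices[phase] = choice
                    phase_logs.append(log)
                    gt_rows.append({
                        "pair": pair_id, "session": session,
                        "condition": condition, "trial": trial, "phase": phase,
                        "prop_correct": (np.nan if prop is None else prop),
                        "success_prob": p_succ, "u_pair": u,
                        "success": int(success),
                    })
                ctx = replace(ctx, choice_phase1=choices.get(1),
                              choice_phase2=choices.get(2, choices.get(1)))
                contexts[ctx.key] = ctx
                for log in phase_logs:
                    log.context = ctx
                    logs.append(log)
    truth = GroundTruth(config=config,
                        per_observation=pd.DataFrame(gt_rows),
                        u_pair=u_pairs)
    return logs, contexts, truth


def simulate_effort_rows(
    rng: np.random.Generator | int,
    n_pairs: int = 30,
    phase_effect: float = -0.05,
    baseline: float = 0.35,
    sigma_pair: float = 0.06,
    sigma_resid: float = 0.12,
) -> pd.DataFrame:
    """Gaussian observation-row generator for LMM recovery.

    Effort per cell = baseline + phase_effect * [phase == 2] + pair random
    intercept + residual noise, over the full 2 x 4 x 2 design.  The truth
    is exact at the row level (unlike the event-level generator, where the
    effort effect is an emergent quantity), so this is the recovery target
    for the effort LMM.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rows = []
    for i in range(n_pairs):
        pair_id = f"pair{i + 1:02d}"
        u = rng.normal(0.0, sigma_pair)
        order = ("close", "far") if i % 2 == 0 else ("far", "close")
        for session in (1, 2):
            for trial in (1, 2, 3, 4):
                for phase in (1, 2):
                    effort = (baseline + (phase_effect if phase == 2 else 0.0)
                              + u + rng.normal(0.0, sigma_resid))
                    rows.append({"pair": pair_id, "session": session,
                                 "condition": order[session - 1],
                                 "trial": trial, "phase": phase,
                                 "effort": effort})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# handcrafted worked fixture
# ---------------------------------------------------------------------------

_DIRECTIONAL_ORDER = ("gaze_box", "move_box", "near_box", "jump_box", "open_box")
_ATTENTION_ORDER = ("gaze_owner", "move_owner", "vocalize")


def make_worked_fixture() -> tuple[EventLog, list[Showing]]:
    """A hand-enumerated regression fixture.

    One block per showing type, 8 s apart so blocks cannot cross-pair:
    even blocks alternate with a 1.0 s gap, odd blocks overlap.  Two extra
    boundary blocks probe the window rule: a gap of exactly 2.0 s (included,
    inclusive bound) and a gap of 2.2 s (excluded).  The expected showing
    list is enumerated by hand below and cross-checked against the
    brute-force detector at build time.
    """
    events: list[BehaviorEvent] = []
    expected: list[Showing] = []
    from .codes import classify_showing_type

    event_id = 0
    for k in range(15):
        t0 = 8.0 * k
        d_code = _DIRECTIONAL_ORDER[k // 3]
        a_code = _ATTENTION_ORDER[k % 3]
        box = (k % 4) + 1
        if k % 2 == 0:  # alternation, gap 1.0 s
            d = BehaviorEvent("dog", d_code, box, t0, round(t0 + 1.0, 10))
            a = BehaviorEvent("dog", a_code, None, round(t0 + 2.0, 10),
                              round(t0 + 2.4, 10))
            mode = "alternation"
        else:  # overlap
            d = BehaviorEvent("dog", d_code, box, t0, round(t0 + 2.0, 10))
            a = BehaviorEvent("dog", a_code, None, round(t0 + 1.0, 10),
                              round(t0 + 1.4, 10))
            mode = "overlap"
        events += [d, a]
        expected.append(Showing(
            directional_code=d_code, attention_code=a_code,
            type_id=classify_showing_type(d_code, a_code), referent=box,
            mode=mode, anchor=t0, source_ids=(event_id, event_id + 1)))
        event_id += 2

    # boundary: gap exactly 2.0 s -> included (inclusive bound)
    t0 = 120.0
    events += [BehaviorEvent("dog", "gaze_box", 1, t0, t0 + 1.0),
               BehaviorEvent("dog", "gaze_owner", None, t0 + 3.0, t0 + 3.4)]
    expected.append(Showing("gaze_box", "gaze_owner", 1, 1, "alternation",
                            t0, (event_id, event_id + 1)))
    event_id += 2
    # boundary: gap 2.2 s -> excluded
    t0 = 128.0
    events += [BehaviorEvent("dog", "gaze_box", 2, t0, t0 + 1.0),
               BehaviorEvent("dog", "gaze_owner", None, t0 + 3.2, t0 + 3.6)]
    event_id += 2

    context = TrialContext(pair_id="fixture", session=1, condition="close",
                           trial=1, target_box=1, choice_phase1=1,
                           choice_phase2=1,
                           phase_durations={1: 140.0, 2: 140.0})
    log = EventLog(context=context, phase=1, events=events)
    expected.sort(key=Showing.sort_key)

    check = brute_force_detect(log)
    if check != expected:
        raise AssertionError(
            "worked fixture enumeration disagrees with the brute-force "
            "detector; fixture construction is broken")
    return log, expected
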