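"""Shared test utilities: deterministic fixture generators and frozen
reference values from independent mixed-model software."""

from __future__ import annotations

import numpy as np
import pandas as pd

from canishow.codes import ATTENTION_CODES, DIRECTIONAL_CODES, RETRIEVE_CODE
from canishow.events import BehaviorEvent, EventLog, TrialContext

GRID = 0.20


def glmm_oracle_fixture() -> pd.DataFrame:
    """Deterministic logistic random-intercept dataset (24 groups x 16)."""
    rng = np.random.default_rng(42)
    rows = []
    for g in range(24):
        u = rng.normal(0, 0.8)
        x = rng.normal(size=16)
        eta = -0.5 + 1.2 * x + u
        y = (rng.random(16) < 1 / (1 + np.exp(-eta))).astype(int)
        for xi, yi in zip(x, y):
            rows.append({"g": f"g{g:02d}", "x": xi, "y": yi})
    return pd.DataFrame(rows)


#: reference fit of glmm_oracle_fixture from lme4::glmer (binomial, nAGQ=25)
GLMM_ORACLE = {
    "beta": (-0.2005365344, 0.9373909805),
    "se": (0.1760249886, 0.1397738189),
    "sigma_u": 0.6529056802,
    "loglik": -232.7180144737,
}


def lmm_oracle_fixture() -> pd.DataFrame:
    """Deterministic Gaussian random-intercept dataset (20 groups x 12)."""
    rng = np.random.default_rng(7)
    rows = []
    for g in range(20):
        u = rng.normal(0, 0.6)
        x = rng.normal(size=12)
        y = 1.0 + 0.5 * x + u + rng.normal(0, 0.9, size=12)
        for xi, yi in zip(x, y):
            rows.append({"g": f"g{g:02d}", "x": xi, "y": yi})
    return pd.DataFrame(rows)


#: reference fit of lmm_oracle_fixture from lmerTest::lmer (REML,
#: Satterthwaite df)
LMM_ORACLE = {
    "beta": (0.8103401639, 0.5464111859),
    "se": (0.16827265013, 0.06371805397),
    "df": (19.01143769, 221.35917740),
    "sigma_u2": 0.5040763877,
    "sigma_e2": 0.7417006576,
    "loglik": -328.5295754916,
}


def random_event_log(rng: np.random.Generator, max_events: int = 300,
                     p_retrieve: float = 0.05) -> EventLog:
    """A random dog/owner event log on the grid, for detector equivalence."""
    n = int(rng.integers(0, max_events + 1))
    duration = 200.0
    codes = list(DIRECTIONAL_CODES + ATTENTION_CODES) + ["owner_behavior"]
    events = []
    for _ in range(n):
        code = codes[rng.integers(0, len(codes))]
        actor = "owner" if code == "owner_behavior" else "dog"
        onset_frame = int(rng.integers(0, 900))
        dur_frames = int(rng.integers(1, 26))
        referent = (int(rng.integers(1, 5))
                    if code in DIRECTIONAL_CODES else None)
        events.append(BehaviorEvent(
            actor=actor, code=code, referent=referent,
            onset=round(onset_frame * GRID, 10),
            offset=round(min((onset_frame + dur_frames) * GRID, duration), 10)))
    if n and rng.random() < p_retrieve:
        onset_frame = int(rng.integers(100, 900))
        events.append(BehaviorEvent(
            actor="dog", code=RETRIEVE_CODE, referent=None,
            onset=round(onset_frame * GRID, 10),
            offset=round((onset_frame + 1) * GRID, 10)))
    context = TrialContext(pair_id="rand", session=1, condition="close",
                           trial=1, target_box=1, choice_phase1=1,
                           choice_phase2=1,
                           phase_durations={1: duration, 2: duration})
    return EventLog(context=context, phase=1, events=events)


def tiny_log(events, phase_duration: float = 60.0, target: int = 2) -> EventLog:
    """Wrap a list of events in a minimal valid log."""
    context = TrialContext(pair_id="t", session=1, condition="close", trial=1,
                           target_box=target, choice_phase1=target,
                           choice_phase2=target,
                           phase_durations={1: phase_duration, 2: phase_duration})
    return EventLog(context=context, phase=1, events=list(events))


def dog(code, onset, offset, referent=None) -> BehaviorEvent:
    return BehaviorEvent(actor="dog", code=code, referent=referent,
                         onset=onset, offset=offset)
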