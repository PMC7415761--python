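"""Observation scoring, effort, type summaries and inter-coder reliability."""

import numpy as np
import pandas as pd
import pytest

from canishow import (
    Showing,
    TrialContext,
    build_observation_table,
    cicchetti_band,
    classify_effort,
    detect_showings,
    effort_score,
    intercoder_reliability,
    score_showings,
    summarize_types,
)
from canishow.codes import classify_showing_type, showing_type_components

from helpers import dog, tiny_log


def mk_showing(type_id: int, referent: int, anchor: float = 0.0) -> Showing:
    d, a = showing_type_components(type_id)
    return Showing(directional_code=d, attention_code=a, type_id=type_id,
                   referent=referent, mode="alternation", anchor=anchor,
                   source_ids=(0, 1))


def mk_context(target=2, choice1=2, choice2=2, condition="close") -> TrialContext:
    return TrialContext("p01", 1, condition, 1, target_box=target,
                        choice_phase1=choice1, choice_phase2=choice2)


class TestEffort:
    def test_effort_classes(self):
        assert classify_effort(classify_showing_type("gaze_box", "gaze_owner")) == "low"
        assert classify_effort(classify_showing_type("jump_box", "vocalize")) == "high"
        assert classify_effort(classify_showing_type("move_box", "move_owner")) == "high"
        assert classify_effort(classify_showing_type("near_box", "gaze_owner")) == "other"
        with pytest.raises(ValueError):
            classify_effort(16)

    def test_effort_score_arithmetic(self):
        high = [mk_showing(10, 1)] * 3
        low = [mk_showing(1, 1)]
        assert effort_score(high + low) == pytest.approx(0.75)
        assert effort_score([mk_showing(1, 1)] * 5) == 0.0
        # only 'other' types: denominator empty -> undefined
        assert effort_score([mk_showing(4, 1)] * 4) is None


class TestScoreShowings:
    def test_proportion_correct(self):
        ctx = mk_context(target=2)
        showings = [mk_showing(1, 2), mk_showing(1, 2), mk_showing(4, 2),
                    mk_showing(1, 3)]
        row = score_showings(showings, ctx, phase=1)
        assert row.n_showings == 4
        assert row.prop_correct_showing == pytest.approx(0.75)
        assert row.success is True

    def test_zero_showings_proportion_missing_success_still_scored(self):
        row = score_showings([], mk_context(target=2, choice1=3), phase=1)
        assert row.prop_correct_showing is None
        assert row.effort is None
        assert row.success is False

    def test_blank_questionnaire_scored_incorrect(self):
        ctx = mk_context(target=2, choice1=0)
        row = score_showings([mk_showing(1, 2)], ctx, phase=1)
        assert row.success is False

    def test_missing_choice_raises(self):
        ctx = TrialContext("p01", 1, "close", 1, target_box=2, choice_phase2=2)
        with pytest.raises(ValueError, match="choice is missing"):
            score_showings([], ctx, phase=1)

    def test_conservation_invariants(self, default_observations):
        obs, cells = default_observations
        type_cols = [f"type_{t}" for t in range(1, 16)]
        assert (obs[type_cols].sum(axis=1) == obs["n_showings"]).all()
        assert (obs["n_correct_showings"] <= obs["n_showings"]).all()
        defined = obs["prop_correct_showing"].dropna()
        assert ((defined >= 0) & (defined <= 1)).all()
        undefined_effort = obs["effort"].isna()
        assert (undefined_effort == ((obs.n_low_effort + obs.n_high_effort) == 0)).all()

    def test_box_relabeling_invariance(self):
        """A consistent permutation of box labels leaves the scores unchanged."""
        perm = {1: 3, 2: 1, 3: 4, 4: 2}
        events = [dog("gaze_box", 1.0, 2.0, referent=2),
                  dog("gaze_owner", 2.4, 2.8),
                  dog("move_box", 5.0, 6.0, referent=4),
                  dog("move_owner", 6.2, 6.6)]
        ctx = mk_context(target=2, choice1=4, choice2=2)
        base = score_showings(detect_showings(tiny_log(events)), ctx, 1)

        events_p = [dog(e.code, e.onset, e.offset,
                        perm[e.referent] if e.referent else None) for e in events]
        ctx_p = mk_context(target=perm[2], choice1=perm[4], choice2=perm[2])
        permuted = score_showings(detect_showings(tiny_log(events_p)), ctx_p, 1)
        for attr in ("n_showings", "prop_correct_showing", "effort", "success",
                     "n_low_effort", "n_high_effort"):
            assert getattr(base, attr) == getattr(permuted, attr)


class TestSummarizeTypes:
    def test_all_showings_at_target_gives_unit_accuracy(self):
        ctx = mk_context(target=2)
        cells = [(ctx, 1, [mk_showing(1, 2), mk_showing(5, 2)])]
        summary = summarize_types(cells)
        occ = summary[summary.occurs]
        assert (occ.accuracy == 1.0).all()

    def test_single_cell_half_accuracy(self):
        ctx = mk_context(target=2)
        cells = [(ctx, 1, [mk_showing(1, 2), mk_showing(1, 3)])]
        summary = summarize_types(cells)
        row = summary[summary.type_id == 1].iloc[0]
        assert row.accuracy == pytest.approx(0.5)
        assert row.mean_frequency == pytest.approx(2.0)

    def test_never_occurring_type_flagged(self):
        ctx = mk_context()
        summary = summarize_types([(ctx, 1, [mk_showing(1, 2)])])
        missing = summary[summary.type_id == 13].iloc[0]
        assert not missing.occurs
        assert np.isnan(missing.accuracy) and np.isnan(missing.choice_rate)

    def test_accuracy_matches_direct_recount(self, default_observations):
        obs, cells = default_observations
        summary = summarize_types(cells)
        # independent recount from the raw showings
        for t in (1, 5, 7):
            num = den = 0
            for ctx, phase, showings in cells:
                for s in showings:
                    if s.type_id == t:
                        den += 1
                        num += int(s.referent == ctx.target_box)
            row = summary[summary.type_id == t].iloc[0]
            if den:
                assert row.accuracy == pytest.approx(num / den)
            else:
                assert not row.occurs

    def test_choice_rate_phase_switch(self):
        ctx = mk_context(target=2, choice1=3, choice2=2)
        cells = [(ctx, 1, [mk_showing(1, 3)])]
        matched = summarize_types(cells, choice_rate_phase="matched")
        phase2 = summarize_types(cells, choice_rate_phase="phase2")
        assert matched[matched.type_id == 1].iloc[0].choice_rate == 1.0
        assert phase2[phase2.type_id == 1].iloc[0].choice_rate == 0.0


class TestIntercoderReliability:
    def _tables(self, values_a, values_b):
        idx = [f"v{i}" for i in range(len(values_a))]
        return (pd.DataFrame({"gaze_freq": values_a}, index=idx),
                pd.DataFrame({"gaze_freq": values_b}, index=idx))

    def test_identical_tables_excellent(self):
        a, b = self._tables([3, 1, 4, 1, 5, 9], [3, 1, 4, 1, 5, 9])
        out = intercoder_reliability(a, b)
        assert out.iloc[0].rho == pytest.approx(1.0)
        assert out.iloc[0].band == "excellent"

    def test_reversed_ranks(self):
        a, b = self._tables([1, 2, 3, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert intercoder_reliability(a, b).iloc[0].rho == pytest.approx(-1.0)

    def test_constant_vector_undefined(self):
        a, b = self._tables([2, 2, 2, 2, 2, 2], [1, 2, 3, 4, 5, 6])
        row = intercoder_reliability(a, b).iloc[0]
        assert not row.defined and row.band == "undefined"

    def test_shape_mismatch_rejected(self):
        a, _ = self._tables([1, 2, 3], [1, 2, 3])
        b = pd.DataFrame({"other": [1, 2, 3]}, index=a.index)
        with pytest.raises(ValueError):
            intercoder_reliability(a, b)

    @pytest.mark.parametrize("rho,band", [
        (0.39, "poor"), (0.40, "fair"), (0.59, "fair"),
        (0.60, "good"), (0.74, "good"), (0.75, "excellent"), (0.97, "excellent"),
    ])
    def test_cicchetti_cut_points(self, rho, band):
        assert cicchetti_band(rho) == band
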