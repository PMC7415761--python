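"""Detect showing events in a small hand-built event log.

A showing pairs a box-directed behavior with an owner-directed
attention-getting behavior that overlaps it or follows/precedes it within
2 seconds.
"""

from canishow import BehaviorEvent, EventLog, TrialContext, detect_showings

context = TrialContext(pair_id="demo", session=1, condition="close", trial=1,
                       target_box=2, choice_phase1=2, choice_phase2=2)
log = EventLog(context=context, phase=1, events=[
    BehaviorEvent("dog", "gaze_box", 2, 1.0, 2.0),     # looks at box 2
    BehaviorEvent("dog", "gaze_owner", None, 2.6, 3.0),  # then at the owner
    BehaviorEvent("dog", "near_box", 3, 10.0, 20.0),   # parks near box 3
    BehaviorEvent("dog", "vocalize", None, 12.0, 12.4),  # barks meanwhile
    BehaviorEvent("dog", "gaze_owner", None, 30.0, 31.0),  # too late: gap 10 s
])

for s in detect_showings(log):
    print(f"type {s.type_id:2d}  {s.directional_code} + {s.attention_code}  "
          f"box {s.referent}  {s.mode}  at {s.anchor:.1f} s")

# Two showings: a gaze alternation at box 2 (the target) and an overlap of
# staying near box 3 with a vocalization.  The last gaze at the owner pairs
# with nothing: the 10 s gap exceeds the 2 s window.
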