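"""Inter-coder reliability from two coders' per-video behavior totals.

Agreement is Spearman rank correlation per behavior, labeled with the
conventional bands (poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent).
"""

import pandas as pd

from canishow import intercoder_reliability

videos = [f"video{i}" for i in range(1, 7)]
coder_a = pd.DataFrame({
    "gaze_freq": [12, 5, 20, 8, 15, 3],
    "near_box_dur": [30.4, 12.0, 55.2, 20.8, 44.0, 8.6],
    "vocalize_freq": [2, 0, 7, 1, 4, 0],
}, index=videos)
coder_b = pd.DataFrame({
    "gaze_freq": [11, 6, 18, 9, 14, 4],
    "near_box_dur": [29.0, 13.2, 54.0, 22.4, 41.8, 9.0],
    "vocalize_freq": [2, 1, 6, 1, 5, 0],
}, index=videos)

print(intercoder_reliability(coder_a, coder_b).to_string(index=False))

# rho near 1 with the "excellent" band means the two coders ranked the six
# videos almost identically on that behavior.
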