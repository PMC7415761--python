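"""Simulate a small study and score it into observation cells.

Each cell is one pair x session x trial x phase; the scores are the
showing counts, the share of showings at the target box (correct showing),
the effort ratio (high-effort over high + low), and success.
"""

from canishow import SimConfig, build_observation_table, simulate_dataset, summarize_types
from canishow.metrics import format_type_summary

logs, contexts, truth = simulate_dataset(SimConfig(n_pairs=6, seed=42))
obs, cells = build_observation_table(logs)

print(f"{len(obs)} observation cells, {obs.n_showings.sum()} showings total")
print(f"overall success rate:        {obs.success.mean():.3f}")
print(f"mean correct-showing prop.:  {obs.prop_correct_showing.mean():.3f}")
print(f"mean effort ratio:           {obs.effort.mean():.3f}")
print()
print(format_type_summary(summarize_types(cells)))

# The frequency block shows which of the 15 showing types the simulated
# dogs used; accuracy is the share of each type's showings aimed at the
# target box (chance would be 0.25), choice rate the share aimed at the
# box the owner picked.
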