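"""Quantify the diversity contribution of nonnative taxa by removal.

Compares observed per-sample richness against communities with (a) every
flagged taxon removed from its habitat and (b) an equal number of random taxa
removed from the habitat pool.  When flagged taxa occupy more samples than
the pool average, targeted removal erodes richness more than random removal.
"""

import pandas as pd

from habniche import SimulationConfig, compare_removals, simulate_metacommunity

cfg = SimulationConfig(
    n_habitats=4, samples_per_habitat=12, natives_per_habitat=80,
    regional_generalists=20, native_occupancy=0.4, colonist_occupancy=0.9,
    colonist_abundance_factor=0.3, depth=3000, seed=3,
)
table, _, truth = simulate_metacommunity(cfg)
calls = pd.DataFrame(
    [{"taxon_id": t, "habitat": h, "nonnative": True}
     for t, h in sorted(truth.nonnative_pairs)]
)

result = compare_removals(table, calls, replicates=100, seed=1)
cols = ["observed_norm", "targeted_norm", "random_mean_norm"]
print(result.per_sample.groupby("habitat")[cols].mean().round(3))
print()
tr = result.stats[result.stats["comparison"] == "targeted_vs_random"]
print(tr[["habitat", "mean_diff", "t", "p_adj"]].to_string(index=False))
print("\nnegative mean_diff with adjusted p < 0.05: communities stripped of "
      "their colonists are significantly poorer than communities that lost "
      "the same number of random taxa")
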