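"""Functional richness and C/N/P/S redundancy under removal scenarios.

The simulator assigns part of each biogeochemical function set exclusively to
colonist taxa; removing those taxa therefore erases functions entirely, which
shows up as lower functional richness and lower Rao-type redundancy than
random removal of equally many taxa.
"""

import pandas as pd

from habniche import (
    SimulationConfig,
    simulate_function_table,
    simulate_metacommunity,
    simulate_sequences,
)
from habniche.functional import removal_functional_comparison

cfg = SimulationConfig(
    n_habitats=4, samples_per_habitat=12, natives_per_habitat=80,
    regional_generalists=20, native_occupancy=0.4, colonist_occupancy=0.9,
    colonist_abundance_factor=0.3, cycle_exclusive_fraction=1.0,
    depth=3000, seed=3,
)
table, _, truth = simulate_metacommunity(cfg)
calls = pd.DataFrame(
    [{"taxon_id": t, "habitat": h, "nonnative": True}
     for t, h in sorted(truth.nonnative_pairs)]
)
_, tree = simulate_sequences(truth, cfg)
ftable = simulate_function_table(truth, cfg)

res = removal_functional_comparison(table, calls, ftable, tree,
                                    replicates=10, seed=2)
ps = res["per_sample"]
summary = ps.groupby("habitat")[
    ["observed_functional_richness", "targeted_functional_richness",
     "random_functional_richness"]
].mean().round(1)
print(summary)
print()
stats = res["stats"]
show = stats[(stats["comparison"] == "targeted_vs_random")
             & (stats["metric"] == "functional_richness")]
print(show[["habitat", "mean_diff", "p_adj"]].to_string(index=False))
print("\ntargeted removal costs each community tens of functions that random "
      "removal would have spared (colonist-exclusive cycle genes)")
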