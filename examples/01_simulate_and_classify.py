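"""Simulate a multi-habitat metacommunity and recover the planted colonists.

Builds a 4-habitat landscape with habitat-native taxa, shared generalists and
dispersal-derived colonists, computes per-(taxon, habitat) Levins niche
breadth, applies the dual abundance/breadth nonnative rule, and scores the
calls against the simulator's ground truth.
"""

from habniche import (
    SimulationConfig,
    classify_nonnative,
    evaluate_against_truth,
    habitat_profiles,
    simulate_metacommunity,
    summarize_nonnative,
)

cfg = SimulationConfig(seed=42)
table, metadata, truth = simulate_metacommunity(cfg)
print(f"simulated {len(table.taxon_ids)} taxa x {len(table.sample_ids)} samples "
      f"in {cfg.n_habitats} habitats; {len(truth.nonnative_pairs)} planted "
      "colonist (taxon, habitat) pairs")

profiles = habitat_profiles(table)
calls = classify_nonnative(profiles, quantile=0.5)
metrics = evaluate_against_truth(calls, truth)
print(f"flagged {int(calls['nonnative'].sum())} pairs as putative nonnative")
print(f"precision {metrics['precision']:.3f}, recall {metrics['recall']:.3f} "
      f"over {metrics['n_pairs']} evaluable pairs")

per_hab, per_sample = summarize_nonnative(table, calls)
print(per_hab.to_string(index=False))
mean_ab = per_sample["flagged_abundance"].mean()
mean_rich = per_sample["flagged_richness_fraction"].mean()
print(f"nonnative taxa hold {100 * mean_ab:.2f}% of reads but "
      f"{100 * mean_rich:.2f}% of per-sample richness — "
      "rare colonists contribute diversity disproportionately to biomass")
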