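"""Simulate a clone tree, compartment mixtures and amplicon read counts.

Builds a six-mutation clone tree, distributes clone fractions across four
sorted stem/progenitor compartments with mild drift, and draws 800x bulk
amplicon counts. The printed table shows, per mutation, the true underlying
mutant allele burden (MAB = carrying-cell fraction / 2 for heterozygous
mutations) next to the observed read-count estimate.
"""

from clonearch import (
    SimulationConfig,
    assign_clone_fractions,
    simulate_bulk_counts,
    simulate_clone_tree,
)

cfg = SimulationConfig(seed=1)
tree = simulate_clone_tree(cfg)
print("Simulated clone tree (edge labels = newly acquired mutations):")
print(tree.render_text())

profiles = assign_clone_fractions(tree, ["HSC", "MPP", "GMP", "MEP"], cfg)
print("\nHSC clone fractions:",
      {c: round(f, 3) for c, f in profiles[0].fractions.items()})

bulk = simulate_bulk_counts(profiles[0], tree, cfg)
print("\nHSC bulk counts at 800x (observed vs true MAB):")
for r in bulk.itertuples():
    print(f"  {r.mutation_id}: {r.alt_reads}/{r.total_reads} reads "
          f"-> MAB {r.alt_reads / r.total_reads:.3f} (true {r.true_mab:.3f})")
print("\nObserved MABs scatter binomially around the true values; at 800x "
      "the standard error of a 40% burden is about 1.7 percentage points.")
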