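"""Test whether DE gene lists overlap cell-type signatures beyond chance.

Runs the four canonical scenarios (down-regulated vs endothelial
signature, up-regulated vs epithelial signature, and the two
wrong-direction pairings) with both the exact hypergeometric tail and
the 10,000-iteration bootstrap sampling-distribution test.
"""

from cenckit import (PROFILES, GeneSet, SimulationConfig, apply_de_filters,
                     compute_gene_stats, de_gene_sets, run_enrichment_scenarios,
                     simulate_compendium)

compendium, truth, sig_epc, sig_enc = simulate_compendium(SimulationConfig(seed=1))
stats = compute_gene_stats(compendium, "disease", "control")
up, down = de_gene_sets(apply_de_filters(stats, PROFILES["ppcd"]))
universe = GeneSet("universe", compendium.gene_ids)

results = run_enrichment_scenarios(up, down, sig_epc, sig_enc, universe,
                                   r=10_000, seed=7)
print(f"{'scenario':<14} {'k_obs':>5} {'expected':>9} {'p_boot':>10} "
      f"{'p_hgt':>10}  call")
for r in results:
    print(f"{r.name:<14} {r.k_obs:>5} {r.expected_mean:>9.2f} "
          f"{r.p_boot_empirical:>10.2g} {r.p_hyper_enrich:>10.2g}  {r.call}")
# k_obs is the observed intersection; 'expected' is the chance level
# n_a*n_b/N. The two planted scenarios come out 'enriched' (p << 0.01 by
# both tests); the wrong-direction scenarios do not.
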