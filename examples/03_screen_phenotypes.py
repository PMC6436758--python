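"""Quantify CRISPRi growth-screen phenotypes and call drug-specific hits.

Simulates a pooled screen (T0 / vehicle / drug arms, 2 replicates) in
which 6 of 100 genes carry a true drug-specific phenotype |rho| = 0.4,
then computes per-sgRNA gamma/tau/rho enrichments, gene-level top-3
scores and Mann-Whitney p-values against the 300 non-targeting controls,
and applies the hit filter |rho score| > 0.1, adjusted p < 1e-6.
"""

import stallscreen as ss

sim_config = ss.ScreenSimConfig(
    n_genes=100, n_nontargeting=300, n_rho_genes=6, seed=3
)
counts, truth = ss.simulate_screen(sim_config)

phen = ss.compute_phenotypes(
    counts,
    doublings_vehicle=sim_config.doublings_vehicle,
    doublings_drug=sim_config.doublings_drug,
)
genes = ss.call_hits(ss.score_genes(phen))

hits = genes[genes.is_hit]
print(f"genes scored: {len(genes)}, hits: {len(hits)}")
print("(positive rho = knockdown protects under drug, i.e. the encoded")
print(" protein sensitizes cells; negative rho = knockdown sensitizes)")
print()
cols = ["gene", "score_gamma", "score_rho", "mw_p_adjusted", "direction"]
print(hits[cols].to_string(index=False))
print()
true_rho = truth[~truth.is_nontargeting].groupby("gene").rho_true.max()
print("true |rho| of the hit genes was 0.4; top-3 scores recover it up to")
print("sgRNA activity (<=1) and the count pseudocount's shrinkage.")
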