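"""Check the pipelines' behavior on data with no signal at all.

Two null experiments: a stall-free profiling run (no transcript should
reach a final stalled call) and pseudo-genes assembled from non-targeting
sgRNAs (none should pass the screen's hit filter). Also measures the
empirical type-I error of the negative-binomial readthrough test on
5000 null count rows.
"""

import numpy as np

import stallscreen as ss
from stallscreen.screen import pseudogene_scores

# stall-free profiling experiment
config = ss.RunConfig(
    seed=4,
    ribo_sim=ss.RiboSimConfig(
        n_transcripts=200, stalled_fraction=0.0,
        reads_per_transcript=1000, seed=4,
    ),
)
calls, _, report = ss.run_ribo_pipeline(config)
print(f"null profiling run: {report['dmax']['candidates']} Z>=2 candidates "
      f"(right tail of the null DMax distribution),")
print(f"but {int(calls.stalled.sum())} final stalled calls after the "
      f"downstream depletion test.")

# type-I error of the NB test at its nominal 0.05 level
rng = np.random.default_rng(4)
mu = rng.lognormal(np.log(300), 0.5, size=5000)
r = 1 / 0.1
counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(5000, 6))
res = ss.nb_test(counts, np.arange(3), np.arange(3, 6))
print(f"\nnb_test type-I error at 0.05 on 5000 null rows: "
      f"{(res.p_value < 0.05).mean():.4f}")

# pseudo-genes drawn from non-targeting controls
scounts, _ = ss.simulate_screen(
    ss.ScreenSimConfig(n_genes=50, n_nontargeting=400, n_rho_genes=0, seed=4)
)
phen = ss.compute_phenotypes(scounts, doublings_vehicle=10, doublings_drug=10)
pseudo = pseudogene_scores(phen, 200, rng=4)
print(f"\npseudo-gene hits at the screen filter: {int(pseudo.is_hit.sum())} "
      f"/ {len(pseudo)} (min adjusted p = {pseudo.mw_p_adjusted.min():.3g})")
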