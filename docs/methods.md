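# Methods

This note documents the models implemented in `stallscreen`, the
reasoning behind the tunable parameters and the numerical choices, and
what the synthetic-data validation does and does not establish.

## Coordinate and data conventions

All ribosome-profiling coordinates are transcript-space, 0-based.
CDS intervals are half-open `[cds_start, cds_end)` in nucleotides; codon
index 0 is the initiator codon. Reads whose P-site lands in a UTR are
dropped (not clamped): the analysis is CDS-only. Multimapping status is
an upstream attribute (an `n_mappings` column, or the SAM `NH` tag);
alignment itself is out of scope — the package consumes transcript-space
alignments of rRNA-depleted footprints. Every filter stage returns a
tally, and the pipeline reports are written so that each input read is
accounted for exactly once (conservation is asserted in the tests).

## Stall detection

### P-site assignment and codon maps

Fragment lengths are restricted to 26–34 nt (the library size
selection; both bounds configurable). The P-site offset from the 5' end
is piecewise constant in fragment length: 14 nt (≤26), 15 nt (27–29),
16 nt (≥30). Codon maps tally P-sites per codon per
(condition, replicate) sample; densities divide by the sample's total
CDS-aligned reads and scale by 100 (percent mode, sums to 100 per
sample) or 10⁶ (RPM mode).

### DMax and candidacy

Replicate counts are **summed** (not averaged) per condition before
normalization — after per-transcript normalization the two differ only
by depth weighting, and pooled counts match the count-based test
downstream. Each condition's profile is normalized to end at 1, making
DMax a distribution-shift statistic bounded in [−1, 1] and comparable
across transcripts, which the Z-transform across transcripts presumes.
The sign convention is treated − control: a stall shifts treated
density 5'-ward, so the treated cumulative leads and genuine stalls give
positive DMax; negative-going shifts are never candidates. Ties in the
maximum are broken toward the 5'-most codon (compound-induced stalls
concentrate near the N-terminus). Z-scores use the sample standard
deviation (n−1); candidacy is Z ≥ 2 (configurable). Transcripts with
zero replicate-summed reads in either condition are excluded from DMax
with a tallied reason.

### Analysis region and the readthrough test

The downstream region starts one codon strictly 3' of the DMax position
for candidates, or at codon 10 for transcripts without a clear DMax
(non-candidates and DMax-excluded transcripts); it always ends 10 codons
before the stop. The boundary semantics (strict 3' start, final-10
exclusion, half-open interval) are a recorded convention: prose
descriptions of "3' of" and "before the end" do not fix inclusivity.
Region counts are summed per sample; transcripts with ≤ 30 reads total
across all six samples are dropped — the total-count reading is the
weaker, more inclusive interpretation of the count filter, and the
threshold is configurable.

Size factors are DESeq-style median-of-ratios: for each sample, the
median over zero-free rows of the count divided by the row's geometric
mean (the median is taken in linear space). With no zero-free rows the
factors fall back to column totals scaled to geometric mean 1, with a
warning.

The per-transcript test models counts as negative binomial with
variance μ + αμ². The dispersion α is a per-row method-of-moments
estimate pooled over the two groups ((v − m)/m² per group, averaged
with df weights) and floored at 10⁻⁸; rows at the floor are flagged as
the Poisson limit. The Wald statistic is the difference of log group
means of size-factor-normalized counts over its delta-method standard
error, `(1/m_A + α)/n_A + (1/m_B + α)/n_B`. With three replicates per
group a standard-normal reference is markedly anti-conservative
(empirically ~12% rejections at the 5% level), so the statistic is
referenced to a t distribution with n_A + n_B − 2 degrees of freedom;
measured type-I error is then 0.046–0.054 across the count scales and
dispersions the pipeline encounters. When a group mean is zero, a
pseudocount of 0.5 keeps the log2 fold change finite (configurable).
Benjamini–Hochberg adjustment is the classic step-up with monotonicity
enforcement. The final stalled call is the conjunction: DMax candidate
AND adjusted p < 0.05 AND log2FC < 0 — stalling necessarily depletes
downstream reads, so positive fold changes are never called. This test
is a defined statistic of this package, not a re-implementation of any
external differential-expression tool; numerical equality with such
tools is not claimed.

### Pause sites

On replicate-averaged densities of one condition (treated by default),
a pause site is a codon with density ≥ 10× the median over positions
with more than 0 reads (zeros excluded from the median, deliberately:
they would otherwise drag it toward 0 on sparse transcripts). The
maximal-ratio site is labeled the main site. No automated choice among
multiple sites beyond that label is attempted.

## Screen phenotypes

Per-sgRNA enrichment between two samples is
`log2(((c_b + ψ)/T_b) / ((c_a + ψ)/T_a)) / doublings` with pseudocount
ψ = 10 by default (stabilizes low-count log-ratios in pooled screens;
configurable) and raw sample totals T. Gamma is T0 → vehicle over the
vehicle arm's doublings, tau is T0 → drug, and rho is vehicle-end →
drug-end over the drug arm's doublings, so rho = tau − gamma exactly
when the arms double equally. Each phenotype is centered per replicate
by the median over non-targeting sgRNAs — "no effect" maps to 0, which
the |rho| > 0.1 cutoff presumes — then averaged across replicates.
Doubling numbers are configuration inputs; the default of 1 reduces
phenotypes to raw log2 enrichments, which leaves sign and ranking (all
the hit filter uses, after rescaling the cutoff) unchanged.

Gene scores average the 3 sgRNAs of largest absolute replicate-averaged
phenotype, signs retained, ties broken by sgRNA id for determinism;
genes with fewer than 3 sgRNAs average what they have. The Mann–Whitney
U test compares all of a gene's sgRNA phenotypes against the full
non-targeting population, two-sided. When the pooled sample is tie-free
the **exact** null distribution of U is used (scipy's implementation,
cached per sample-size pair); with ties, the tie-corrected normal
approximation. The exact tail matters: for n = 10 sgRNAs against a
large control set the normal approximation's two-sided p is bounded
below by ~4×10⁻⁸ (the z statistic saturates at √(3n)), which would put
an adjusted cutoff of 10⁻⁶ out of reach even for complete separation;
the exact distribution has no such floor. Mann–Whitney p-values are
BH-adjusted across genes (the adjustment method is a package choice;
at a 10⁻⁶ cutoff it rarely flips calls). A hit requires
|rho score| > 0.1 and adjusted p < 10⁻⁶. Sign convention, stated
prominently because it inverts a naive reading: **positive rho = the
knockdown is enriched under drug relative to vehicle**, i.e. losing the
gene protects the cell and the encoded protein sensitizes it to the
compound; negative rho marks protective proteins.

Null pseudo-genes — random groups of 10 non-targeting sgRNAs scored
through the identical machinery, BH-adjusted within their own family —
provide an empirical null for the full gene-scoring path.

## Synthetic data

### Profiling generator

Each transcript draws a CDS length (default uniform over 150–600
codons) and a log-normal per-codon baseline occupancy (σ = 0.5,
a realistic codon-to-codon heterogeneity), normalized per transcript.
A configured fraction of transcripts (default 5%) receives a stall at a
codon drawn uniformly from [30, min(100, L−30)] (N-terminal-biased, as
compound-induced stalls are), or at a fixed configured position. In
treated samples the stall multiplies occupancy by `pileup_factor`
(default 15) over a window of `pileup_width_codons` (default 3)
adjacent codons ending at the stall — elongation slows over several
codons, and absent a known shape the window is uniform — and scales all
occupancy 3' of the stall by 1 − `dropoff_fraction` (default 0.75).
Treated occupancy is deliberately **not** renormalized to the
configured depth: this makes the expected downstream log2 fold change
exactly log2(1 − dropoff), the quantity the readthrough test estimates,
at the cost of a slightly different expected total depth on stalled
transcripts (negligible at a 5% stalled fraction). Per-codon counts are
negative-binomial across replicates (dispersion 0.1, a typical
biological-replicate overdispersion; matching the test's noise model);
counts expand into read records with lengths drawn from a 26–34 nt
distribution peaked at 29–31 nt and 5' positions back-calculated so the
length-dependent offset lands the P-site on the codon. Reads TSV, CDS
table, ground truth and a config copy (seed included) are written as
plain text; a random-sequence FASTA with correct ATG/stop placement is
available for interface completeness.

Known departures from real data: codon counts are drawn independently
per codon and replicate, so summed region counts have near-Poisson
effective dispersion rather than the transcript-level correlated
variability of real libraries (the dedicated type-I calibration
therefore draws rows from the NB model directly); there is no
codon-identity structure, ramp, or metagene trend; no rRNA
contamination, dedup structure or alignment artifacts (all out of
scope). Recovery results on this generator validate the machinery —
correctness of the statistics and filters — not performance on any real
library.

### Screen generator

sgRNA abundances start log-normal (σ = 0.25, library non-uniformity),
then grow as abundance × 2^(doublings × (1 + effect)) with effect =
activity × gamma in the vehicle arm and activity × (gamma + rho) in the
drug arm; non-targeting sgRNAs have zero effect by construction.
Defaults: 500 genes × 10 sgRNAs + 1000 non-targeting controls, 2
replicates, 10 doublings per arm (an ~11-day suspension-cell screen at
about one doubling per day), 500 reads/sgRNA, NB dispersion 0.01
(sequencing + PCR noise). Per-gene truth defaults to gamma ~ N(0, 0.05)
and a block of 20 genes with rho = ±0.4 (alternating sign), the rest 0.
The per-gene activity pattern is fixed at
(1, 1, 1, .95, .95, .9, .85, .85, .6, .3) — most guides of a compact
CRISPRi library knock their gene down efficiently, a few are weak —
so a gene's top-3 score recovers ~98% of its true effect. The
pseudocount biases strongly depleted guides toward zero (at 500
reads/sgRNA and |rho| = 0.4 over 10 doublings, roughly 0.03 on the rho
scale); phenotype recovery to ±0.05 therefore needs deeper sequencing,
while hit calling is unaffected at |rho| ≥ 0.4.

## Validation scales

The test suite and `scripts/acceptance.py` exercise the profiling arm
at 1000 transcripts × 2000 reads × 3+3 replicates (50 stalled; plus an
equal-sized fully null run and a 5000-row type-I calibration) and the
screen arm at 500 genes + 1000 controls × 2 replicates with 1000
pseudo-genes. These sizes keep a full from-scratch validation under a
minute or two on one CPU while leaving sampling error well below the
margins being checked. Genome-scale datasets (tens of thousands of
transcripts or genes) run through the same vectorized code paths.

## Known limitations

- The NB test uses per-row moment dispersions without shrinkage across
  transcripts; at three replicates its power is accordingly limited,
  and its p-values will not numerically match tools that shrink
  dispersions.
- "Lacking a clear DMax value" is operationalized as
  below-threshold Z (or exclusion from DMax); no other criterion is
  available from the verbal definition.
- Pause-site output flags the maximal-ratio site as "main" but performs
  no further curation; distinguishing the biologically relevant stall
  among multiple called sites is left to the analyst.
- The screen model treats replicates as independent NB draws around
  shared true abundances; it does not simulate infection bottlenecks,
  cell-cycle structure or guide-level off-target effects.
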