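"""Synthetic ribosome-profiling reads and pooled-screen counts with ground truth.

Both generators emit the statistical structure the downstream analyses
assume, with every generative parameter recorded, so each pipeline stage
can be validated by parameter recovery rather than against deposited
sequencing data.

Ribosome-profiling model: each transcript has a log-normal per-codon
baseline occupancy. In treated samples, stalled transcripts multiply
occupancy by ``pileup_factor`` over a window of ``pileup_width_codons``
adjacent codons ending at the stall position (elongation slows over
several codons, not one), and scale occupancy 3' of the stall by
``1 - dropoff_fraction`` (ribosomes that never translate past the
stall). Treated occupancy is deliberately not renormalized to the
configured depth, so the expected downstream depletion is exactly
``log2(1 - dropoff_fraction)``. Per-codon counts are negative-binomial
across replicates; counts are expanded into footprint reads whose
lengths follow the configured 26-34 nt distribution and whose 5' ends
are placed so the length-dependent P-site offset lands on the codon.

Screen model: sgRNA abundances start log-normal, then grow as
``2^(doublings * (1 + effect))`` with effect = activity x gamma in the
vehicle arm and activity x (gamma + rho) in the drug arm; non-targeting
sgRNAs have zero effect. Sequencing counts are negative-binomial around
depth-scaled frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .footprints import p_site_offset

__all__ = [
    "RiboSimConfig",
    "ScreenSimConfig",
    "RiboSim",
    "simulate_ribo_experiment",
    "simulate_screen",
]

READ_LENGTHS = np.arange(26, 35)
#: Footprint length distribution over 26-34 nt, peaked at 29-31 nt.
DEFAULT_LENGTH_PROBS = (0.02, 0.05, 0.10, 0.16, 0.20, 0.20, 0.14, 0.08, 0.05)
UTR5 = 18  # nt; leaves room for the largest P-site offset (16 nt)
UTR3 = 18

#: Per-gene sgRNA activity profile (fraction of the gene's effect each
#: guide transmits), mimicking a compact CRISPRi library in which most of
#: the ten guides per gene knock the gene down efficiently.
DEFAULT_ACTIVITY_PATTERN = (1.0, 1.0, 1.0, 0.95, 0.95, 0.9, 0.85, 0.85, 0.6, 0.3)


def _nb_draw(rng, mean, dispersion):
    """NB (gamma-Poisson) counts with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=np.float64)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + np.maximum(mean, 1e-300)))


@dataclass
class RiboSimConfig:
    """Generative parameters for a treated-vs-control profiling experiment."""

    n_transcripts: int = 1000
    cds_length_codons: tuple = (150, 600)  # int or (low, high) range
    baseline_sigma: float = 0.5  # log-normal sd of per-codon occupancy
    stalled_fraction: float = 0.05
    stall_position: int | None = None  # None: uniform in [30, min(100, L-30)]
    pileup_width_codons: int = 3
    pileup_factor: float = 15.0
    dropoff_fraction: float = 0.75
    reads_per_transcript: float = 2000.0
    read_length_probs: tuple = DEFAULT_LENGTH_PROBS
    n_replicates: int = 3
    dispersion: float = 0.1
    seed: int = 0

    def validate(self):
        if self.n_transcripts < 1:
            raise ValueError("n_transcripts must be positive")
        if not 0.0 <= self.stalled_fraction <= 1.0:
            raise ValueError("stalled_fraction must lie in [0, 1]")
        if not 0.0 <= self.dropoff_fraction < 1.0:
            raise ValueError("dropoff_fraction must lie in [0, 1)")
        if self.pileup_factor <= 0 or self.pileup_width_codons < 1:
            raise ValueError("pile-up window must be >= 1 codon with positive factor")
        probs = np.asarray(self.read_length_probs, dtype=np.float64)
        if probs.size != READ_LENGTHS.size or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"read_length_probs needs {READ_LENGTHS.size} entries summing to 1"
            )
        if self.reads_per_transcript <= 0 or self.n_replicates < 1:
            raise ValueError("depth and replicate count must be positive")
        lo = self.cds_length_codons if np.isscalar(self.cds_length_codons) \
            else min(self.cds_length_codons)
        if self.stall_position is not None:
            if not 10 < self.stall_position < lo - 10:
                raise ValueError(
                    "stall_position must lie strictly inside (10, cds_length-10) "
                    "so the start/end exclusion zones cannot swallow it"
                )
        if lo <= 21:
            raise ValueError("CDS must exceed 21 codons for a usable region")


@dataclass
class RiboSim:
    """Simulated experiment: reads, CDS table, and the generating truth."""

    reads: pd.DataFrame
    cds_table: pd.DataFrame
    truth: pd.DataFrame
    config: RiboSimConfig

    def write(self, out_dir, fasta: bool = True):
        """Write reads/CDS/truth TSVs, a config copy, and optionally FASTA."""
        import pathlib
        import yaml

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reads.to_csv(out / "reads.tsv", sep="\t", index=False)
        self.cds_table.to_csv(out / "cds_table.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "ribo_truth.tsv", sep="\t", index=False)
        with open(out / "ribo_sim_config.yaml", "w") as fh:
            yaml.safe_dump(asdict(self.config), fh, sort_keys=False)
        if fasta:
            write_transcriptome_fasta(
                out / "transcriptome.fasta", self.cds_table, seed=self.config.seed
            )


def simulate_ribo_experiment(config: RiboSimConfig) -> RiboSim:
    """Draw a full treated-vs-control footprint read set with known truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_transcripts

    if np.isscalar(config.cds_length_codons):
        n_codons = np.full(n, int(config.cds_length_codons))
    else:
        lo, hi = config.cds_length_codons
        n_codons = rng.integers(lo, hi + 1, size=n)
    tids = np.array([f"TX{i:05d}" for i in range(n)])
    cds_start = np.full(n, UTR5)
    cds_end = cds_start + 3 * n_codons
    offsets = np.concatenate(([0], np.cumsum(n_codons)))
    total = int(offsets[-1])

    # per-codon baseline occupancy, normalized per transcript
    base = rng.lognormal(0.0, config.baseline_sigma, size=total)
    for i in range(n):
        seg = slice(offsets[i], offsets[i + 1])
        base[seg] /= base[seg].sum()
    control_mu = base * config.reads_per_transcript

    # choose stalled transcripts and positions
    n_stalled = int(round(config.stalled_fraction * n))
    stalled_idx = np.sort(rng.choice(n, size=n_stalled, replace=False))
    is_stalled = np.zeros(n, dtype=bool)
    is_stalled[stalled_idx] = True
    stall_pos = np.full(n, -1)
    for i in stalled_idx:
        if config.stall_position is not None:
            stall_pos[i] = config.stall_position
        else:
            hi = min(100, n_codons[i] - 30)
            stall_pos[i] = rng.integers(30, hi + 1)

    treated_mu = control_mu.copy()
    w = config.pileup_width_codons
    for i in stalled_idx:
        seg = offsets[i]
        p = stall_pos[i]
        treated_mu[seg + max(0, p - w + 1): seg + p + 1] *= config.pileup_factor
        treated_mu[seg + p + 1: offsets[i + 1]] *= 1.0 - config.dropoff_fraction

    reads = _draw_reads(
        rng, config, tids, n_codons, offsets, cds_start,
        {"control": control_mu, "treated": treated_mu},
    )

    cds_table = pd.DataFrame(
        {"transcript_id": tids, "cds_start": cds_start, "cds_end": cds_end}
    )
    truth = pd.DataFrame(
        {
            "transcript_id": tids,
            "n_codons": n_codons,
            "is_stalled": is_stalled,
            "stall_position": stall_pos,
            "dropoff_fraction": np.where(is_stalled, config.dropoff_fraction, 0.0),
            "pileup_factor": np.where(is_stalled, config.pileup_factor, 1.0),
            "pileup_width_codons": np.where(is_stalled, w, 0),
        }
    )
    return RiboSim(reads=reads, cds_table=cds_table, truth=truth, config=config)


def _draw_reads(rng, config, tids, n_codons, offsets, cds_start, mu_by_condition):
    """Expand per-codon NB counts into footprint read records, per sample."""
    total = int(offsets[-1])
    codon_tid_row = np.searchsorted(offsets, np.arange(total), side="right") - 1
    codon_index = np.arange(total) - offsets[codon_tid_row]
    p_site_nt = cds_start[codon_tid_row] + 3 * codon_index
    probs = np.asarray(config.read_length_probs, dtype=np.float64)

    frames = []
    for condition in ("control", "treated"):  # fixed order for determinism
        mu = mu_by_condition[condition]
        for rep in range(1, config.n_replicates + 1):
            counts = _nb_draw(rng, mu, config.dispersion)
            nz = np.nonzero(counts)[0]
            reps = counts[nz]
            row = np.repeat(nz, reps)
            lengths = rng.choice(READ_LENGTHS, size=row.size, p=probs)
            five_prime = p_site_nt[row] - p_site_offset(lengths)
            frames.append(
                pd.DataFrame(
                    {
                        "transcript_id": pd.Categorical.from_codes(
                            codon_tid_row[row], categories=list(tids)
                        ),
                        "five_prime_pos": five_prime.astype(np.int32),
                        "length": lengths.astype(np.int16),
                        "condition": condition,
                        "replicate": np.int16(rep),
                        "n_mappings": np.int16(1),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def write_transcriptome_fasta(path, cds_table, seed: int = 0, line_width: int = 70):
    """Random-sequence transcriptome FASTA matching the CDS table's lengths.

    Sequences carry an ATG at the CDS start and a stop at the CDS end so
    the coordinates are biologically sensible; the rest is uniform ACGT.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xFA57A]))
    alphabet = np.array(list("ACGT"))
    records = []
    for row in cds_table.itertuples():
        length = int(row.cds_end) + UTR3
        seq = alphabet[rng.integers(0, 4, size=length)]
        seq[row.cds_start: row.cds_start + 3] = list("ATG")
        seq[row.cds_end - 3: row.cds_end] = list("TAA")
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=str(row.transcript_id),
                description=f"cds={row.cds_start}-{row.cds_end}",
            )
        )
    SeqIO.write(records, str(path), "fasta")


# -- pooled CRISPRi screen ---------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Generative parameters for a pooled growth screen (vehicle vs drug)."""

    n_genes: int = 500
    sgrnas_per_gene: int = 10
    n_nontargeting: int = 1000
    gamma_effects: tuple | None = None  # per-gene; None -> N(0, gamma_sd)
    rho_effects: tuple | None = None  # per-gene; None -> block design below
    n_rho_genes: int = 20  # genes carrying a drug effect in the default design
    rho_effect_size: float = 0.4  # alternating +/- across those genes
    gamma_sd: float = 0.05
    activity_pattern: tuple = DEFAULT_ACTIVITY_PATTERN
    doublings_vehicle: float = 10.0  # ~11-day screen at ~1 doubling/day
    doublings_drug: float = 10.0
    reads_per_sgrna: float = 500.0
    dispersion: float = 0.01
    n_replicates: int = 2
    t0_sigma: float = 0.25  # log-normal spread of library abundances
    seed: int = 0

    def validate(self):
        if self.n_genes < 1 or self.sgrnas_per_gene < 1 or self.n_nontargeting < 1:
            raise ValueError("gene, sgRNA and control counts must be positive")
        if self.reads_per_sgrna <= 0:
            raise ValueError("sequencing depth must be positive")
        if self.doublings_vehicle <= 0 or self.doublings_drug <= 0:
            raise ValueError("doubling counts must be positive")
        act = np.asarray(self.activity_pattern, dtype=np.float64)
        if act.size != self.sgrnas_per_gene or ((act < 0) | (act > 1)).any():
            raise ValueError(
                "activity_pattern needs one value in [0, 1] per sgRNA of a gene"
            )
        for name in ("gamma_effects", "rho_effects"):
            eff = getattr(self, name)
            if eff is not None and len(eff) != self.n_genes:
                raise ValueError(f"{name} must have one entry per gene")

    def resolve_effects(self, rng) -> tuple[np.ndarray, np.ndarray]:
        """Per-gene (gamma, rho) truth under the configured design."""
        if self.gamma_effects is not None:
            gamma = np.asarray(self.gamma_effects, dtype=np.float64)
        else:
            gamma = rng.normal(0.0, self.gamma_sd, size=self.n_genes)
        if self.rho_effects is not None:
            rho = np.asarray(self.rho_effects, dtype=np.float64)
        else:
            rho = np.zeros(self.n_genes)
            k = min(self.n_rho_genes, self.n_genes)
            signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
            rho[:k] = signs * self.rho_effect_size
        return gamma, rho


def simulate_screen(config: ScreenSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw sgRNA count tables and the generating truth for a screen.

    Returns ``(counts, truth)``. Counts columns: ``sgrna_id``, ``gene``,
    ``is_nontargeting`` and one column per arm x replicate named
    ``T0_r`` / ``vehicle_r`` / ``drug_r``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gamma_gene, rho_gene = config.resolve_effects(rng)

    genes = np.repeat(
        [f"GENE{i:04d}" for i in range(config.n_genes)], config.sgrnas_per_gene
    )
    n_targeting = config.n_genes * config.sgrnas_per_gene
    activity = np.tile(
        np.asarray(config.activity_pattern, dtype=np.float64), config.n_genes
    )
    gamma_sg = np.repeat(gamma_gene, config.sgrnas_per_gene) * activity
    rho_sg = np.repeat(rho_gene, config.sgrnas_per_gene) * activity

    genes = np.concatenate(
        [genes, np.repeat("non-targeting", config.n_nontargeting)]
    )
    activity = np.concatenate([activity, np.zeros(config.n_nontargeting)])
    gamma_sg = np.concatenate([gamma_sg, np.zeros(config.n_nontargeting)])
    rho_sg = np.concatenate([rho_sg, np.zeros(config.n_nontargeting)])
    n_total = n_targeting + config.n_nontargeting
    sgrna_ids = np.array(
        [f"sg{genes[i]}_{i % config.sgrnas_per_gene}" if i < n_targeting
         else f"sgNTC_{i - n_targeting:05d}" for i in range(n_total)]
    )
    is_nt = np.arange(n_total) >= n_targeting

    abundance_t0 = rng.lognormal(0.0, config.t0_sigma, size=n_total)
    growth = {
        "T0": abundance_t0,
        "vehicle": abundance_t0 * 2.0 ** (config.doublings_vehicle * (1.0 + gamma_sg)),
        "drug": abundance_t0 * 2.0 ** (config.doublings_drug * (1.0 + gamma_sg + rho_sg)),
    }
    depth = config.reads_per_sgrna * n_total

    counts = pd.DataFrame(
        {"sgrna_id": sgrna_ids, "gene": genes, "is_nontargeting": is_nt}
    )
    for arm in ("T0", "vehicle", "drug"):
        freq = growth[arm] / growth[arm].sum()
        for rep in range(1, config.n_replicates + 1):
            counts[f"{arm}_{rep}"] = _nb_draw(rng, freq * depth, config.dispersion)

    truth = pd.DataFrame(
        {
            "sgrna_id": sgrna_ids,
            "gene": genes,
            "is_nontargeting": is_nt,
            "activity": activity,
            "gamma_true": gamma_sg,
            "rho_true": rho_sg,
        }
    )
    return counts, truth
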