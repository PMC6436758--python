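"""End-to-end orchestration of the profiling and screen analysis arms.

A single :class:`RunConfig` carries every threshold (all of them
defaults, never hard-coded at call sites), the seed, and either input
file paths or a simulation block per arm. Each pipeline returns its
result tables plus a run report that accounts for every read or sgRNA
entering each filter stage.
"""

from __future__ import annotations

import dataclasses
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import footprints, readthrough, screen, simulate, stalls

__all__ = ["RunConfig", "run_ribo_pipeline", "run_screen_pipeline"]


@dataclass
class RunConfig:
    """All knobs for both analysis arms.

    Exactly one of a simulation block or input paths should be set per
    arm. Thresholds default to the analysis constants: Z >= 2 candidacy,
    10x pause ratio, 10-codon edge exclusions, >30 region counts,
    adjusted p < 0.05 depletion, |rho| > 0.1 and adjusted MW p < 1e-6
    screen hits.
    """

    out_dir: str | None = None
    seed: int = 0

    # ribo arm thresholds
    z_threshold: float = stalls.DEFAULT_Z_THRESHOLD
    pause_ratio: float = stalls.DEFAULT_PAUSE_RATIO
    edge_exclusion: int = stalls.DEFAULT_EDGE_EXCLUSION
    fallback_start: int = stalls.DEFAULT_FALLBACK_START
    min_region_counts: int = readthrough.DEFAULT_MIN_REGION_COUNTS
    alpha: float = readthrough.DEFAULT_ALPHA
    min_read_length: int = footprints.DEFAULT_MIN_LENGTH
    max_read_length: int = footprints.DEFAULT_MAX_LENGTH

    # screen arm thresholds
    rho_cutoff: float = screen.DEFAULT_RHO_CUTOFF
    p_cutoff: float = screen.DEFAULT_P_CUTOFF
    screen_pseudocount: float = screen.DEFAULT_PSEUDOCOUNT
    doublings_vehicle: float = 1.0
    doublings_drug: float = 1.0

    # inputs: simulation blocks ...
    ribo_sim: simulate.RiboSimConfig | None = None
    screen_sim: simulate.ScreenSimConfig | None = None
    # ... or file paths
    reads_path: str | None = None
    cds_path: str | None = None
    screen_counts_path: str | None = None

    def validate(self):
        for name in ("z_threshold", "pause_ratio", "alpha", "rho_cutoff",
                     "p_cutoff", "min_region_counts", "edge_exclusion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.ribo_sim is not None and self.reads_path is not None:
            raise ValueError("give either a ribo simulation block or read paths, not both")
        if self.screen_sim is not None and self.screen_counts_path is not None:
            raise ValueError("give either a screen simulation block or a counts path, not both")

    # -- config file round trip -------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if raw.get("ribo_sim") is not None:
            raw["ribo_sim"] = simulate.RiboSimConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["ribo_sim"].items()
            })
        if raw.get("screen_sim") is not None:
            raw["screen_sim"] = simulate.ScreenSimConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["screen_sim"].items()
            })
        return cls(**raw)

    def to_yaml(self, path):
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def _write(df: pd.DataFrame, out_dir, name):
    if out_dir is not None:
        df.to_csv(pathlib.Path(out_dir) / name, sep="\t", index=False,
                  float_format="%.6g")


def run_ribo_pipeline(config: RunConfig):
    """Simulate or load reads, then filter -> map -> DMax -> DE -> classify.

    Returns ``(calls, pause_sites, report)``; when ``config.out_dir`` is
    set, writes ``stall_calls.tsv``, ``pause_sites.tsv``, ``report.yaml``
    and a config copy.
    """
    config.validate()
    report = {"stage": "ribo", "thresholds": {
        "z_threshold": config.z_threshold, "pause_ratio": config.pause_ratio,
        "edge_exclusion": config.edge_exclusion,
        "min_region_counts": config.min_region_counts, "alpha": config.alpha,
    }}
    if config.out_dir is not None:
        pathlib.Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        config.to_yaml(pathlib.Path(config.out_dir) / "run_config.yaml")

    if config.ribo_sim is not None:
        sim_config = dataclasses.replace(config.ribo_sim, seed=config.seed)
        sim = simulate.simulate_ribo_experiment(sim_config)
        reads, cds = sim.reads, sim.cds_table
        report["simulated"] = True
    elif config.reads_path and config.cds_path:
        reads = pd.read_csv(config.reads_path, sep="\t")
        cds = pd.read_csv(config.cds_path, sep="\t")
        report["simulated"] = False
    else:
        raise ValueError("ribo arm needs a simulation block or reads/CDS paths")

    reads, filter_tally = footprints.filter_alignments(
        reads, config.min_read_length, config.max_read_length
    )
    report["alignment_filter"] = filter_tally

    maps, map_tally = footprints.CodonMaps.from_reads(reads, cds)
    report["codon_map"] = map_tally

    dmax = stalls.dmax_table(maps, z_threshold=config.z_threshold)
    report["dmax"] = {
        "transcripts": int(len(dmax)),
        "excluded_zero_reads": int((dmax["excluded_reason"] == "zero_reads").sum()),
        "candidates": int(dmax["is_candidate"].sum()),
    }

    regions = stalls.define_regions(
        dmax, fallback_start=config.fallback_start,
        edge_exclusion=config.edge_exclusion,
    )
    de, region_tally = readthrough.test_readthrough(
        maps, regions, min_region_counts=config.min_region_counts
    )
    report["region_filter"] = region_tally

    calls = readthrough.classify_stalled(regions, de, alpha=config.alpha)
    report["final"] = {
        "tested": int(len(de)),
        "significant": int(calls["significant"].sum()),
        "stalled": int(calls["stalled"].sum()),
    }

    candidate_ids = calls.loc[calls["is_candidate"], "transcript_id"].to_numpy()
    pause = stalls.pause_site_table(
        maps, condition="treated", ratio_threshold=config.pause_ratio,
        transcript_ids=candidate_ids,
    )
    report["pause_sites"] = {"transcripts_with_sites": int(pause["transcript_id"].nunique())
                             if len(pause) else 0}

    _write(calls, config.out_dir, "stall_calls.tsv")
    _write(pause, config.out_dir, "pause_sites.tsv")
    if config.out_dir is not None:
        with open(pathlib.Path(config.out_dir) / "ribo_report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
    return calls, pause, report


def run_screen_pipeline(config: RunConfig):
    """Simulate or load screen counts, then phenotypes -> gene scores -> hits.

    Returns ``(phenotypes, gene_table, report)``; writes
    ``sgrna_phenotypes.tsv``, ``gene_scores.tsv`` and ``screen_report.yaml``
    when an output directory is configured.
    """
    config.validate()
    report = {"stage": "screen", "thresholds": {
        "rho_cutoff": config.rho_cutoff, "p_cutoff": config.p_cutoff,
        "pseudocount": config.screen_pseudocount,
    }}
    if config.out_dir is not None:
        pathlib.Path(config.out_dir).mkdir(parents=True, exist_ok=True)

    if config.screen_sim is not None:
        sim_config = dataclasses.replace(config.screen_sim, seed=config.seed)
        counts, _truth = simulate.simulate_screen(sim_config)
        doublings_vehicle = sim_config.doublings_vehicle
        doublings_drug = sim_config.doublings_drug
        report["simulated"] = True
    elif config.screen_counts_path:
        counts = pd.read_csv(config.screen_counts_path, sep="\t")
        doublings_vehicle = config.doublings_vehicle
        doublings_drug = config.doublings_drug
        report["simulated"] = False
    else:
        raise ValueError("screen arm needs a simulation block or a counts path")

    report["input"] = {
        "sgrnas": int(len(counts)),
        "nontargeting": int(counts["is_nontargeting"].sum()),
        "genes": int(counts.loc[~counts["is_nontargeting"].astype(bool), "gene"].nunique()),
    }

    phen = screen.compute_phenotypes(
        counts, doublings_vehicle=doublings_vehicle,
        doublings_drug=doublings_drug, pseudocount=config.screen_pseudocount,
    )
    rep_cols = [c for c in phen.columns if c.startswith("rho_")]
    if len(rep_cols) >= 2:
        report["replicate_correlation_rho"] = float(
            np.corrcoef(phen[rep_cols[0]], phen[rep_cols[1]])[0, 1]
        )

    gene_table = screen.call_hits(
        screen.score_genes(phen),
        rho_cutoff=config.rho_cutoff, p_cutoff=config.p_cutoff,
    )
    report["final"] = {
        "genes_scored": int(len(gene_table)),
        "hits": int(gene_table["is_hit"].sum()),
        "protective": int((gene_table["direction"] == "protective").sum()),
        "sensitizing": int((gene_table["direction"] == "sensitizing").sum()),
    }

    _write(phen, config.out_dir, "sgrna_phenotypes.tsv")
    _write(gene_table, config.out_dir, "gene_scores.tsv")
    if config.out_dir is not None:
        with open(pathlib.Path(config.out_dir) / "screen_report.yaml", "w") as fh:
            yaml.safe_dump(report, fh, sort_keys=False)
    return phen, gene_table, report
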