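import numpy as np
import pandas as pd
import pytest

import stallscreen as ss
from stallscreen.footprints import CodonMaps
from stallscreen.simulate import (
    RiboSimConfig,
    ScreenSimConfig,
    simulate_ribo_experiment,
    simulate_screen,
    write_transcriptome_fasta,
)


def tiny_ribo(**kw):
    base = dict(n_transcripts=40, cds_length_codons=(100, 160),
                reads_per_transcript=400, seed=7)
    base.update(kw)
    return RiboSimConfig(**base)


class TestRiboSimulator:
    def test_seed_determinism(self):
        a = simulate_ribo_experiment(tiny_ribo())
        b = simulate_ribo_experiment(tiny_ribo())
        pd.testing.assert_frame_equal(a.reads, b.reads)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_different_seeds_differ(self):
        a = simulate_ribo_experiment(tiny_ribo())
        b = simulate_ribo_experiment(tiny_ribo(seed=8))
        assert not a.reads.equals(b.reads)

    def test_read_records_respect_transcript_bounds(self):
        sim = simulate_ribo_experiment(tiny_ribo())
        cds = sim.cds_table.set_index("transcript_id")
        merged = sim.reads.merge(sim.cds_table, on="transcript_id")
        assert (merged.five_prime_pos >= 0).all()
        # transcript extends UTR3 nt past the CDS end
        assert (merged.five_prime_pos + merged.length <= merged.cds_end + 18).all()
        assert merged.length.between(26, 34).all()

    def test_depth_matches_configuration(self):
        # control condition carries the configured depth; z-test on the total
        cfg = tiny_ribo(n_transcripts=100, reads_per_transcript=300,
                        stalled_fraction=0.0, n_replicates=1)
        sim = simulate_ribo_experiment(cfg)
        total = (sim.reads.condition == "control").sum()
        expected = 100 * 300
        # NB with per-codon dispersion 0.1: Var ~ sum(mu) + 0.1 * sum(mu_c^2)
        var = expected + 0.1 * expected * cfg.reads_per_transcript / 120
        z = (total - expected) / np.sqrt(var)
        assert abs(z) < 4

    def test_dropoff_forces_downstream_depletion_ratio(self):
        cfg = tiny_ribo(n_transcripts=80, stalled_fraction=1.0,
                        stall_position=40, dropoff_fraction=0.75,
                        reads_per_transcript=1000)
        sim = simulate_ribo_experiment(cfg)
        maps, _ = CodonMaps.from_reads(sim.reads, sim.cds_table)
        t_down = c_down = 0
        for row in sim.truth.itertuples():
            t = maps.condition_sum(row.transcript_id, "treated")
            c = maps.condition_sum(row.transcript_id, "control")
            t_down += t[row.stall_position + 1:].sum()
            c_down += c[row.stall_position + 1:].sum()
        assert np.log2(t_down / c_down) == pytest.approx(np.log2(0.25), abs=0.1)

    def test_null_config_gives_near_nominal_candidate_rate(self):
        cfg = tiny_ribo(n_transcripts=400, stalled_fraction=0.0,
                        reads_per_transcript=300)
        sim = simulate_ribo_experiment(cfg)
        maps, _ = CodonMaps.from_reads(sim.reads, sim.cds_table)
        table = ss.dmax_table(maps)
        # Z >= 2 tail of a right-skewed null: a few percent, never a flood
        assert 0.0 < table.is_candidate.mean() < 0.10

    def test_dmax_monotone_in_dropoff(self):
        means = []
        for d in (0.0, 0.3, 0.6, 0.9):
            cfg = tiny_ribo(n_transcripts=30, stalled_fraction=1.0,
                            stall_position=40, dropoff_fraction=d,
                            pileup_factor=1.0, pileup_width_codons=1)
            sim = simulate_ribo_experiment(cfg)
            maps, _ = CodonMaps.from_reads(sim.reads, sim.cds_table)
            table = ss.dmax_table(maps)
            means.append(table.dmax_value.mean())
        assert all(a < b for a, b in zip(means, means[1:]))

    @pytest.mark.parametrize(
        "kw",
        [
            dict(stall_position=5),
            dict(stall_position=95, cds_length_codons=100),
            dict(dropoff_fraction=1.0),
            dict(stalled_fraction=1.5),
            dict(read_length_probs=(0.5, 0.5)),
            dict(n_transcripts=0),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            simulate_ribo_experiment(tiny_ribo(**kw))

    def test_truth_is_sufficient_for_scoring(self):
        sim = simulate_ribo_experiment(tiny_ribo(stalled_fraction=0.2))
        truth = sim.truth
        stalled = truth[truth.is_stalled]
        assert {"transcript_id", "stall_position", "dropoff_fraction",
                "pileup_factor"} <= set(truth.columns)
        lengths = truth.set_index("transcript_id").n_codons
        assert ((stalled.stall_position > 10)
                & (stalled.stall_position
                   < lengths[stalled.transcript_id].to_numpy() - 10)).all()

    def test_fasta_matches_cds_table(self, tmp_path):
        from Bio import SeqIO

        sim = simulate_ribo_experiment(tiny_ribo(n_transcripts=5))
        path = tmp_path / "tx.fasta"
        write_transcriptome_fasta(path, sim.cds_table, seed=7)
        records = {r.id: r for r in SeqIO.parse(str(path), "fasta")}
        for row in sim.cds_table.itertuples():
            seq = str(records[row.transcript_id].seq)
            assert seq[row.cds_start: row.cds_start + 3] == "ATG"
            assert seq[row.cds_end - 3: row.cds_end] == "TAA"


class TestScreenSimulator:
    def test_seed_determinism(self):
        cfg = ScreenSimConfig(n_genes=20, n_nontargeting=50, seed=3)
        a, ta = simulate_screen(cfg)
        b, tb = simulate_screen(ScreenSimConfig(n_genes=20, n_nontargeting=50, seed=3))
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_null_screen_enrichments_centered_at_zero(self):
        cfg = ScreenSimConfig(n_genes=50, n_nontargeting=100, n_rho_genes=0,
                              gamma_effects=(0.0,) * 50, seed=4)
        counts, _ = simulate_screen(cfg)
        enr = np.log2((counts.vehicle_1 + 10) / (counts.T0_1 + 10))
        assert abs(np.median(enr - np.median(enr))) < 0.05

    def test_rho_recovery_at_high_depth(self):
        # activity-1 sgRNAs, gamma 0, rho -0.5: recovered within +/-0.05
        cfg = ScreenSimConfig(
            n_genes=10, n_nontargeting=200, sgrnas_per_gene=10,
            activity_pattern=(1.0,) * 10, gamma_effects=(0.0,) * 10,
            rho_effects=(-0.5,) * 5 + (0.0,) * 5, reads_per_sgrna=5000, seed=5,
        )
        counts, truth = simulate_screen(cfg)
        phen = ss.compute_phenotypes(
            counts, doublings_vehicle=cfg.doublings_vehicle,
            doublings_drug=cfg.doublings_drug,
        )
        est = phen.merge(truth[["sgrna_id", "rho_true"]], on="sgrna_id")
        affected = est[est.rho_true == -0.5]
        assert affected.rho.mean() == pytest.approx(-0.5, abs=0.05)

    def test_nontargeting_truth_is_null(self):
        counts, truth = simulate_screen(ScreenSimConfig(n_genes=10, seed=1))
        nt = truth[truth.is_nontargeting]
        assert (nt.gamma_true == 0).all() and (nt.rho_true == 0).all()
        arm_cols = counts.filter(regex=r"^(T0|vehicle|drug)_").to_numpy()
        assert (arm_cols >= 0).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            simulate_screen(ScreenSimConfig(reads_per_sgrna=0))
        with pytest.raises(ValueError):
            simulate_screen(ScreenSimConfig(activity_pattern=(1.0,) * 3))
        with pytest.raises(ValueError):
            simulate_screen(ScreenSimConfig(n_genes=5, rho_effects=(0.1,) * 4))
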