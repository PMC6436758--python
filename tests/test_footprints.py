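import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from conftest import make_maps
from stallscreen.footprints import (
    CodonMaps,
    assign_p_site,
    build_codon_map,
    filter_alignments,
    p_site_offset,
    read_sam_alignments,
)


def oracle_offset(length):
    # independent restatement of the three-branch rule
    if length <= 26:
        return 14
    if length <= 29:
        return 15
    return 16


@pytest.mark.parametrize("length", range(20, 41))
def test_p_site_offset_three_branch_rule(length):
    assert p_site_offset(length) == oracle_offset(length)


@pytest.mark.parametrize(
    "length,pos,expected",
    [(26, 100, 114), (28, 0, 15), (34, 10, 26)],
)
def test_assign_p_site_examples(length, pos, expected):
    assert assign_p_site(length, pos) == expected


def test_assign_p_site_vectorized():
    lengths = np.array([26, 28, 34])
    pos = np.array([100, 0, 10])
    np.testing.assert_array_equal(assign_p_site(lengths, pos), [114, 15, 26])


class TestBuildCodonMap:
    def test_empty_reads_give_zero_map(self):
        counts, dropped = build_codon_map(
            pd.DataFrame(columns=["five_prime_pos", "length"]), 18, 48
        )
        assert counts.tolist() == [0] * 10 and dropped == 0

    def test_start_codon_read(self):
        # a 26-nt read whose 5' end is offset-distance upstream of the CDS
        reads = pd.DataFrame({"five_prime_pos": [18 - 14], "length": [26]})
        counts, dropped = build_codon_map(reads, 18, 48)
        assert counts[0] == 1 and counts.sum() == 1 and dropped == 0

    def test_utr_p_site_dropped_not_clamped(self):
        reads = pd.DataFrame({"five_prime_pos": [0], "length": [26]})  # P-site 14 < 18
        counts, dropped = build_codon_map(reads, 18, 48)
        assert counts.sum() == 0 and dropped == 1

    def test_matches_naive_tally(self, rng):
        cds_start, cds_end = 18, 18 + 150
        reads = pd.DataFrame(
            {
                "five_prime_pos": rng.integers(0, 160, size=50),
                "length": rng.integers(26, 35, size=50),
            }
        )
        counts, dropped = build_codon_map(reads, cds_start, cds_end)
        # brute-force tally, read by read
        expected = np.zeros(50, dtype=int)
        n_drop = 0
        for _, r in reads.iterrows():
            p = r.five_prime_pos + oracle_offset(r.length)
            if cds_start <= p < cds_end:
                expected[(p - cds_start) // 3] += 1
            else:
                n_drop += 1
        np.testing.assert_array_equal(counts, expected)
        assert dropped == n_drop
        assert counts.sum() + dropped == len(reads)  # conservation

    def test_cds_not_multiple_of_three_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            build_codon_map(pd.DataFrame({"five_prime_pos": [], "length": []}), 0, 10)


class TestFilterAlignments:
    def _reads(self, n_mappings):
        n = len(n_mappings)
        return pd.DataFrame(
            {
                "transcript_id": ["t"] * n,
                "five_prime_pos": range(n),
                "length": [28] * n,
                "n_mappings": n_mappings,
            }
        )

    def test_multimapped_excluded(self):
        kept, tally = self._reads([1, 2]), None
        kept, tally = filter_alignments(self._reads([1, 2]))
        assert len(kept) == 1 and tally["multimapped"] == 1

    def test_all_unique_identity(self):
        reads = self._reads([1, 1, 1])
        kept, tally = filter_alignments(reads)
        pd.testing.assert_frame_equal(kept, reads)

    def test_mixed_counts(self):
        kept, tally = filter_alignments(self._reads([1] * 7 + [3, 2, 5]))
        assert len(kept) == 7 and tally["retained"] == 7

    def test_length_bounds_and_conservation(self):
        reads = self._reads([1] * 4)
        reads["length"] = [25, 26, 34, 35]
        kept, tally = filter_alignments(reads)
        assert len(kept) == 2 and tally["length_out_of_bounds"] == 2
        assert tally["retained"] + tally["multimapped"] + tally["length_out_of_bounds"] == tally["input"]

    def test_missing_multiplicity_warns_once(self):
        reads = self._reads([1, 1]).drop(columns="n_mappings")
        with pytest.warns(UserWarning, match="n_mappings"):
            kept, _ = filter_alignments(reads)
        assert len(kept) == 2


class TestCodonMapsBulk:
    def test_matches_per_transcript_builder(self, small_ribo_sim):
        maps, tally = CodonMaps.from_reads(small_ribo_sim.reads, small_ribo_sim.cds_table)
        assert tally["assigned"] + tally["p_site_outside_cds"] + tally["unknown_transcript"] == tally["input"]
        cds = small_ribo_sim.cds_table.set_index("transcript_id")
        reads = small_ribo_sim.reads
        for tid in maps.transcript_ids[:3]:
            sel = reads[
                (reads.transcript_id == tid)
                & (reads.condition == "treated")
                & (reads.replicate == 1)
            ]
            expected, _ = build_codon_map(
                sel, cds.loc[tid, "cds_start"], cds.loc[tid, "cds_end"]
            )
            np.testing.assert_array_equal(maps.get(tid, "treated", 1), expected)

    def test_frame_roundtrip(self, small_ribo_sim):
        maps, _ = CodonMaps.from_reads(small_ribo_sim.reads, small_ribo_sim.cds_table)
        rebuilt = CodonMaps.from_frame(maps.to_frame(), small_ribo_sim.cds_table)
        np.testing.assert_array_equal(rebuilt.counts, maps.counts)
        assert rebuilt.samples == maps.samples

    def test_bad_frame_transcript_skipped(self):
        cds = pd.DataFrame(
            {"transcript_id": ["a", "b"], "cds_start": [18, 18], "cds_end": [48, 50]}
        )
        reads = pd.DataFrame(
            {
                "transcript_id": ["a", "b"],
                "five_prime_pos": [4, 4],
                "length": [26, 26],
                "condition": ["treated"] * 2,
                "replicate": [1, 1],
            }
        )
        with pytest.warns(UserWarning, match="multiple of 3"):
            maps, tally = CodonMaps.from_reads(reads, cds)
        assert list(maps.transcript_ids) == ["a"]
        assert tally["unknown_transcript"] == 1  # b's read no longer maps


class TestDensities:
    def test_forced_percent_example(self):
        maps = make_maps({("s", 1): [np.array([1, 1, 2])]})
        np.testing.assert_allclose(maps.densities("percent")[0], [25, 25, 50])

    def test_percent_sums_to_100(self, small_ribo_sim):
        maps, _ = CodonMaps.from_reads(small_ribo_sim.reads, small_ribo_sim.cds_table)
        np.testing.assert_allclose(
            maps.densities("percent").sum(axis=1), 100.0, rtol=1e-9
        )
        np.testing.assert_allclose(maps.densities("rpm").sum(axis=1), 1e6, rtol=1e-9)

    def test_scale_invariance(self):
        a = make_maps({("s", 1): [np.array([3, 5, 2])]})
        b = make_maps({("s", 1): [np.array([30, 50, 20])]})
        np.testing.assert_allclose(a.densities(), b.densities())

    def test_zero_sample_raises(self):
        maps = make_maps({("s", 1): [np.zeros(3, dtype=int)]})
        with pytest.raises(ValueError, match="zero CDS-aligned"):
            maps.densities()


def test_read_sam_roundtrip(tmp_path):
    import pysam

    header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 500, "SN": "TX00001"}]}
    path = tmp_path / "reads.sam"
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        a = pysam.AlignedSegment(fh.header)
        a.query_name = "r1"
        a.query_sequence = "A" * 28
        a.reference_id = 0
        a.reference_start = 100
        a.cigarstring = "28M"
        a.set_tag("NH", 1)
        fh.write(a)
    reads = read_sam_alignments(path)
    assert reads.iloc[0].tolist() == ["TX00001", 100, 28, 1]
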