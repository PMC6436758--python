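"""Footprint processing: P-site assignment, codon maps, density normalization.

Ribosome-protected fragments are 26-34 nt mRNA pieces whose 5' end sits a
fixed, length-dependent distance upstream of the ribosomal P-site codon.
This module turns transcript-space alignments of such fragments into
per-codon count maps for each (condition, replicate) sample, and normalizes
those maps to read-percentage or reads-per-million densities.

Coordinates are transcript-space, 0-based; CDS intervals are half-open
``[cds_start, cds_end)`` in nucleotides; codon 0 is the initiator codon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "p_site_offset",
    "assign_p_site",
    "filter_alignments",
    "build_codon_map",
    "CodonMaps",
    "read_sam_alignments",
]

#: Default fragment-length bounds from the library size selection.
DEFAULT_MIN_LENGTH = 26
DEFAULT_MAX_LENGTH = 34

READ_COLUMNS = ["transcript_id", "five_prime_pos", "length"]


def p_site_offset(length):
    """Distance (nt) from a fragment's 5' end to its P-site, by length.

    The rule is piecewise constant in three branches: 14 nt for fragments
    of 26 nt or shorter, 15 nt for 27-29 nt, and 16 nt for 30 nt or longer.
    Accepts a scalar or array and returns the same shape.
    """
    length = np.asarray(length)
    offset = np.where(length <= 26, 14, np.where(length <= 29, 15, 16))
    return offset if offset.ndim else int(offset)


def assign_p_site(length, five_prime_pos):
    """P-site nucleotide position of a fragment: 5' position + offset(length)."""
    return np.asarray(five_prime_pos) + p_site_offset(length)


def filter_alignments(
    reads: pd.DataFrame,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> tuple[pd.DataFrame, dict]:
    """Keep uniquely-mapped reads of acceptable length; tally rejections.

    ``reads`` needs columns ``transcript_id``, ``five_prime_pos``,
    ``length`` and optionally ``n_mappings`` (number of alignment
    positions, as reported upstream). Reads with ``n_mappings != 1`` are
    multimapped and excluded; a missing column is treated as all-unique
    with a single warning.

    Returns the retained reads and a tally dict accounting for every
    input read (``input``, ``multimapped``, ``length_out_of_bounds``,
    ``retained``).
    """
    tally = {"input": int(len(reads))}
    if "n_mappings" in reads.columns:
        unique = reads["n_mappings"].to_numpy() == 1
    else:
        warnings.warn(
            "reads carry no 'n_mappings' column; treating all as uniquely mapped",
            stacklevel=2,
        )
        unique = np.ones(len(reads), dtype=bool)
    length = reads["length"].to_numpy()
    good_len = (length >= min_length) & (length <= max_length)
    tally["multimapped"] = int((~unique).sum())
    tally["length_out_of_bounds"] = int((unique & ~good_len).sum())
    kept = reads.loc[unique & good_len]
    tally["retained"] = int(len(kept))
    return kept, tally


def build_codon_map(
    reads: pd.DataFrame, cds_start: int, cds_end: int
) -> tuple[np.ndarray, int]:
    """Per-codon P-site counts for one transcript's reads.

    Each read's P-site nucleotide maps to codon ``(p_site - cds_start) // 3``;
    P-sites outside ``[cds_start, cds_end)`` (UTRs) are dropped, not clamped.
    Returns ``(counts, n_dropped)`` where ``counts`` has one entry per codon.

    Raises ``ValueError`` if the CDS length is not a multiple of 3.
    """
    if (cds_end - cds_start) % 3 != 0:
        raise ValueError(
            f"CDS length {cds_end - cds_start} is not a multiple of 3"
        )
    n_codons = (cds_end - cds_start) // 3
    if len(reads) == 0:
        return np.zeros(n_codons, dtype=np.int64), 0
    p_site = assign_p_site(
        reads["length"].to_numpy(), reads["five_prime_pos"].to_numpy()
    )
    in_cds = (p_site >= cds_start) & (p_site < cds_end)
    codon = (p_site[in_cds] - cds_start) // 3
    counts = np.bincount(codon, minlength=n_codons).astype(np.int64)
    return counts, int((~in_cds).sum())


@dataclass
class CodonMaps:
    """Codon-resolution count maps for a set of transcripts and samples.

    Counts are stored as one dense matrix of shape
    ``(n_samples, total_codons)`` with transcripts laid out contiguously;
    ``offsets`` gives each transcript's start column. Samples are
    ``(condition, replicate)`` pairs.
    """

    transcript_ids: np.ndarray
    n_codons: np.ndarray
    samples: list
    counts: np.ndarray
    offsets: np.ndarray = field(init=False)
    _tid_index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.offsets = np.concatenate(([0], np.cumsum(self.n_codons)))
        self._tid_index = {t: i for i, t in enumerate(self.transcript_ids)}

    # -- construction ------------------------------------------------------

    @classmethod
    def from_reads(
        cls, reads: pd.DataFrame, cds_table: pd.DataFrame
    ) -> tuple["CodonMaps", dict]:
        """Build maps for every transcript in ``cds_table`` from P-site-assigned reads.

        ``reads`` needs columns ``transcript_id``, ``five_prime_pos``,
        ``length``, ``condition``, ``replicate``; ``cds_table`` needs
        ``transcript_id``, ``cds_start``, ``cds_end``. Transcripts whose CDS
        length is not a multiple of 3 are skipped with a warning. Returns
        the maps plus a tally accounting for every input read.
        """
        cds = cds_table.reset_index(drop=True)
        frame = (cds["cds_end"] - cds["cds_start"]) % 3 != 0
        if frame.any():
            bad = cds.loc[frame, "transcript_id"].tolist()
            warnings.warn(
                f"skipping {len(bad)} transcript(s) with CDS length not a "
                f"multiple of 3: {bad[:5]}",
                stacklevel=2,
            )
            cds = cds.loc[~frame].reset_index(drop=True)

        tids = cds["transcript_id"].to_numpy()
        n_codons = ((cds["cds_end"] - cds["cds_start"]) // 3).to_numpy()
        offsets = np.concatenate(([0], np.cumsum(n_codons)))
        total = int(offsets[-1])
        cds_start = cds["cds_start"].to_numpy()
        cds_end = cds["cds_end"].to_numpy()

        sample_key = pd.MultiIndex.from_arrays(
            [reads["condition"], reads["replicate"]]
        )
        sample_codes, sample_uniques = pd.factorize(sample_key, sort=True)
        samples = [(c, int(r)) for c, r in sample_uniques]

        tid_to_row = pd.Series(np.arange(len(tids)), index=tids)
        row = tid_to_row.reindex(reads["transcript_id"]).to_numpy()
        known = ~np.isnan(row)
        row = np.where(known, row, 0).astype(np.int64)

        p_site = assign_p_site(
            reads["length"].to_numpy(), reads["five_prime_pos"].to_numpy()
        )
        in_cds = np.zeros(len(reads), dtype=bool)
        k = known
        in_cds[k] = (p_site[k] >= cds_start[row[k]]) & (p_site[k] < cds_end[row[k]])

        keep = known & in_cds
        codon = (p_site[keep] - cds_start[row[keep]]) // 3
        flat = sample_codes[keep] * total + offsets[row[keep]] + codon
        counts = np.bincount(flat, minlength=len(samples) * total).reshape(
            len(samples), total
        )

        tally = {
            "input": int(len(reads)),
            "unknown_transcript": int((~known).sum()),
            "p_site_outside_cds": int((known & ~in_cds).sum()),
            "assigned": int(keep.sum()),
        }
        return cls(tids, n_codons, samples, counts), tally

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cds_table: pd.DataFrame) -> "CodonMaps":
        """Rebuild maps from the long-format TSV written by :meth:`to_frame`."""
        cds = cds_table.reset_index(drop=True)
        tids = cds["transcript_id"].to_numpy()
        n_codons = ((cds["cds_end"] - cds["cds_start"]) // 3).to_numpy()
        offsets = np.concatenate(([0], np.cumsum(n_codons)))
        total = int(offsets[-1])
        sample_key = pd.MultiIndex.from_arrays(
            [frame["condition"], frame["replicate"]]
        )
        sample_codes, sample_uniques = pd.factorize(sample_key, sort=True)
        samples = [(c, int(r)) for c, r in sample_uniques]
        tid_to_row = pd.Series(np.arange(len(tids)), index=tids)
        row = tid_to_row.reindex(frame["transcript_id"]).to_numpy().astype(np.int64)
        flat = sample_codes * total + offsets[row] + frame["codon"].to_numpy()
        counts = np.zeros(len(samples) * total, dtype=np.int64)
        np.add.at(counts, flat, frame["count"].to_numpy())
        return cls(tids, n_codons, samples, counts.reshape(len(samples), total))

    # -- access ------------------------------------------------------------

    @property
    def conditions(self):
        return sorted({c for c, _ in self.samples})

    def sample_index(self, condition, replicate) -> int:
        return self.samples.index((condition, replicate))

    def _span(self, transcript_id):
        i = self._tid_index[transcript_id]
        return slice(self.offsets[i], self.offsets[i + 1])

    def get(self, transcript_id, condition, replicate) -> np.ndarray:
        """Codon counts for one transcript in one sample."""
        return self.counts[self.sample_index(condition, replicate), self._span(transcript_id)]

    def condition_rows(self, condition) -> np.ndarray:
        rows = [i for i, (c, _) in enumerate(self.samples) if c == condition]
        if not rows:
            raise KeyError(f"no samples for condition {condition!r}")
        return np.array(rows)

    def condition_sum(self, transcript_id, condition) -> np.ndarray:
        """Replicate-summed codon counts for one transcript in one condition."""
        rows = self.condition_rows(condition)
        return self.counts[rows][:, self._span(transcript_id)].sum(axis=0)

    # -- normalization -----------------------------------------------------

    def densities(self, mode: str = "percent") -> np.ndarray:
        """Per-sample normalized densities, same shape as ``counts``.

        ``percent`` divides by each sample's total CDS-aligned reads and
        multiplies by 100 (densities sum to 100 per sample); ``rpm`` uses
        1e6. Raises ``ValueError`` on a sample with zero CDS reads.
        """
        scale = {"percent": 100.0, "rpm": 1e6}[mode]
        totals = self.counts.sum(axis=1, dtype=np.float64)
        if (totals == 0).any():
            empty = [self.samples[i] for i in np.where(totals == 0)[0]]
            raise ValueError(f"sample(s) with zero CDS-aligned reads: {empty}")
        return self.counts / totals[:, None] * scale

    def mean_density(self, condition, mode: str = "percent") -> np.ndarray:
        """Replicate-averaged density vector (all transcripts concatenated)."""
        dens = self.densities(mode=mode)
        return dens[self.condition_rows(condition)].mean(axis=0)

    def density_for(self, transcript_id, condition, mode: str = "percent") -> np.ndarray:
        """Replicate-averaged density over one transcript's codons."""
        return self.mean_density(condition, mode=mode)[self._span(transcript_id)]

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long format: transcript_id, codon, count, condition, replicate.

        Zero counts are omitted to keep files small.
        """
        parts = []
        for s, (condition, replicate) in enumerate(self.samples):
            nz = np.nonzero(self.counts[s])[0]
            row = np.searchsorted(self.offsets, nz, side="right") - 1
            parts.append(
                pd.DataFrame(
                    {
                        "transcript_id": self.transcript_ids[row],
                        "codon": nz - self.offsets[row],
                        "count": self.counts[s, nz],
                        "condition": condition,
                        "replicate": replicate,
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)


def read_sam_alignments(path) -> pd.DataFrame:
    """Read transcript-space alignments from SAM/BAM into the reads layout.

    The reference name is taken as the transcript id, ``reference_start``
    as the 5' position and the query length as the fragment length. The
    ``NH`` tag, when present, fills ``n_mappings``.
    """
    import pysam

    rows = {"transcript_id": [], "five_prime_pos": [], "length": [], "n_mappings": []}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            rows["transcript_id"].append(aln.reference_name)
            rows["five_prime_pos"].append(aln.reference_start)
            rows["length"].append(aln.query_length or len(aln.query_sequence or ""))
            rows["n_mappings"].append(
                aln.get_tag("NH") if aln.has_tag("NH") else 1
            )
    return pd.DataFrame(rows)
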