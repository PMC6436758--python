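"""Stall-candidate detection via the DMax cumulative-read statistic.

A compound that stalls elongating ribosomes shifts footprint density
toward the 5' end of the CDS: reads pile up over the slow codons and are
depleted 3' of them. Comparing the treated and control cumulative read
distributions per transcript, the maximum difference (DMax, a
Kolmogorov-Smirnov-like statistic bounded in [-1, 1]) measures the shift
and its position marks the putative stall. DMax values are Z-scored
across transcripts and transcripts at Z >= 2 become stall candidates.
Pause sites are codons whose average density is at least 10x the median
of the transcript's non-zero positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "cumulative_profile",
    "cumulative_profiles",
    "compute_dmax",
    "z_transform",
    "define_region",
    "call_pause_sites",
    "dmax_table",
    "define_regions",
    "pause_site_table",
]

DEFAULT_Z_THRESHOLD = 2.0
DEFAULT_PAUSE_RATIO = 10.0
DEFAULT_EDGE_EXCLUSION = 10
DEFAULT_FALLBACK_START = 10


def cumulative_profile(counts) -> np.ndarray:
    """Cumulative fraction of a transcript's reads, codon by codon.

    Counts are divided by their total so the profile ends at 1, making
    profiles comparable across transcripts and conditions regardless of
    depth. Raises ``ValueError`` on an all-zero input.
    """
    counts = np.asarray(counts, dtype=np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot build a cumulative profile from zero reads")
    return np.cumsum(counts) / total


def cumulative_profiles(treated_counts, control_counts):
    """Per-condition cumulative profiles from replicate-summed codon counts."""
    return cumulative_profile(treated_counts), cumulative_profile(control_counts)


def compute_dmax(cum_treated, cum_control) -> tuple[float, int]:
    """Maximum treated-minus-control cumulative difference and its codon.

    The sign convention is treated minus control: a stall pushes treated
    reads 5', so its cumulative profile leads and the difference is
    positive. Ties are broken toward the 5'-most codon (argmax of the
    first maximum).
    """
    diff = np.asarray(cum_treated) - np.asarray(cum_control)
    pos = int(np.argmax(diff))
    return float(diff[pos]), pos


def z_transform(values) -> np.ndarray:
    """Standardize values to mean 0, sample standard deviation 1 (ddof=1).

    Raises ``ValueError`` when fewer than two values are given or when
    they are all identical (zero spread: no Z-scores are defined).
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two DMax values to standardize")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("all DMax values identical; Z-scores undefined")
    return (values - values.mean()) / sd


def define_region(
    dmax_position,
    cds_codons: int,
    fallback_start: int = DEFAULT_FALLBACK_START,
    edge_exclusion: int = DEFAULT_EDGE_EXCLUSION,
):
    """Downstream analysis region ``[start, end)`` for the read-count test.

    When a candidate DMax position exists the region starts at the first
    codon strictly 3' of it; otherwise it falls back to ``fallback_start``
    codons after the start codon. The final ``edge_exclusion`` codons are
    always excluded. Returns ``(start, end, fallback_used)`` or ``None``
    when the region would be empty.
    """
    if dmax_position is None:
        start, fallback = fallback_start, True
    else:
        start, fallback = int(dmax_position) + 1, False
    end = int(cds_codons) - edge_exclusion
    if start >= end or start < 0:
        return None
    return start, end, fallback


def call_pause_sites(
    density, ratio_threshold: float = DEFAULT_PAUSE_RATIO
) -> pd.DataFrame:
    """Codons whose density is >= ``ratio_threshold`` x the non-zero median.

    The median is computed over positions with more than 0 reads only.
    Returns a frame with columns ``codon``, ``ratio``, ``is_main`` sorted
    by position; the maximal-ratio site is flagged as the main site.
    Empty for an all-zero transcript.
    """
    density = np.asarray(density, dtype=np.float64)
    nonzero = density[density > 0]
    if nonzero.size == 0:
        return pd.DataFrame(columns=["codon", "ratio", "is_main"])
    med = np.median(nonzero)
    ratio = density / med
    hit = np.where(ratio >= ratio_threshold)[0]
    out = pd.DataFrame({"codon": hit, "ratio": ratio[hit]})
    out["is_main"] = False
    if len(out):
        out.loc[out["ratio"].idxmax(), "is_main"] = True
    return out


# -- bulk drivers over a CodonMaps container --------------------------------


def dmax_table(
    maps,
    treated: str = "treated",
    control: str = "control",
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> pd.DataFrame:
    """DMax value/position, Z-score and candidate flag for every transcript.

    Transcripts with zero replicate-summed reads in either condition are
    excluded from the DMax computation (``excluded_reason`` records why)
    and never become candidates. Z-scores are computed across the
    analyzable transcripts only.
    """
    rows = []
    for tid in maps.transcript_ids:
        t = maps.condition_sum(tid, treated)
        c = maps.condition_sum(tid, control)
        if t.sum() == 0 or c.sum() == 0:
            rows.append((tid, len(t), np.nan, -1, "zero_reads"))
            continue
        value, pos = compute_dmax(*cumulative_profiles(t, c))
        rows.append((tid, len(t), value, pos, ""))
    out = pd.DataFrame(
        rows,
        columns=["transcript_id", "n_codons", "dmax_value", "dmax_position", "excluded_reason"],
    )
    ok = out["excluded_reason"] == ""
    out["z_score"] = np.nan
    if ok.sum() >= 2:
        try:
            out.loc[ok, "z_score"] = z_transform(out.loc[ok, "dmax_value"].to_numpy())
        except ValueError:  # zero spread: leave Z undefined, no candidates
            pass
    out["is_candidate"] = out["z_score"] >= z_threshold
    return out


def define_regions(
    dmax_frame: pd.DataFrame,
    fallback_start: int = DEFAULT_FALLBACK_START,
    edge_exclusion: int = DEFAULT_EDGE_EXCLUSION,
) -> pd.DataFrame:
    """Attach the downstream analysis region to each DMax row.

    Candidates anchor the region at their DMax position; non-candidates
    (including transcripts excluded from DMax) use the fallback start.
    Transcripts whose region would be empty get ``region_start = -1`` and
    ``region_excluded = True``.
    """
    starts, ends, fallbacks, excluded = [], [], [], []
    for row in dmax_frame.itertuples():
        pos = int(row.dmax_position) if bool(row.is_candidate) else None
        region = define_region(
            pos, int(row.n_codons), fallback_start=fallback_start,
            edge_exclusion=edge_exclusion,
        )
        if region is None:
            starts.append(-1), ends.append(-1)
            fallbacks.append(pos is None), excluded.append(True)
        else:
            starts.append(region[0]), ends.append(region[1])
            fallbacks.append(region[2]), excluded.append(False)
    out = dmax_frame.copy()
    out["region_start"] = starts
    out["region_end"] = ends
    out["fallback_used"] = fallbacks
    out["region_excluded"] = excluded
    return out


def pause_site_table(
    maps,
    condition: str = "treated",
    ratio_threshold: float = DEFAULT_PAUSE_RATIO,
    transcript_ids=None,
) -> pd.DataFrame:
    """Pause sites per transcript from replicate-averaged densities."""
    density = maps.mean_density(condition)
    tids = maps.transcript_ids if transcript_ids is None else transcript_ids
    parts = []
    for tid in tids:
        sites = call_pause_sites(
            density[maps._span(tid)], ratio_threshold=ratio_threshold
        )
        if len(sites):
            sites.insert(0, "transcript_id", tid)
            parts.append(sites)
    if not parts:
        return pd.DataFrame(columns=["transcript_id", "codon", "ratio", "is_main"])
    return pd.concat(parts, ignore_index=True)
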