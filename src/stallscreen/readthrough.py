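"""Differential read-count test 3' of the stall position.

A genuine stall depletes footprints downstream of the slow codons. For
each transcript the reads in the downstream analysis region are summed
per sample, lightly filtered (more than ``min_region_counts`` reads over
all samples), normalized by median-of-ratios size factors, and tested
for a treated-vs-control difference with a negative-binomial Wald test.
P-values are Benjamini-Hochberg adjusted; a transcript is finally called
stalled when it is both a DMax candidate (Z >= 2) and significantly
depleted downstream (adjusted p < alpha with log2 fold change < 0).

The test models counts as NB with variance ``mu + alpha * mu^2``; the
per-row dispersion ``alpha`` is a method-of-moments estimate pooled over
the two groups and floored at 1e-8. Because only three replicates per
group are available, the Wald statistic is referenced to a t
distribution with ``nA + nB - 2`` degrees of freedom rather than a
standard normal; the normal reference is markedly anti-conservative at
this sample size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sum_region_counts",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "classify_stalled",
    "test_readthrough",
]

DEFAULT_MIN_REGION_COUNTS = 30
DEFAULT_ALPHA = 0.05
DISPERSION_FLOOR = 1e-8


def sum_region_counts(
    maps,
    regions: pd.DataFrame,
    min_region_counts: int = DEFAULT_MIN_REGION_COUNTS,
) -> tuple[pd.DataFrame, dict]:
    """Per-sample read sums over each transcript's analysis region.

    ``regions`` is the frame from :func:`stallscreen.stalls.define_regions`.
    Rows whose total over all samples is not strictly greater than
    ``min_region_counts`` are dropped, as are transcripts with an empty
    region. Returns the count matrix (index: transcript_id, columns:
    ``condition_replicate``) and a tally of exclusions.

    Raises ``KeyError`` if a region references an unknown transcript.
    """
    tally = {"input": int(len(regions)), "empty_region": 0, "low_counts": 0}
    sample_cols = [f"{c}_{r}" for c, r in maps.samples]
    rows, index = [], []
    for row in regions.itertuples():
        tid = row.transcript_id
        if tid not in maps._tid_index:
            raise KeyError(f"region references unknown transcript {tid!r}")
        if bool(row.region_excluded):
            tally["empty_region"] += 1
            continue
        span = maps._span(tid)
        sums = maps.counts[:, span][:, int(row.region_start): int(row.region_end)].sum(axis=1)
        if sums.sum() <= min_region_counts:
            tally["low_counts"] += 1
            continue
        rows.append(sums)
        index.append(tid)
    matrix = pd.DataFrame(rows, index=index, columns=sample_cols, dtype=np.int64)
    matrix.index.name = "transcript_id"
    tally["retained"] = int(len(matrix))
    return matrix, tally


def size_factors(matrix) -> np.ndarray:
    """Median-of-ratios sample scale factors.

    Each sample's factor is the median, over rows with no zero count, of
    the ratio of that row's count to the row's geometric mean. When no
    zero-free row exists, falls back to column totals scaled to geometric
    mean 1, with a warning.
    """
    counts = np.asarray(matrix, dtype=np.float64)
    zero_free = (counts > 0).all(axis=1)
    if zero_free.any():
        sub = counts[zero_free]
        gm = np.exp(np.log(sub).mean(axis=1, keepdims=True))
        return np.median(sub / gm, axis=0)
    warnings.warn(
        "no zero-free rows for median-of-ratios; using total-count ratios",
        stacklevel=2,
    )
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts; cannot normalize")
    return totals / np.exp(np.log(totals).mean())


def nb_test(
    counts,
    group_a,
    group_b,
    factors=None,
    pseudocount: float = 0.5,
    dispersion_floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Row-wise NB Wald test of group B vs group A normalized means.

    ``counts`` is (rows, samples); ``group_a``/``group_b`` are column
    index arrays (A = reference, e.g. control; B = treated). Returns a
    frame with ``log2_fold_change`` (B over A; ``pseudocount`` added to a
    group mean only when it is zero), ``p_value``, the estimated
    ``dispersion`` and a ``poisson_limit`` flag marking rows where the
    method-of-moments estimate collapsed to the floor.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.float64))
    if factors is None:
        factors = np.ones(counts.shape[1])
    norm = counts / np.asarray(factors, dtype=np.float64)
    A, B = norm[:, group_a], norm[:, group_b]
    nA, nB = A.shape[1], B.shape[1]
    if nA < 2 or nB < 2:
        raise ValueError("need at least two samples per group")

    mA, mB = A.mean(axis=1), B.mean(axis=1)
    vA, vB = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alphaA = (vA - mA) / mA**2
        alphaB = (vB - mB) / mB**2
    alphaA = np.where(np.isfinite(alphaA), alphaA, 0.0)
    alphaB = np.where(np.isfinite(alphaB), alphaB, 0.0)
    alpha = ((nA - 1) * alphaA + (nB - 1) * alphaB) / (nA + nB - 2)
    poisson_limit = alpha <= dispersion_floor
    alpha = np.maximum(alpha, dispersion_floor)

    mA_safe = np.where(mA > 0, mA, pseudocount)
    mB_safe = np.where(mB > 0, mB, pseudocount)
    log2_fc = np.log2(mB_safe / mA_safe)

    # delta-method variance of the log group means under the NB model
    var_log = (1.0 / mA_safe + alpha) / nA + (1.0 / mB_safe + alpha) / nB
    wald = np.log(mB_safe / mA_safe) / np.sqrt(var_log)
    p = 2.0 * stats.t.sf(np.abs(wald), df=nA + nB - 2)

    return pd.DataFrame(
        {
            "log2_fold_change": log2_fc,
            "p_value": p,
            "dispersion": alpha,
            "poisson_limit": poisson_limit,
        }
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(adjusted[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def classify_stalled(
    dmax_frame: pd.DataFrame,
    de_frame: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Final stalled calls: DMax candidate AND significant downstream depletion.

    ``significant`` requires adjusted p < ``alpha`` and a negative log2
    fold change (downstream depletion); the final call is the conjunction
    with the Z >= threshold candidacy. Transcripts absent from the DE
    stage (filtered out) carry NaN statistics and are never called.
    """
    merged = dmax_frame.merge(de_frame, on="transcript_id", how="left")
    merged["significant"] = (
        (merged["fdr_adjusted_p"] < alpha) & (merged["log2_fold_change"] < 0)
    ).fillna(False)
    merged["stalled"] = merged["is_candidate"] & merged["significant"]
    return merged


def test_readthrough(
    maps,
    regions: pd.DataFrame,
    treated: str = "treated",
    control: str = "control",
    min_region_counts: int = DEFAULT_MIN_REGION_COUNTS,
) -> tuple[pd.DataFrame, dict]:
    """Region summation, filtering, normalization and NB testing in one step.

    Returns the per-transcript DE frame (log2_fold_change, p_value,
    fdr_adjusted_p, base counts) and the region-filter tally.
    """
    matrix, tally = sum_region_counts(
        maps, regions, min_region_counts=min_region_counts
    )
    if len(matrix) == 0:
        empty = pd.DataFrame(
            columns=["transcript_id", "base_counts", "log2_fold_change",
                     "p_value", "fdr_adjusted_p"]
        )
        return empty, tally
    factors = size_factors(matrix)
    cond = [c for c, _ in maps.samples]
    group_a = np.array([i for i, c in enumerate(cond) if c == control])
    group_b = np.array([i for i, c in enumerate(cond) if c == treated])
    de = nb_test(matrix.to_numpy(), group_a, group_b, factors)
    de.insert(0, "transcript_id", matrix.index.to_numpy())
    de.insert(1, "base_counts", matrix.sum(axis=1).to_numpy())
    de["fdr_adjusted_p"] = bh_adjust(de["p_value"].to_numpy())
    return de, tally
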