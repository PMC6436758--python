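"""Pooled CRISPRi growth-screen phenotypes: Gamma, Tau, Rho and gene hits.

Each sgRNA's abundance is measured at T0 and after growth in vehicle and
in drug. Per-doubling log2 enrichments define three phenotypes:

* gamma — growth effect without drug (T0 -> vehicle end),
* tau   — growth effect with drug (T0 -> drug end),
* rho   — drug-specific effect (vehicle end -> drug end).

When both arms undergo the same number of doublings, rho = tau - gamma.
Phenotypes are centered so the median non-targeting sgRNA is 0. Gene
scores average the 3 sgRNAs of largest absolute phenotype; a Mann-Whitney
U test compares all of a gene's sgRNAs against the non-targeting
population. A gene is a hit when |rho score| exceeds 0.1 and the
BH-adjusted Mann-Whitney p-value is below 1e-6. Positive rho means the
knockdown is enriched under drug relative to vehicle (protective
knockdown, i.e. the encoded protein sensitizes cells to the compound).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "sgrna_enrichment",
    "compute_phenotypes",
    "gene_score",
    "mann_whitney_gene",
    "score_genes",
    "call_hits",
    "pseudogene_scores",
]

DEFAULT_PSEUDOCOUNT = 10.0
DEFAULT_RHO_CUTOFF = 0.1
DEFAULT_P_CUTOFF = 1e-6
ARMS = ("T0", "vehicle", "drug")


def sgrna_enrichment(
    count_a,
    count_b,
    total_a: float,
    total_b: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    doublings: float = 1.0,
) -> np.ndarray:
    """Per-doubling log2 enrichment of endpoint B relative to endpoint A.

    Counts get ``pseudocount`` added, are converted to frequencies using
    the sample totals, and the log2 frequency ratio is divided by the
    number of population doublings. Centering on the non-targeting
    median is applied separately (see :func:`compute_phenotypes`).
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("sample totals must be positive")
    if doublings <= 0:
        raise ValueError("doublings must be positive")
    fa = (np.asarray(count_a, dtype=np.float64) + pseudocount) / total_a
    fb = (np.asarray(count_b, dtype=np.float64) + pseudocount) / total_b
    return np.log2(fb / fa) / doublings


def _arm_columns(counts: pd.DataFrame) -> dict:
    """Map each arm to its replicate-sorted count columns; validate presence."""
    arms = {}
    for arm in ARMS:
        cols = sorted(
            c for c in counts.columns
            if c == arm or c.startswith(arm + "_")
        )
        if not cols:
            raise ValueError(f"count table is missing the {arm!r} arm")
        arms[arm] = cols
    reps = {len(v) for v in arms.values()}
    if len(reps) != 1:
        raise ValueError(f"unequal replicate counts per arm: { {a: len(c) for a, c in arms.items()} }")
    return arms


def compute_phenotypes(
    counts: pd.DataFrame,
    doublings_vehicle: float = 1.0,
    doublings_drug: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Gamma/tau/rho per sgRNA: per replicate, centered, then replicate-averaged.

    ``counts`` needs ``sgrna_id``, ``gene``, ``is_nontargeting`` and count
    columns named ``<arm>_<replicate>`` for arms T0/vehicle/drug. Each
    phenotype is centered by subtracting the median over non-targeting
    sgRNAs within the same replicate, so "no effect" maps to 0. Rho is
    normalized by the drug arm's doublings.
    """
    arms = _arm_columns(counts)
    n_rep = len(arms["T0"])
    nt = counts["is_nontargeting"].to_numpy().astype(bool)
    if not nt.any():
        raise ValueError("count table contains no non-targeting sgRNAs")

    out = counts[["sgrna_id", "gene", "is_nontargeting"]].copy()
    pairs = {
        "gamma": ("T0", "vehicle", doublings_vehicle),
        "tau": ("T0", "drug", doublings_drug),
        "rho": ("vehicle", "drug", doublings_drug),
    }
    for name, (arm_a, arm_b, doublings) in pairs.items():
        per_rep = []
        for r in range(n_rep):
            ca = counts[arms[arm_a][r]].to_numpy()
            cb = counts[arms[arm_b][r]].to_numpy()
            phen = sgrna_enrichment(
                ca, cb, ca.sum(), cb.sum(),
                pseudocount=pseudocount, doublings=doublings,
            )
            phen = phen - np.median(phen[nt])
            out[f"{name}_{r + 1}"] = phen
            per_rep.append(phen)
        out[name] = np.mean(per_rep, axis=0)
    return out


def gene_score(values, ids=None) -> float:
    """Average of the 3 phenotypes of largest absolute value, signs kept.

    With fewer than 3 sgRNAs all are averaged. Ties in absolute value are
    broken by sgRNA id (then input order) for determinism.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("gene has no sgRNA phenotypes")
    ids = np.arange(values.size) if ids is None else np.asarray(ids)
    order = np.lexsort((ids, -np.abs(values)))
    return float(values[order[: min(3, values.size)]].mean())


def mann_whitney_gene(gene_values, control_values) -> float:
    """Two-sided Mann-Whitney U p-value of a gene's sgRNAs vs controls.

    With no ties in the pooled sample the exact null distribution of U is
    used (the normal approximation truncates the extreme tails that the
    screen's stringent p cutoff lives in); with ties, the tie-corrected
    normal approximation. The exact distribution is cached per sample-size
    pair, so scoring thousands of same-sized genes stays fast.
    """
    x = np.asarray(gene_values, dtype=np.float64)
    y = np.asarray(control_values, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both sgRNA sets must be non-empty")
    pooled = np.concatenate([x, y])
    method = "exact" if np.unique(pooled).size == pooled.size else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def score_genes(
    phenotypes: pd.DataFrame,
    phenotype_columns=("gamma", "tau", "rho"),
    mw_phenotype: str = "rho",
) -> pd.DataFrame:
    """Gene-level top-3 scores and Mann-Whitney p-values vs non-targeting.

    Scores use the replicate-averaged phenotypes. The Mann-Whitney test
    compares all of a gene's sgRNAs (``mw_phenotype`` values) against the
    full non-targeting population; p-values are BH-adjusted across genes.
    """
    nt = phenotypes["is_nontargeting"].astype(bool)
    controls = phenotypes.loc[nt, mw_phenotype].to_numpy()
    targeting = phenotypes.loc[~nt]
    rows = []
    for gene, grp in targeting.groupby("gene", sort=True):
        ids = grp["sgrna_id"].to_numpy()
        row = {"gene": gene, "n_sgrnas": len(grp)}
        for col in phenotype_columns:
            row[f"score_{col}"] = gene_score(grp[col].to_numpy(), ids)
        row["mw_p"] = mann_whitney_gene(grp[mw_phenotype].to_numpy(), controls)
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        from .readthrough import bh_adjust

        out["mw_p_adjusted"] = bh_adjust(out["mw_p"].to_numpy())
    return out


def call_hits(
    gene_scores: pd.DataFrame,
    rho_cutoff: float = DEFAULT_RHO_CUTOFF,
    p_cutoff: float = DEFAULT_P_CUTOFF,
) -> pd.DataFrame:
    """Apply the hit filter: |rho score| > cutoff and adjusted p < cutoff.

    Hits are labeled ``protective`` (positive rho: knockdown enriched
    under drug, the protein product sensitizes) or ``sensitizing``
    (negative rho: knockdown depleted under drug, the protein protects).
    """
    out = gene_scores.copy()
    out["is_hit"] = (
        (out["score_rho"].abs() > rho_cutoff) & (out["mw_p_adjusted"] < p_cutoff)
    )
    direction = np.where(out["score_rho"] > 0, "protective", "sensitizing")
    out["direction"] = np.where(out["is_hit"], direction, "")
    return out


def pseudogene_scores(
    phenotypes: pd.DataFrame,
    n_pseudogenes: int,
    sgrnas_per_gene: int = 10,
    mw_phenotype: str = "rho",
    rng=None,
) -> pd.DataFrame:
    """Score random groups of non-targeting sgRNAs as null pseudo-genes.

    Groups of ``sgrnas_per_gene`` control sgRNAs are drawn (without
    replacement within a group) and pushed through the same gene scoring
    and Mann-Whitney machinery, giving an empirical null for the hit
    filter. BH adjustment is applied within the pseudo-gene family.
    """
    rng = np.random.default_rng(rng)
    nt = phenotypes.loc[phenotypes["is_nontargeting"].astype(bool)]
    if len(nt) < sgrnas_per_gene:
        raise ValueError("not enough non-targeting sgRNAs to form a pseudo-gene")
    pieces = []
    for i in range(n_pseudogenes):
        pick = nt.iloc[rng.choice(len(nt), size=sgrnas_per_gene, replace=False)].copy()
        pick["gene"] = f"pseudo_{i:05d}"
        pick["is_nontargeting"] = False
        pieces.append(pick)
    combined = pd.concat([*pieces, nt], ignore_index=True)
    scored = score_genes(combined, mw_phenotype=mw_phenotype)
    return call_hits(scored)
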