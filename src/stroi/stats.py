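"""Downstream statistics: Wilcoxon DEG, BH correction, ORA, proportions.

The differential-expression contrast between ROI 1 and ROI 2 uses the
two-sided Wilcoxon rank-sum test per gene on the log-normalized matrix,
with the normal approximation, tie-corrected variance and no continuity
correction — the convention of the standard single-cell gene-ranking
routines, so volcano panels are directly comparable.  Fold changes are
log2 ratios of group means on the de-logged (expm1) scale with a small
pseudocount.  Multiple testing uses Benjamini-Hochberg step-up.
Over-representation of a DEG list in curated gene sets uses the
upper-tail hypergeometric test, BH-adjusted across terms.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import (
    CellTypeProportions,
    DEGTable,
    GeneSetLibrary,
    ORATable,
    SpatialDataset,
    SpotAssignment,
    SpotLabel,
)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``adj[i] = min_{j: p_(j) >= p_(i)} ( p_(j) * m / j )`` clipped at 1,
    returned in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


_EXACT_GROUP_MAX = 10


@lru_cache(maxsize=64)
def _exact_u_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the Mann-Whitney U statistic, by counting.

    ``counts[u]`` is the number of the C(n1+n2, n1) rank assignments with
    U = u, built with the standard recurrence
    ``f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u)``.
    """
    table = np.zeros((n1 + 1, n2 + 1, n1 * n2 + 1), dtype=float)
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            prev = np.zeros(n1 * n2 + 1)
            prev[j:] = table[i - 1, j, : n1 * n2 + 1 - j]
            table[i, j] = prev + table[i, j - 1]
    return table[n1, n2]


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    For small tie-free groups (each at most 10) the p-value comes from the
    exact permutation null of U; otherwise from the normal approximation
    with tie-corrected variance and no continuity correction.  Returns 1.0
    when every observation is tied (zero variance).
    """
    n1, n2 = len(a), len(b)
    n = n1 + n2
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    _, counts = np.unique(combined, return_counts=True)
    has_ties = counts.size < n
    if max(n1, n2) <= _EXACT_GROUP_MAX and not has_ties:
        dist = _exact_u_counts(n1, n2)
        u_values = np.arange(dist.size)
        extreme = np.abs(u_values - mu) >= abs(u1 - mu) - 1e-9
        return float(dist[extreme].sum() / dist.sum())
    tie_sum = float(np.sum(counts.astype(float) ** 3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (u1 - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


def wilcoxon_deg(
    ds: SpatialDataset,
    labels: SpotAssignment,
    pseudocount: float = 1e-9,
) -> DEGTable:
    """Per-gene Wilcoxon rank-sum DEG table between ROI 1 and ROI 2.

    Requires the normalized matrix and at least two spots per ROI.
    ``log_fc = log2((mean expm1 over ROI1 + pc) / (mean expm1 over ROI2 + pc))``,
    positive meaning up in ROI 1; BH adjustment over all tested genes.
    Genes expressed in neither group get p = 1 and log_fc = 0 by
    convention.
    """
    if ds.normalized is None:
        raise ValueError("dataset must be log-normalized before DEG testing")
    idx1 = labels.indices(SpotLabel.ROI1)
    idx2 = labels.indices(SpotLabel.ROI2)
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError(
            f"each ROI needs >= 2 spots (got {len(idx1)} and {len(idx2)})"
        )
    x1 = ds.normalized[idx1]
    x2 = ds.normalized[idx2]

    expm1_1 = np.expm1(x1)
    expm1_2 = np.expm1(x2)
    mean1 = expm1_1.mean(axis=0)
    mean2 = expm1_2.mean(axis=0)
    # difference of logs rather than log of ratio: same value, and exactly
    # antisymmetric under swapping the ROIs
    with np.errstate(divide="ignore", invalid="ignore"):
        log_fc = np.log2(mean1 + pseudocount) - np.log2(mean2 + pseudocount)

    n_genes = ds.n_genes
    p = np.ones(n_genes, dtype=float)
    for g in range(n_genes):
        a, b = x1[:, g], x2[:, g]
        if not (a.any() or b.any()):  # zero in both groups
            p[g] = 1.0
            log_fc[g] = 0.0
            continue
        p[g] = _rank_sum_p(a, b)

    table = pd.DataFrame(
        {
            "gene": ds.gene_ids,
            "log_fc": log_fc,
            "p_value": p,
            "p_adj": bh_adjust(p),
            "mean_roi1": mean1,
            "mean_roi2": mean2,
            "group": "ns",
        }
    )
    return DEGTable(table=table)


def classify_degs(
    table: DEGTable, logfc_cutoff: float, padj_cutoff: float
) -> DEGTable:
    """Partition genes into up_roi1 / up_roi2 / ns by strict cutoffs.

    ``up_roi1`` needs ``log_fc > logfc_cutoff`` and ``p_adj < padj_cutoff``;
    ``up_roi2`` mirrors with ``log_fc < -logfc_cutoff``.  A gene exactly at
    a cutoff stays ``ns``.
    """
    if logfc_cutoff < 0 or padj_cutoff < 0:
        raise ValueError("cutoffs must be non-negative")
    t = table.table.copy()
    sig = t["p_adj"] < padj_cutoff
    t["group"] = "ns"
    t.loc[sig & (t["log_fc"] > logfc_cutoff), "group"] = "up_roi1"
    t.loc[sig & (t["log_fc"] < -logfc_cutoff), "group"] = "up_roi2"
    return DEGTable(table=t, logfc_cutoff=logfc_cutoff, padj_cutoff=padj_cutoff)


def top_degs(table: DEGTable, n: int = 10, group: str = "up_roi1") -> List[str]:
    """Top-n genes of a DEG group by fold-change magnitude.

    ``up_roi1`` genes are sorted by log_fc descending (``up_roi2`` by
    ascending, i.e. strongest ROI2 enrichment first); ties break by
    smaller p_adj, then lexicographic gene id.
    """
    t = table.table
    sub = t.loc[t["group"] == group]
    ascending_fc = group == "up_roi2"
    sub = sub.sort_values(
        by=["log_fc", "p_adj", "gene"],
        ascending=[ascending_fc, True, True],
        kind="mergesort",
    )
    return sub["gene"].head(n).tolist()


def ora(
    query_genes: Sequence[str],
    library: GeneSetLibrary,
    universe_genes: Sequence[str],
    padj_keep: float = 0.05,
) -> ORATable:
    """Hypergeometric over-representation of a gene list in a library.

    Gene matching is case-insensitive (symbols uppercased).  For each term
    with ``K = |term ∩ universe| > 0``, the upper-tail probability
    ``P(X >= k)`` of drawing ``k = |query ∩ term|`` term genes in ``n``
    draws from a universe of ``N`` is computed, then BH-adjusted across
    tested terms.  Rows with ``p_adj < padj_keep`` are flagged
    ``reported``; every tested term stays in the table.
    """
    universe = {str(g).upper() for g in universe_genes}
    query = {str(g).upper() for g in query_genes} & universe
    if not query:
        raise ValueError(
            "query has no genes in the universe; check gene-symbol case and "
            "naming conventions between the expression data and the library"
        )
    N = len(universe)
    n = len(query)
    rows = []
    for term, genes in library.terms.items():
        term_in_universe = genes & universe
        K = len(term_in_universe)
        if K == 0:
            continue
        k = len(query & term_in_universe)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(1.0, p)))
    if not rows:
        table = pd.DataFrame(
            columns=["term", "k", "K", "n", "N", "p_value", "p_adj", "reported"]
        )
        return ORATable(table=table, library_name=library.name)
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_value"])
    table["p_adj"] = bh_adjust(table["p_value"].to_numpy())
    table["reported"] = table["p_adj"] < padj_keep
    table = table.sort_values(
        by=["p_adj", "p_value", "term"], kind="mergesort"
    ).reset_index(drop=True)
    return ORATable(table=table, library_name=library.name)


def celltype_proportions(
    fractions: pd.DataFrame,
    labels: SpotAssignment,
    barcodes: Sequence[str],
) -> CellTypeProportions:
    """Mean cell-type fraction per ROI from a spot-level fraction matrix.

    ``fractions`` is indexed by barcode (externally produced deconvolution
    output); ``barcodes`` aligns the label vector with that index.  A ROI
    barcode missing from the fraction matrix is an error.
    """
    if len(barcodes) != len(labels.labels):
        raise ValueError("barcodes must align with labels")
    means: Dict[str, np.ndarray] = {}
    counts: Dict[str, int] = {}
    for roi in (SpotLabel.ROI1, SpotLabel.ROI2):
        idx = labels.indices(roi)
        roi_barcodes = [str(barcodes[i]) for i in idx]
        missing = [b for b in roi_barcodes if b not in fractions.index]
        if missing:
            raise ValueError(
                f"{len(missing)} {roi.value} barcode(s) missing from the "
                f"fraction matrix; first missing: {missing[:5]}"
            )
        sub = fractions.loc[roi_barcodes]
        means[roi.value] = sub.to_numpy(dtype=float).mean(axis=0)
        counts[roi.value] = len(idx)
    roi_means = pd.DataFrame(means, index=fractions.columns).T
    roi_means.index.name = "roi"
    return CellTypeProportions(
        fractions=fractions, roi_means=roi_means, roi_counts=counts
    )
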