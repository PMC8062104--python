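"""Minimal single-cell expression stage and DME-gene expression comparisons.

Counts live in a genes x cells pandas DataFrame of non-negative integers.
The processing mirrors the standard droplet-RNA-seq recipe: keep cells with
more than ``min_umi`` transcripts (strictly more, default 10,000), scale each
cell to ``scale`` counts and take ln(1 + x) ("LogNormalize"), then select
variable genes by dispersion z-scored within mean-expression bins. Gene-set
comparisons (all genes / DME-regulated / differentially expressed / random
control) use Welch's unequal-variance t-test on per-gene mean expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genelink import hypergeom_overlap

logger = logging.getLogger(__name__)


def validate_counts(m: pd.DataFrame) -> None:
    if m.index.has_duplicates or m.columns.has_duplicates:
        raise ValueError("duplicate gene or cell identifiers")
    values = m.to_numpy()
    if not np.isfinite(values).all() or (values < 0).any():
        raise ValueError("counts must be finite and non-negative")


def filter_cells(m: pd.DataFrame, min_umi: int = 10_000) -> pd.DataFrame:
    """Keep cells with strictly more than ``min_umi`` total counts."""
    validate_counts(m)
    if m.shape[1] == 0:
        raise ValueError("empty count matrix")
    keep = m.sum(axis=0) > min_umi
    if not keep.any():
        raise ValueError(f"no cell exceeds {min_umi} UMIs")
    return m.loc[:, keep]


def log_normalize(m: pd.DataFrame, scale: float = 10_000.0, base: float | None = None) -> pd.DataFrame:
    """Per-cell global scaling: value = log(1 + scale * count / cell_total).

    Natural log by default; pass ``base`` to change it (recorded by callers
    in output metadata). Zeros stay zero and within-cell ordering is
    preserved.
    """
    totals = m.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("cells with zero total counts; run filter_cells first")
    normalized = np.log1p(m * (scale / totals))
    if base is not None:
        normalized = normalized / np.log(base)
    return normalized


def variable_genes(
    m_norm: pd.DataFrame,
    x_low: float = 0.2,
    x_high: float = 5.0,
    y_cutoff: float = 0.5,
    y_high: float = 10.0,
    n_bins: int = 20,
) -> list:
    """Dispersion-based variable-gene selection on a log-normalized matrix.

    Per gene: mean and dispersion (variance/mean) are computed on
    expm1-back-transformed values, the mean is re-logged, and dispersions are
    z-scored within ``n_bins`` equal-frequency mean bins. Genes pass with
    mean in (x_low, x_high) and dispersion z-score in (y_cutoff, y_high).
    """
    back = np.expm1(m_norm)
    gene_mean = back.mean(axis=1)
    gene_var = back.var(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(gene_mean > 0, gene_var / gene_mean, 0.0)
    dispersion = pd.Series(dispersion, index=m_norm.index)
    log_mean = np.log1p(gene_mean)

    n_genes = len(log_mean)
    if n_genes < n_bins:
        logger.warning("only %d genes for %d bins; reducing bins", n_genes, n_bins)
        n_bins = max(1, n_genes)
    try:
        bins = pd.qcut(log_mean.rank(method="first"), n_bins, labels=False)
    except ValueError:
        bins = pd.Series(0, index=log_mean.index)

    z = pd.Series(0.0, index=m_norm.index)
    for _, idx in pd.Series(m_norm.index, index=bins.values).groupby(level=0):
        d = dispersion.loc[idx.values]
        sd = d.std(ddof=1)
        z.loc[idx.values] = (d - d.mean()) / sd if sd and sd > 0 else 0.0

    keep = (log_mean > x_low) & (log_mean < x_high) & (z > y_cutoff) & (z < y_high)
    return list(m_norm.index[keep])


@dataclass
class GroupCompareResult:
    set_means: dict  # set name -> per-gene mean expression (pd.Series)
    summary: pd.DataFrame
    pairwise: pd.DataFrame
    skipped: list
    random_seed: int | None = None

    def mean_of(self, name: str) -> float:
        return float(self.set_means[name].mean())


def group_expression_compare(
    m_norm: pd.DataFrame,
    gene_sets: Mapping[str, Sequence],
    *,
    random_control: bool = True,
    match_set: str = "dme_genes",
    seed: int = 0,
) -> GroupCompareResult:
    """Compare per-gene mean expression between named gene sets.

    Adds a ``random`` control set size-matched to ``match_set`` (seeded draw
    from all genes) unless one is supplied. Every pair of sets with >= 2
    genes is compared with Welch's two-sample t-test; smaller sets are
    skipped with a notice.
    """
    per_gene = m_norm.mean(axis=1)
    sets = {name: [g for g in genes if g in per_gene.index]
            for name, genes in gene_sets.items()}
    random_seed = None
    if random_control and "random" not in sets:
        size = len(sets.get(match_set, per_gene.index))
        rng = np.random.default_rng(seed)
        sets["random"] = list(
            rng.choice(per_gene.index.to_numpy(), size=min(size, len(per_gene)), replace=False)
        )
        random_seed = seed

    set_means = {}
    skipped = []
    for name, genes in sets.items():
        if len(genes) < 2:
            skipped.append(name)
            logger.warning("gene set %s has %d genes; comparisons skipped", name, len(genes))
            continue
        set_means[name] = per_gene.loc[genes]

    summary = pd.DataFrame(
        {
            "n_genes": {k: len(v) for k, v in set_means.items()},
            "mean": {k: float(v.mean()) for k, v in set_means.items()},
            "median": {k: float(v.median()) for k, v in set_means.items()},
        }
    )
    rows = []
    names = list(set_means)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = set_means[a], set_means[b]
            if set(va.index) == set(vb.index):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_ind(va, vb, equal_var=False)
            rows.append({"set_a": a, "set_b": b, "t": float(t), "p_value": float(p)})
    pairwise = pd.DataFrame(rows, columns=["set_a", "set_b", "t", "p_value"])
    return GroupCompareResult(set_means, summary, pairwise, skipped, random_seed)


def marker_overlap(
    cluster_markers: Mapping[str, Sequence],
    dme_genes: Sequence,
    universe: Sequence,
) -> dict:
    """Hypergeometric overlap of DME-regulated genes with per-cluster markers.

    Returns per-cluster (overlap, p) plus a pooled test over the union of all
    marker genes; ``n_distinct_markers_hit`` counts distinct marker genes
    regulated by a DME.
    """
    universe = set(universe)
    dme_set = set(dme_genes)
    per_cluster = {}
    pooled_markers: set = set()
    for cluster, markers in cluster_markers.items():
        k, p = hypergeom_overlap(dme_set, markers, universe)
        per_cluster[cluster] = {"overlap": k, "p_value": p, "n_markers": len(set(markers))}
        pooled_markers |= set(markers)
    k_pooled, p_pooled = hypergeom_overlap(dme_set, pooled_markers, universe)
    return {
        "per_cluster": per_cluster,
        "pooled": {"overlap": k_pooled, "p_value": p_pooled,
                   "n_markers": len(pooled_markers)},
        "n_distinct_markers_hit": len(pooled_markers & dme_set),
        "universe_size": len(universe),
    }


def windowed_read_count(
    read_intervals: Sequence,
    anchors: Sequence,
    half_window: int = 1000,
) -> dict:
    """Reads whose midpoint falls in [anchor - hw, anchor + hw) per anchor.

    ``read_intervals`` are (chrom, start, end[, ...]) records; ``anchors``
    are TSS-like records with chrom/pos (or (chrom, pos) tuples). Used for
    e.g. counting repressive-mark reads around TSSs.
    """
    mids: dict = {}
    for r in read_intervals:
        chrom, start, end = r[0], r[1], r[2]
        mids.setdefault(chrom, []).append((start + end) // 2)
    mids = {c: np.sort(np.asarray(v)) for c, v in mids.items()}
    out = {}
    for a in anchors:
        chrom, pos = (a.chrom, a.pos) if hasattr(a, "pos") else (a[0], a[1])
        key = getattr(a, "gene_id", None) or (chrom, pos)
        m = mids.get(chrom)
        if m is None:
            out[key] = 0
            continue
        lo = int(np.searchsorted(m, pos - half_window, side="left"))
        hi = int(np.searchsorted(m, pos + half_window, side="left"))
        out[key] = hi - lo
    return out
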