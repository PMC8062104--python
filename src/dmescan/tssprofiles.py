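"""Composite methylation profiles around transcription start sites.

Classified reads (methylated vs unmethylated; mixed reads removed upstream)
are assigned, by midpoint, to strand-oriented 200-bp offset bins around each
TSS (upstream negative, downstream positive). Counts are normalized per
million classified reads so conditions of different depth are comparable.
The composite (mean over TSSs per offset) exposes where 5mC accumulates
relative to promoters: active-promoter nucleosomes keep a central ~1.5-kb
window depleted of methylation, so that window is masked by default when
relating TSS-proximal methylation to expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .methcalls import METHYLATED, UNMETHYLATED, ReadMethRecord

logger = logging.getLogger(__name__)

LAYERS = (UNMETHYLATED, METHYLATED)


@dataclass
class ProfileMatrix:
    """Per-anchor, per-offset read counts split by methylation class.

    ``offsets`` holds bin start offsets relative to the TSS (strand-oriented,
    so -10000..-9800 is the farthest upstream bin). ``raw`` holds integer
    read counts; :meth:`values` rescales to reads per million classified
    reads.
    """

    anchors: list  # gene_ids of the TSSs profiled
    offsets: np.ndarray  # bin start offsets, symmetric about 0
    raw: dict  # layer -> int array (n_anchors, n_offsets)
    n_classified: int
    bin_size: int
    half_window: int

    @property
    def norm_factor(self) -> float:
        return 1e6 / self.n_classified if self.n_classified else 0.0

    def values(self, layer: str) -> np.ndarray:
        return self.raw[layer] * self.norm_factor

    def composite(self, layer: str) -> pd.Series:
        """Mean normalized count per offset over all anchors."""
        return pd.Series(self.values(layer).mean(axis=0), index=self.offsets, name=layer)

    def mc_peaks(self) -> dict:
        """Location (bin start offset) and height of the 5mC composite peak
        on each side of the TSS."""
        comp = self.composite(METHYLATED)
        out = {}
        for side, mask in (("upstream", comp.index < 0), ("downstream", comp.index >= 0)):
            sub = comp[mask]
            if len(sub) == 0 or sub.max() == 0:
                out[side] = None
            else:
                off = int(sub.idxmax())
                out[side] = {"offset": off, "height": float(sub.max())}
        return out


def tss_profile(
    records: Sequence[ReadMethRecord],
    tss: Sequence,
    half_window: int = 10_000,
    bin_size: int = 200,
    *,
    stranded: bool = True,
) -> ProfileMatrix:
    """Accumulate classified reads into TSS-centered offset bins.

    A read contributes (by midpoint) to every TSS whose window contains it.
    Offsets are oriented by TSS strand when ``stranded``: for a minus-strand
    TSS, genomically higher coordinates map to negative (upstream) offsets.
    Reads on chromosomes without any TSS are ignored.
    """
    if half_window % bin_size:
        raise ValueError("half_window must be a multiple of bin_size")
    offsets = np.arange(-half_window, half_window, bin_size)
    n_off = len(offsets)

    mids: dict = {layer: {} for layer in LAYERS}
    n_classified = 0
    for rec in records:
        if rec.meth_class not in LAYERS:
            continue
        n_classified += 1
        mids[rec.meth_class].setdefault(rec.chrom, []).append(rec.midpoint)
    mids = {
        layer: {c: np.sort(np.asarray(v)) for c, v in per.items()}
        for layer, per in mids.items()
    }

    anchors = []
    raw = {layer: np.zeros((len(tss), n_off), dtype=np.int64) for layer in LAYERS}
    for ai, t in enumerate(tss):
        anchors.append(t.gene_id if hasattr(t, "gene_id") else f"{t[0]}:{t[1]}")
        chrom = t.chrom if hasattr(t, "chrom") else t[0]
        pos = t.pos if hasattr(t, "pos") else t[1]
        strand = getattr(t, "strand", "+") if stranded else "+"
        for layer in LAYERS:
            m = mids[layer].get(chrom)
            if m is None:
                continue
            lo = int(np.searchsorted(m, pos - half_window, side="left"))
            hi = int(np.searchsorted(m, pos + half_window, side="left"))
            window = m[lo:hi]
            rel = window - pos if strand != "-" else pos - window
            rel = rel[(rel >= -half_window) & (rel < half_window)]
            idx = (rel + half_window) // bin_size
            np.add.at(raw[layer][ai], idx.astype(int), 1)
    return ProfileMatrix(anchors, offsets, raw, n_classified, bin_size, half_window)


def expression_ordered_heatmap(
    profile: ProfileMatrix,
    expression: Mapping,
    half_window: int = 5_000,
    n_expr_bins: int = 10,
    n_tss: int = 3_500,
    seed: int = 0,
) -> dict:
    """Stratified random TSS sample ordered high-to-low by expression.

    Anchors with known expression are split into ``n_expr_bins``
    equal-frequency bins; an equal random sample is drawn per bin (seeded)
    up to ``n_tss`` rows total, and rows are ordered by decreasing
    expression. Returns one DataFrame per layer restricted to
    +-``half_window`` offsets.
    """
    expr = pd.Series({a: expression[a] for a in profile.anchors if a in expression})
    if expr.empty:
        raise ValueError("no profiled anchor has an expression value")
    n_bins = min(n_expr_bins, len(expr))
    bins = pd.qcut(expr.rank(method="first"), n_bins, labels=False)
    per_bin = max(1, n_tss // n_bins)
    rng = np.random.default_rng(seed)
    chosen: list = []
    for b in range(n_bins):
        members = expr.index[bins == b].to_numpy()
        if len(members) <= per_bin:
            if len(members) < per_bin:
                logger.warning("expression bin %d has %d < %d anchors; taking all",
                               b, len(members), per_bin)
            chosen.extend(members)
        else:
            chosen.extend(rng.choice(members, size=per_bin, replace=False))
    order = expr.loc[chosen].sort_values(ascending=False).index

    col_mask = (profile.offsets >= -half_window) & (profile.offsets < half_window)
    anchor_pos = {a: i for i, a in enumerate(profile.anchors)}
    out = {}
    for layer in LAYERS:
        values = profile.values(layer)
        rows = np.array([values[anchor_pos[a]] for a in order])
        out[layer] = pd.DataFrame(rows[:, col_mask], index=list(order),
                                  columns=profile.offsets[col_mask])
    return out


def expression_meth_curve(
    profile: ProfileMatrix,
    expression: Mapping,
    gene_sets: Mapping[str, Sequence] | None = None,
    *,
    promoter_mask: int = 1_500,
    window: int | None = None,
) -> dict:
    """Per-gene TSS-proximal 5mC read counts against expression rank.

    The 5mC layer is summed per anchor over the profile window (optionally
    restricted to +-``window``), excluding offset bins overlapping the
    central +-``promoter_mask`` promoter region where active nucleosomes keep
    DNA unmethylated. Returns per-set curves (sorted high-to-low expression)
    and the Pearson/Spearman correlation between counts and expression over
    anchors with known expression.
    """
    offs = profile.offsets
    keep = np.ones_like(offs, dtype=bool)
    if promoter_mask:
        keep &= ~((offs + profile.bin_size > -promoter_mask) & (offs < promoter_mask))
    if window is not None:
        keep &= (offs >= -window) & (offs < window)
    mc = profile.values(METHYLATED)[:, keep].sum(axis=1)
    per_gene = pd.Series(mc, index=profile.anchors)

    expr = pd.Series({a: expression[a] for a in profile.anchors if a in expression})
    gene_sets = dict(gene_sets or {})
    gene_sets.setdefault("all", list(expr.index))

    curves = {}
    skipped = []
    for name, genes in gene_sets.items():
        genes = [g for g in genes if g in expr.index]
        if not genes:
            skipped.append(name)
            logger.warning("gene set %s empty after matching anchors; skipped", name)
            continue
        df = pd.DataFrame({"expression": expr.loc[genes], "mc_reads": per_gene.loc[genes]})
        curves[name] = df.sort_values("expression", ascending=False)

    correlation = None
    note = None
    base = curves.get("all")
    if base is None or base.mc_reads.sum() == 0 or base.mc_reads.nunique() < 2:
        note = "correlation undefined: no (or constant) methylated reads"
    else:
        pr = stats.pearsonr(base.mc_reads, base.expression)
        sr = stats.spearmanr(base.mc_reads, base.expression)
        correlation = {
            "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
        }
    return {"curves": curves, "correlation": correlation, "skipped": skipped,
            "note": note, "promoter_mask": promoter_mask}
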