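"""Enhancer methylation states and differentially methylated enhancers (DMEs).

A 200-bp bin observed under two pull-downs (mark A = H3K4me1, mark B =
H3K27ac) forms an :class:`EnhancerBinPair` when both marks pass the coverage
filter at that bin. A DME is a pair whose per-CpG 5mC percentages differ by
at least ``min_diff`` points (default 20, chosen to clear the 2-5% spike-in
error rate with margin). The direction matters biologically: higher
methylation under H3K4me1 than H3K27ac is the signature of a cell
subpopulation in which the enhancer lost H3K27ac and is being decommissioned,
since the two marks sample different cells at the same genomic position.

Methylation state labels follow the standard methylome vocabulary:
UMR (<20% 5mC), LMR (20-80%), HMR (>80%).
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genomebins import MethBin

logger = logging.getLogger(__name__)

K4ME1_HIGH = "K4me1_high"
K27AC_HIGH = "K27ac_high"

UMR = "UMR"
LMR = "LMR"
HMR = "HMR"


@dataclass(frozen=True)
class MethState:
    label: str
    umr_max: float = 20.0
    lmr_max: float = 80.0


@dataclass
class EnhancerBinPair:
    """The same genomic bin observed under both chromatin pull-downs."""

    chrom: str
    bin_start: int
    pct_a: float
    pct_b: float
    n_calls_a: int
    n_calls_b: int
    in_peak_a: bool = False
    in_peak_b: bool = False
    dist_to_peak_center_b: int | None = None
    n_reads_b: int = 0
    bin_size: int = 200

    @property
    def key(self) -> tuple:
        return (self.chrom, self.bin_start)

    @property
    def delta(self) -> float:
        return self.pct_a - self.pct_b


@dataclass(frozen=True)
class DMECall:
    """A bin called differentially methylated between the two marks."""

    chrom: str
    bin_start: int
    delta: float  # pct_a - pct_b, percentage points
    direction: str

    @property
    def key(self) -> tuple:
        return (self.chrom, self.bin_start)


def _peak_trees(peaks: Sequence) -> dict:
    trees: dict = {}
    for p in peaks:
        if p.end > p.start:
            trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)
    return trees


def _peak_centers(peaks: Sequence) -> dict:
    centers: dict = {}
    for p in peaks:
        centers.setdefault(p.chrom, []).append((p.start + p.end) // 2)
    return {c: np.sort(np.asarray(v)) for c, v in centers.items()}


def intersect_peaks(bins: Sequence[MethBin], peaks: Sequence) -> dict:
    """Annotate bins with peak membership and distance to a peak center.

    A bin is in-peak when it overlaps any peak by >= 1 bp (half-open
    intervals: touching does not overlap). The distance is |bin midpoint -
    peak midpoint| of the nearest overlapping peak; for bins outside all
    peaks it falls back to the nearest peak center on the chromosome.
    Returns ``{(chrom, bin_start): (in_peak, distance_or_None)}``.
    """
    trees = _peak_trees(peaks)
    centers = _peak_centers(peaks)
    out = {}
    for b in bins:
        mid = b.bin_start + b.bin_size // 2
        tree = trees.get(b.chrom)
        hits = tree.overlap(b.bin_start, b.bin_start + b.bin_size) if tree else ()
        if hits:
            dist = min(abs(mid - (h.data.start + h.data.end) // 2) for h in hits)
            out[b.key] = (True, int(dist))
        else:
            cs = centers.get(b.chrom)
            dist = int(np.min(np.abs(cs - mid))) if cs is not None and len(cs) else None
            out[b.key] = (False, dist)
    return out


def pair_bins(
    bins_a: Sequence[MethBin],
    bins_b: Sequence[MethBin],
    peaks_a: Sequence | None = None,
    peaks_b: Sequence | None = None,
) -> list[EnhancerBinPair]:
    """Pair bins covered under both marks (intersection of bin keys)."""
    index_b = {b.key: b for b in bins_b}
    ann_a = intersect_peaks(bins_a, peaks_a) if peaks_a else {}
    ann_b = intersect_peaks(bins_b, peaks_b) if peaks_b else {}
    pairs = []
    for a in bins_a:
        b = index_b.get(a.key)
        if b is None:
            continue
        in_a, _ = ann_a.get(a.key, (False, None))
        in_b, dist_b = ann_b.get(a.key, (False, None))
        pairs.append(
            EnhancerBinPair(
                a.chrom, a.bin_start, a.pct_5mc, b.pct_5mc, a.n_calls, b.n_calls,
                in_peak_a=in_a, in_peak_b=in_b, dist_to_peak_center_b=dist_b,
                n_reads_b=b.n_reads, bin_size=a.bin_size,
            )
        )
    return pairs


def classify_state(pct: float, umr_max: float = 20.0, lmr_max: float = 80.0) -> MethState:
    """UMR below ``umr_max``, LMR in [umr_max, lmr_max], HMR above."""
    if not (0.0 <= pct <= 100.0):
        raise ValueError(f"pct {pct} outside [0, 100]")
    if pct < umr_max:
        label = UMR
    elif pct <= lmr_max:
        label = LMR
    else:
        label = HMR
    return MethState(label, umr_max, lmr_max)


def call_dmes(pairs: Sequence[EnhancerBinPair], min_diff: float = 20.0) -> list[DMECall]:
    """Emit DME calls for pairs whose 5mC percentages differ by >= ``min_diff``."""
    out = []
    for p in pairs:
        delta = p.delta
        if abs(delta) >= min_diff:
            direction = K4ME1_HIGH if delta > 0 else K27AC_HIGH
            out.append(DMECall(p.chrom, p.bin_start, delta, direction))
    return out


def dme_direction_counts(dmes: Sequence[DMECall]) -> Counter:
    return Counter(d.direction for d in dmes)


@dataclass
class CorrelationResult:
    pearson: pd.DataFrame
    spearman: pd.DataFrame
    n_bins: int


def correlate_maps(map_set: Mapping[str, pd.Series]) -> CorrelationResult:
    """Pearson and Spearman correlations between per-bin read-count maps.

    Maps (e.g. the eight mark x C/5mC x condition groups) are aligned on the
    intersection of their bin indices and log-scaled as log2(count + 1);
    both matrices are symmetric with unit diagonal.
    """
    if len(map_set) < 2:
        raise ValueError("need at least two maps to correlate")
    df = pd.concat(map_set, axis=1, join="inner")
    if len(df) < 3:
        raise ValueError(f"only {len(df)} shared bins; need >= 3")
    logdf = np.log2(df.astype(float) + 1.0)
    return CorrelationResult(
        pearson=logdf.corr(method="pearson"),
        spearman=logdf.corr(method="spearman"),
        n_bins=len(df),
    )


def bin_count_series(bins: Sequence[MethBin], layer: str) -> pd.Series:
    """Per-bin read counts for one layer ('C' unmethylated / '5mC' methylated)."""
    if layer not in ("C", "5mC"):
        raise ValueError("layer must be 'C' or '5mC'")
    data = {
        b.key: (b.n_reads_meth if layer == "5mC" else b.n_reads_unmeth) for b in bins
    }
    s = pd.Series(data, dtype=float)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["chrom", "bin_start"])
    return s.sort_index()


TRANSITIONS = ("UMR->UMR", "UMR->LMR", "LMR->UMR", "LMR->LMR")


@dataclass
class TransitionTable:
    counts: dict
    summaries: pd.DataFrame
    n_indeterminate: int

    def as_dict(self) -> dict:
        return {
            "counts": dict(self.counts),
            "n_indeterminate": self.n_indeterminate,
        }


def state_transitions(
    bins_cond1: Sequence[MethBin],
    bins_cond2: Sequence[MethBin],
    shift_min: float = 30.0,
    umr_max: float = 20.0,
) -> TransitionTable:
    """Classify UMR/LMR transitions of bins covered in both conditions.

    A bin is UMR in a condition when its 5mC is below ``umr_max``; calling a
    gain (``->LMR``) additionally requires condition-2 methylation above
    ``shift_min`` so that small drifts near the UMR border are not counted as
    state shifts. Bins whose condition-2 methylation falls between ``umr_max``
    and ``shift_min`` fit neither state and are tallied as indeterminate.
    """
    index2 = {b.key: b for b in bins_cond2}
    shared = [(a, index2[a.key]) for a in bins_cond1 if a.key in index2]
    if not shared:
        raise ValueError("no bins covered in both conditions")
    counts: Counter = Counter({t: 0 for t in TRANSITIONS})
    rows = []
    n_indet = 0
    for a, b in shared:
        s1 = UMR if a.pct_5mc < umr_max else LMR
        if b.pct_5mc < umr_max:
            s2 = UMR
        elif b.pct_5mc > shift_min:
            s2 = LMR
        else:
            n_indet += 1
            continue
        t = f"{s1}->{s2}"
        counts[t] += 1
        rows.append(
            {"transition": t, "pct_1": a.pct_5mc, "pct_2": b.pct_5mc,
             "reads_1": a.n_reads, "reads_2": b.n_reads}
        )
    frame = pd.DataFrame(rows, columns=["transition", "pct_1", "pct_2", "reads_1", "reads_2"])
    summaries = (
        frame.groupby("transition").mean().reindex(TRANSITIONS)
        if len(frame)
        else pd.DataFrame(index=pd.Index(TRANSITIONS, name="transition"))
    )
    return TransitionTable(dict(counts), summaries, n_indet)


def chrom_distribution(
    dmes: Sequence[DMECall],
    enhancer_bins: Sequence[MethBin],
    x_chrom: str = "chrX",
):
    """Per-chromosome DME fraction normalized by enhancer-bin count.

    Returns ``(table, report)``: the table holds n_dme, n_bins and fraction
    per chromosome; the report compares the X chromosome against the pooled
    autosomes (z-score under a binomial model), the negative control for
    allelic asymmetry. Chromosomes without enhancer bins are excluded with a
    warning.
    """
    n_bins: Counter = Counter(b.chrom for b in enhancer_bins)
    n_dme: Counter = Counter(d.chrom for d in dmes)
    for chrom in n_dme:
        if n_bins[chrom] == 0:
            logger.warning("chromosome %s has DMEs but no enhancer bins; excluded", chrom)
    chroms = sorted(c for c in n_bins if n_bins[c] > 0)
    table = pd.DataFrame(
        {
            "chrom": chroms,
            "n_dme": [n_dme[c] for c in chroms],
            "n_enhancer_bins": [n_bins[c] for c in chroms],
        }
    )
    table["fraction"] = table.n_dme / table.n_enhancer_bins

    auto = table[table.chrom != x_chrom]
    report = {
        "x_chrom": x_chrom,
        "x_fraction": None,
        "autosome_fractions": dict(zip(auto.chrom, auto.fraction)),
        "autosome_pooled_fraction": (
            float(auto.n_dme.sum() / auto.n_enhancer_bins.sum()) if len(auto) else None
        ),
        "z_score": None,
    }
    if x_chrom in set(table.chrom) and len(auto):
        fx = float(table.loc[table.chrom == x_chrom, "fraction"].iloc[0])
        nx = int(table.loc[table.chrom == x_chrom, "n_enhancer_bins"].iloc[0])
        p0 = report["autosome_pooled_fraction"]
        se = math.sqrt(max(p0 * (1 - p0), 1e-12) / nx)
        report["x_fraction"] = fx
        report["x_n_bins"] = nx
        report["binomial_se"] = se
        report["z_score"] = (fx - p0) / se
    return table, report


def dme_peak_context(
    dmes: Sequence[DMECall],
    bins_b: Sequence[MethBin],
    peaks_b: Sequence,
) -> dict:
    """Per-direction mark-B read counts and distances to mark-B peak centers.

    Decommissioning leaves H3K4me1-high DMEs sitting where H3K27ac peaks used
    to be centered, so their distance-to-center distribution should sit below
    that of K27ac-high DMEs; the report includes a rank-sum comparison when
    both directions are populated.
    """
    if not dmes:
        return {"groups": {}, "comparison": None, "note": "no DMEs"}
    index_b = {b.key: b for b in bins_b}
    centers = _peak_centers(peaks_b)
    groups: dict = {}
    for d in dmes:
        b = index_b.get(d.key)
        reads = b.n_reads if b is not None else 0
        mid = d.bin_start + (b.bin_size // 2 if b is not None else 100)
        cs = centers.get(d.chrom)
        dist = int(np.min(np.abs(cs - mid))) if cs is not None and len(cs) else None
        g = groups.setdefault(d.direction, {"read_counts": [], "distances": []})
        g["read_counts"].append(reads)
        if dist is not None:
            g["distances"].append(dist)

    summary = {
        direction: {
            "n": len(g["read_counts"]),
            "mean_reads_b": float(np.mean(g["read_counts"])),
            "median_dist_to_center_b": (
                float(np.median(g["distances"])) if g["distances"] else None
            ),
        }
        for direction, g in groups.items()
    }
    comparison = None
    if len(groups) == 2 and all(len(g["distances"]) >= 1 for g in groups.values()):
        d1 = groups[K4ME1_HIGH]["distances"]
        d2 = groups[K27AC_HIGH]["distances"]
        stat, p = stats.mannwhitneyu(d1, d2, alternative="two-sided")
        comparison = {"test": "mannwhitneyu", "statistic": float(stat), "p_value": float(p)}
    note = None if comparison else "comparison skipped: need both directions"
    return {"groups": summary, "raw": groups, "comparison": comparison, "note": note}
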