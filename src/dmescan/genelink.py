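"""Map DMEs to target genes through a cis-regulatory atlas; gene-set overlaps.

The atlas is a many-to-many table of enhancer intervals and the genes they
regulate. A gene is "hit" by a DME when any DME bin overlaps (or lies within
``max_gap`` of) any atlas interval linked to it. Overlap between two gene
sets is scored with the upper-tail hypergeometric test against an explicit,
caller-supplied gene universe — the universe choice changes the p-value, so
it is recorded in every report rather than assumed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree
from scipy import stats

from .simpop import GenomicInterval


class AtlasParseError(ValueError):
    pass


@dataclass
class GeneLinkTable:
    """Deduplicated (enhancer interval, gene_id) records."""

    records: list  # of (GenomicInterval, gene_id)

    @property
    def genes(self) -> set:
        return {g for _, g in self.records}

    def trees(self) -> dict:
        """chrom -> IntervalTree of (interval, gene) payloads."""
        out: dict = {}
        for iv, gene in self.records:
            if iv.end > iv.start:
                out.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, (iv, gene))
        return out


def read_atlas(path) -> GeneLinkTable:
    """Read a chrom/start/end/gene_id TSV; header auto-detected, duplicates collapsed."""
    seen = set()
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4 or not fields[3]:
                raise AtlasParseError(f"{path}: line {lineno}: need chrom, start, end, gene_id")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                if lineno == 1:  # header
                    continue
                raise AtlasParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start > end:
                raise AtlasParseError(f"{path}: line {lineno}: invalid interval [{start}, {end})")
            key = (fields[0], start, end, fields[3])
            if key in seen:
                continue
            seen.add(key)
            records.append((GenomicInterval(fields[0], start, end, fields[3]), fields[3]))
    return GeneLinkTable(records)


def map_dmes_to_genes(
    dmes: Sequence,
    atlas: GeneLinkTable,
    max_gap: int = 0,
    bin_size: int = 200,
) -> dict:
    """Genes whose atlas intervals overlap any DME bin, with supporting DME counts.

    Returns ``{gene_id: n_supporting_DMEs}`` ordered by decreasing support.
    ``max_gap`` pads each DME bin symmetrically before intersecting
    (default 0: strict overlap). Adding DMEs can only add genes.
    """
    trees = atlas.trees()
    support: Counter = Counter()
    for d in dmes:
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        start = max(0, d.bin_start - max_gap)
        end = d.bin_start + bin_size + max_gap
        genes_hit = {payload.data[1] for payload in tree.overlap(start, end)}
        for g in genes_hit:
            support[g] += 1
    return dict(sorted(support.items(), key=lambda kv: (-kv[1], kv[0])))


def hypergeom_overlap(
    set_a: Iterable, set_b: Iterable, universe: Iterable
) -> tuple[int, float]:
    """Observed overlap and upper-tail hypergeometric p-value P(X >= k).

    Population = |universe|, successes = |set_a|, draws = |set_b|. Both sets
    must be contained in the universe; offending elements are named.
    """
    universe = set(universe)
    set_a, set_b = set(set_a), set(set_b)
    for label, s in (("set_a", set_a), ("set_b", set_b)):
        stray = s - universe
        if stray:
            raise ValueError(f"{label} not contained in universe: {sorted(stray)[:10]}")
    k = len(set_a & set_b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
    return k, min(p, 1.0)
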