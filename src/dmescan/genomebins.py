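"""Fixed-width genomic binning of CpG calls with coverage and TSS-distance filters.

The genome is segmented into 200-bp bins — the length of the nucleosomal DNA
unit — and methylated/unmethylated CpG calls are aggregated per bin. A CpG
call belongs to the bin containing its own position; a read's class
(methylated/unmethylated) is credited to the single bin containing the read
midpoint, so call-level and read-level summaries can disagree at bin borders
by design. Downstream analyses keep only bins with enough CpG observations
(default >= 30 calls) lying far from transcription start sites (default
>= 10 kb), which restricts the signal to distal regulatory elements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .methcalls import METHYLATED, UNMETHYLATED, ReadMethRecord


class BedParseError(ValueError):
    """Malformed BED/bedGraph content; message carries the line number."""


@dataclass
class MethBin:
    """One fixed-width bin's methylation call and read counts."""

    chrom: str
    bin_start: int
    n_meth: int = 0
    n_unmeth: int = 0
    n_reads_meth: int = 0
    n_reads_unmeth: int = 0
    n_positions: int = 0
    bin_size: int = 200

    def __post_init__(self) -> None:
        if self.bin_start < 0 or self.bin_start % self.bin_size:
            raise ValueError(
                f"bin_start {self.bin_start} not a non-negative multiple of {self.bin_size}"
            )

    @property
    def n_calls(self) -> int:
        return self.n_meth + self.n_unmeth

    @property
    def n_reads(self) -> int:
        return self.n_reads_meth + self.n_reads_unmeth

    @property
    def pct_5mc(self) -> float:
        if self.n_calls == 0:
            return math.nan
        return 100.0 * self.n_meth / self.n_calls

    @property
    def key(self) -> tuple:
        return (self.chrom, self.bin_start)


def bin_calls(records: Sequence[ReadMethRecord], bin_size: int = 200) -> list[MethBin]:
    """Aggregate classified (non-mixed) read records into methylation bins.

    Only bins receiving at least one CpG call are emitted, sorted by
    coordinate. Reads classified methylated/unmethylated also increment the
    read-level counters of the bin containing their midpoint; a midpoint bin
    that received no CpG call is dropped together with its read counters, so
    conservation is guaranteed for calls but not for read-level counts.
    """
    bins: dict = {}

    def get(chrom: str, start: int) -> MethBin:
        key = (chrom, start)
        if key not in bins:
            bins[key] = MethBin(chrom, start, bin_size=bin_size)
        return bins[key]

    positions: dict = {}
    for rec in records:
        for call in rec.calls:
            b = get(call.chrom, (call.pos // bin_size) * bin_size)
            if call.methylated:
                b.n_meth += 1
            else:
                b.n_unmeth += 1
            positions.setdefault(b.key, set()).add(call.pos)
        if rec.meth_class in (METHYLATED, UNMETHYLATED):
            b = get(rec.chrom, (rec.midpoint // bin_size) * bin_size)
            if rec.meth_class == METHYLATED:
                b.n_reads_meth += 1
            else:
                b.n_reads_unmeth += 1

    out = [b for b in bins.values() if b.n_calls > 0]
    for b in out:
        b.n_positions = len(positions.get(b.key, ()))
    out.sort(key=lambda b: (b.chrom, b.bin_start))
    return out


def filter_bins(
    bins: Sequence[MethBin],
    min_calls: int = 30,
    tss: Sequence | None = None,
    min_tss_distance: int = 10_000,
    *,
    use_distinct_positions: bool = False,
) -> list[MethBin]:
    """Keep bins with sufficient CpG coverage that lie distal to all TSSs.

    Coverage counts total CpG call observations by default (enhancers hold
    few distinct CpG positions, so a distinct-position threshold of 30 in
    200 bp would rarely be satisfiable); set ``use_distinct_positions`` to
    threshold on distinct CpG positions instead. Distance is measured from
    the nearest bin edge to the nearest TSS point, and ties at exactly
    ``min_tss_distance`` are kept.
    """
    tss_by_chrom: dict = {}
    if tss:
        for t in tss:
            chrom, pos = (t.chrom, t.pos) if hasattr(t, "pos") else (t[0], t[1])
            tss_by_chrom.setdefault(chrom, []).append(pos)
        tss_by_chrom = {c: np.sort(np.asarray(p)) for c, p in tss_by_chrom.items()}

    kept = []
    for b in bins:
        coverage = b.n_positions if use_distinct_positions else b.n_calls
        if coverage < min_calls:
            continue
        positions = tss_by_chrom.get(b.chrom)
        if positions is not None and len(positions):
            d = _interval_to_points_distance(b.bin_start, b.bin_start + b.bin_size, positions)
            if d < min_tss_distance:
                continue
        kept.append(b)
    return kept


def _interval_to_points_distance(start: int, end: int, points: np.ndarray) -> int:
    """Distance from [start, end) to the nearest of sorted ``points`` (0 if inside)."""
    i = int(np.searchsorted(points, start))
    best = None
    for p in points[max(0, i - 1) : i + 2]:
        if start <= p < end:
            return 0
        d = start - p if p < start else p - (end - 1)
        best = d if best is None else min(best, d)
    return int(best)


def bins_to_frame(bins: Sequence[MethBin]) -> pd.DataFrame:
    rows = [
        {
            "chrom": b.chrom,
            "bin_start": b.bin_start,
            "n_meth": b.n_meth,
            "n_unmeth": b.n_unmeth,
            "n_reads_meth": b.n_reads_meth,
            "n_reads_unmeth": b.n_reads_unmeth,
            "n_positions": b.n_positions,
            "pct_5mc": b.pct_5mc,
        }
        for b in bins
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "bin_start", "n_meth", "n_unmeth",
                 "n_reads_meth", "n_reads_unmeth", "n_positions", "pct_5mc"],
    )


def write_bin_table(bins: Sequence[MethBin], path) -> None:
    bins_to_frame(bins).to_csv(path, sep="\t", index=False, float_format="%.1f")


def read_bin_table(path, bin_size: int = 200) -> list[MethBin]:
    df = pd.read_csv(path, sep="\t")
    return [
        MethBin(
            r.chrom, int(r.bin_start), int(r.n_meth), int(r.n_unmeth),
            int(r.n_reads_meth), int(r.n_reads_unmeth),
            int(getattr(r, "n_positions", 0)), bin_size,
        )
        for r in df.itertuples(index=False)
    ]


def write_bedgraph(bins: Sequence[MethBin], path) -> None:
    """bedGraph of per-bin 5mC percentages, sorted by coordinate."""
    rows = sorted(bins, key=lambda b: (b.chrom, b.bin_start))
    with open(path, "w") as fh:
        for b in rows:
            fh.write(f"{b.chrom}\t{b.bin_start}\t{b.bin_start + b.bin_size}\t{b.pct_5mc:.1f}\n")


def read_bed(path) -> list:
    """Read BED3-BED6 into 0-based half-open :class:`GenomicInterval` records."""
    from .simpop import GenomicInterval

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from None
            if start < 0 or start > end:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else "."
            out.append(GenomicInterval(chrom, start, end, name))
    return out


def read_tss_bed(path) -> list:
    """Read a BED6 of TSS points into (chrom, pos, strand, gene_id) records."""
    from .simpop import TSS

    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}: line {lineno}: TSS BED needs >= 4 fields")
            strand = fields[5] if len(fields) > 5 else "+"
            try:
                pos = int(fields[1])
            except ValueError:
                raise BedParseError(f"{path}: line {lineno}: non-integer position") from None
            out.append(TSS(fields[0], pos, strand, fields[3]))
    return out
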