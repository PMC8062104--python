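"""Per-read CpG methylation calls: parsing, read classification and spike-in QC.

Sequential ChIP-bisulfite reads carry zero or more CpG cytosines. Because DNA
methyltransferases act processively over nucleosome-scale distances, all CpGs
on one ~200-bp read are expected to share a methylation state; a read whose
CpGs disagree ("mixed") is treated as a bisulfite/PCR/sequencing artifact and
removed before any methylation summary. Reads without CpGs ("non_cpg") are
kept for class accounting but contribute nothing to methylation percentages.

Input is the tab-separated per-call format produced by the Bismark
methylation extractor: read_id, strand flag, chromosome, 1-based position,
single-character call (``Z`` methylated CpG, ``z`` unmethylated CpG; other
context symbols such as ``X/x``, ``H/h``, ``U/u`` are tallied and skipped).
Positions are converted to 0-based on input and back to 1-based on output.
"""

from __future__ import annotations

import gzip
import json
import logging
import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: read-level methylation classes
UNMETHYLATED = "unmethylated"
METHYLATED = "methylated"
MIXED = "mixed"
NON_CPG = "non_cpg"
METH_CLASSES = (UNMETHYLATED, METHYLATED, MIXED, NON_CPG)

#: Bismark context symbols that are counted but not parsed as CpG calls
_SKIPPED_SYMBOLS = {"X", "x", "H", "h", "U", "u", "."}


class ExtractorParseError(ValueError):
    """Raised for malformed extractor lines; message carries the line number."""


@dataclass(frozen=True)
class CpGCall:
    """One CpG observation on one read.

    ``pos`` is the 0-based plus-strand coordinate of the CpG cytosine; both
    strands of a symmetric CpG collapse onto this single position.
    """

    chrom: str
    pos: int
    methylated: bool
    read_id: str

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative CpG position {self.pos}")
        if not self.read_id:
            raise ValueError("read_id must be non-empty")


@dataclass
class ReadMethRecord:
    """A sequencing read with its ordered CpG calls and methylation class."""

    read_id: str
    chrom: str
    start: int
    end: int
    calls: list[CpGCall] = field(default_factory=list)
    meth_class: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")
        for c in self.calls:
            if not (self.start <= c.pos < self.end):
                raise ValueError(
                    f"call at {c.pos} outside read span [{self.start}, {self.end})"
                )
        if self.meth_class is None:
            self.meth_class = classify_read(self)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ClassCounts:
    """Read counts per methylation class with derived fractions."""

    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, meth_class: str) -> float:
        if meth_class not in METH_CLASSES:
            raise KeyError(meth_class)
        total = self.total
        return self.counts[meth_class] / total if total else 0.0

    def as_dict(self) -> dict:
        return {
            "counts": {k: self.counts[k] for k in METH_CLASSES},
            "fractions": {k: self.fraction(k) for k in METH_CLASSES},
            "total": self.total,
        }


@dataclass
class SpikeInReport:
    """Per-class and per-position accuracy of spike-in methylation calls."""

    per_position_accuracy: dict
    accuracy_methylated: float
    accuracy_unmethylated: float
    n_reads: int

    def __post_init__(self) -> None:
        for a in (self.accuracy_methylated, self.accuracy_unmethylated):
            if not math.isnan(a) and not (0.0 <= a <= 100.0):
                raise ValueError(f"accuracy {a} outside [0, 100]")

    def as_dict(self) -> dict:
        return {
            "per_position_accuracy": {
                f"{chrom}:{pos}": acc
                for (chrom, pos), acc in sorted(self.per_position_accuracy.items())
            },
            "accuracy_methylated": self.accuracy_methylated,
            "accuracy_unmethylated": self.accuracy_unmethylated,
            "n_reads": self.n_reads,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1)


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def read_extractor_file(path, *, return_skipped: bool = False):
    """Parse a Bismark-extractor CpG call file into :class:`CpGCall` records.

    1-based input positions become 0-based. Non-CpG context symbols are
    skipped and tallied. Returns the call list, or ``(calls, skipped_tally)``
    when ``return_skipped`` is set.
    """
    calls: list[CpGCall] = []
    skipped: Counter = Counter()
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if lineno == 1 and _looks_like_header(fields):
                continue
            if len(fields) < 5:
                raise ExtractorParseError(
                    f"{path}: line {lineno}: expected 5 fields, got {len(fields)}"
                )
            read_id, _strand, chrom, pos_s, symbol = fields[:5]
            try:
                pos1 = int(pos_s)
            except ValueError:
                raise ExtractorParseError(
                    f"{path}: line {lineno}: non-integer position {pos_s!r}"
                ) from None
            if symbol in _SKIPPED_SYMBOLS:
                skipped[symbol] += 1
                continue
            if symbol not in ("Z", "z"):
                raise ExtractorParseError(
                    f"{path}: line {lineno}: unknown call symbol {symbol!r}"
                )
            calls.append(
                CpGCall(chrom=chrom, pos=pos1 - 1, methylated=symbol == "Z", read_id=read_id)
            )
    if not calls:
        logger.warning("no CpG calls parsed from %s", path)
    if return_skipped:
        return calls, skipped
    return calls


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) < 4:
        return True
    try:
        int(fields[3])
    except ValueError:
        return True
    return False


def group_calls(calls: Iterable[CpGCall], read_len: int | None = None) -> list[ReadMethRecord]:
    """Assemble calls into per-read records keyed by (read_id, chrom).

    Extractor files carry no read span, so the span is taken as the hull of
    the read's calls (optionally widened to ``read_len`` around its center).
    Reads without any CpG never appear in extractor output and so cannot be
    recovered here; the simulator emits them directly.
    """
    grouped: dict[tuple, list[CpGCall]] = defaultdict(list)
    for c in calls:
        grouped[(c.read_id, c.chrom)].append(c)
    records = []
    for (read_id, chrom), cs in grouped.items():
        cs.sort(key=lambda c: c.pos)
        start, end = cs[0].pos, cs[-1].pos + 1
        if read_len is not None and end - start < read_len:
            mid = (start + end) // 2
            start = max(0, mid - read_len // 2)
            end = start + read_len
        records.append(ReadMethRecord(read_id, chrom, start, end, cs))
    records.sort(key=lambda r: (r.chrom, r.start, r.read_id))
    return records


def classify_read(record: ReadMethRecord) -> str:
    """Classify a read: no CpG -> non_cpg; unanimous -> (un)methylated; else mixed."""
    if not record.calls:
        return NON_CPG
    states = {c.methylated for c in record.calls}
    if states == {True}:
        return METHYLATED
    if states == {False}:
        return UNMETHYLATED
    return MIXED


def filter_mixed(records: Sequence[ReadMethRecord]) -> tuple[list[ReadMethRecord], ClassCounts]:
    """Drop mixed reads; return kept reads plus counts over all four classes."""
    counts = ClassCounts()
    kept = []
    for rec in records:
        cls = rec.meth_class or classify_read(rec)
        counts.counts[cls] += 1
        if cls != MIXED:
            kept.append(rec)
    return kept, counts


def class_log2_ratio(counts: ClassCounts) -> float:
    """log2 fold change of unmethylated over methylated read counts."""
    n_c = counts.counts[UNMETHYLATED]
    n_mc = counts.counts[METHYLATED]
    if n_mc == 0:
        raise ZeroDivisionError(
            "no methylated reads: log2 C/5mC ratio undefined; report 'undefined'"
        )
    if n_c == 0:
        raise ZeroDivisionError(
            "no unmethylated reads: log2 C/5mC ratio undefined; report 'undefined'"
        )
    return math.log2(n_c / n_mc)


def percent_5mc(calls: Sequence[CpGCall]) -> float:
    """Percentage of methylated CpG calls; caller must pass non-mixed reads' calls."""
    if not calls:
        raise ValueError("percent_5mc undefined on zero CpG calls")
    n_meth = sum(c.methylated for c in calls)
    return 100.0 * n_meth / len(calls)


def spikein_accuracy(calls: Sequence[CpGCall], truth: Mapping) -> SpikeInReport:
    """Score spike-in calls against the known methylation of each position.

    ``truth`` maps position keys to the true methylation state (bool). Keys
    may be bare offsets (single template) or ``(chrom, offset)`` pairs when
    several templates/strands are pooled. Per-class accuracy is the fraction
    of calls at truly (un)methylated positions that report that state.
    """
    if not truth:
        raise ValueError("empty spike-in truth table")
    qualified = any(isinstance(k, tuple) for k in truth)
    correct: Counter = Counter()
    seen: Counter = Counter()
    per_pos_ok: Counter = Counter()
    per_pos_n: Counter = Counter()
    read_ids = set()
    for c in calls:
        key = (c.chrom, c.pos) if qualified else c.pos
        if key not in truth:
            raise KeyError(f"spike-in call at unknown position {key!r}")
        true_meth = bool(truth[key])
        cls = METHYLATED if true_meth else UNMETHYLATED
        seen[cls] += 1
        ok = c.methylated == true_meth
        correct[cls] += ok
        pkey = key if qualified else ("spikein", key)
        per_pos_ok[pkey] += ok
        per_pos_n[pkey] += 1
        read_ids.add(c.read_id)

    def acc(cls: str) -> float:
        return 100.0 * correct[cls] / seen[cls] if seen[cls] else float("nan")

    per_position = {k: per_pos_ok[k] / per_pos_n[k] for k in per_pos_n}
    return SpikeInReport(
        per_position_accuracy=per_position,
        accuracy_methylated=acc(METHYLATED),
        accuracy_unmethylated=acc(UNMETHYLATED),
        n_reads=len(read_ids),
    )
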