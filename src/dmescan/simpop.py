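"""Synthetic sequential ChIP-bisulfite datasets from a heterogeneous cell population.

The generative model: a genome carries distal enhancers, each of which is, in
every cell independently, in one of three chromatin states —

* ``active``          — H3K4me1 + H3K27ac, essentially unmethylated DNA;
* ``decommissioned``  — H3K4me1 only, highly methylated DNA;
* ``silent``          — no enhancer mark, methylated DNA (never precipitated).

A ChIP-BS experiment for a mark pulls nucleosomal DNA only from cells whose
state carries that mark (rejection sampling over cells), then reports per-CpG
methylation calls corrupted by a symmetric bisulfite error model. The bulk
methylation of an enhancer under a pull-down is therefore a mixture over the
states compatible with the mark: an enhancer that is active in half the cells
and decommissioned in the other half reads ~41% methylated under H3K4me1 but
~2% under H3K27ac — a differentially methylated enhancer by construction.

Matched single-cell expression counts couple transcription to enhancer state
through a cis-regulatory atlas: genes linked to an enhancer that is active in
a given cell have their sampling rate multiplied by ``active_boost`` there.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .methcalls import CpGCall, ReadMethRecord

logger = logging.getLogger(__name__)

H3K4ME1 = "H3K4me1"
H3K27AC = "H3K27ac"
MARKS = (H3K4ME1, H3K27AC)

ACTIVE = "active"
DECOMMISSIONED = "decommissioned"
SILENT = "silent"

#: Table-style spike-in template: 5mC at the two (CpG) cytosines of the
#: central region; the primer-derived cytosines of the opposite strand are
#: unmodified. See :func:`simulate_spikein`.
SPIKE_IN_TEMPLATE = (
    "GAGTGGGTGTTGGTGTTTGTATTTAAATACGATTAAATAATATTAATATATT"
    "ATCGATTAAATAATAATTAATTAATATTTGATGTGATGGGTGGTATGG"
)

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class PlacementError(RuntimeError):
    """Feature placement failed; message names the violated constraint."""


class GenomicInterval(NamedTuple):
    chrom: str
    start: int
    end: int
    name: str = "."

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class TSS(NamedTuple):
    chrom: str
    pos: int
    strand: str
    gene_id: str


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cytosine_offsets(seq: str) -> list[int]:
    return [i for i, b in enumerate(seq) if b in "Cc"]


def cpg_offsets(seq: str) -> list[int]:
    """Offsets of cytosines in CpG context within ``seq``."""
    return [i for i in range(len(seq) - 1) if seq[i : i + 2].upper() == "CG"]


@dataclass
class ErrorModel:
    """Independent per-cytosine bisulfite call errors.

    conv_fail_rate: probability an unmethylated C escapes conversion and is
    read as 5mC. inappropriate_conv_rate: probability a methylated C is
    converted and read as C. Both default to 0.02, inside the 2-5% range a
    spike-in control typically reports.
    """

    conv_fail_rate: float = 0.02
    inappropriate_conv_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("conv_fail_rate", "inappropriate_conv_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 0.5):
                raise ValueError(f"{name}={v} outside [0, 0.5]")


@dataclass
class StateConfig:
    """Mixture over enhancer chromatin states and their observable properties."""

    state_fractions: dict
    mark_presence: dict
    meth_prob: dict

    @classmethod
    def default(cls) -> "StateConfig":
        return cls(
            state_fractions={ACTIVE: 0.5, DECOMMISSIONED: 0.3, SILENT: 0.2},
            mark_presence={
                (ACTIVE, H3K4ME1): 1.0,
                (ACTIVE, H3K27AC): 1.0,
                (DECOMMISSIONED, H3K4ME1): 1.0,
                (DECOMMISSIONED, H3K27AC): 0.0,
                (SILENT, H3K4ME1): 0.0,
                (SILENT, H3K27AC): 0.0,
            },
            meth_prob={ACTIVE: 0.02, DECOMMISSIONED: 0.8, SILENT: 0.85},
        )

    @classmethod
    def two_state(cls, f_active: float, meth_active: float = 0.02,
                  meth_decom: float = 0.8) -> "StateConfig":
        """Active/decommissioned mixture without a silent compartment."""
        return cls(
            state_fractions={ACTIVE: f_active, DECOMMISSIONED: 1.0 - f_active},
            mark_presence={
                (ACTIVE, H3K4ME1): 1.0,
                (ACTIVE, H3K27AC): 1.0,
                (DECOMMISSIONED, H3K4ME1): 1.0,
                (DECOMMISSIONED, H3K27AC): 0.0,
            },
            meth_prob={ACTIVE: meth_active, DECOMMISSIONED: meth_decom},
        )

    @property
    def states(self) -> tuple:
        return tuple(self.state_fractions)

    def presence(self, state: str, mark: str) -> float:
        return float(self.mark_presence.get((state, mark), 0.0))

    def validate(self) -> None:
        total = sum(self.state_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, not 1")
        for s, f in self.state_fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"fraction of {s} = {f} outside [0, 1]")
            m = self.meth_prob.get(s)
            if m is None or not (0.0 <= m <= 1.0):
                raise ValueError(f"meth_prob[{s}] = {m} invalid")
        for key, p in self.mark_presence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"mark_presence[{key}] = {p} outside [0, 1]")


@dataclass
class GenomeAnnotation:
    """Synthetic genome: chromosome sizes, distal enhancers with fixed CpG
    positions, TSSs and an enhancer-to-gene atlas."""

    chrom_sizes: dict
    enhancers: list  # of GenomicInterval
    cpg_positions: dict  # enhancer name -> sorted np.ndarray of C positions
    tss: list  # of TSS
    atlas: list  # of (GenomicInterval, gene_id)

    @property
    def genes(self) -> list:
        return [t.gene_id for t in self.tss]

    def enhancer_index(self) -> dict:
        return {e.name: i for i, e in enumerate(self.enhancers)}

    def gene_to_enhancers(self) -> dict:
        """gene_id -> list of enhancer indices linked through the atlas."""
        by_interval = {(e.chrom, e.start, e.end): i for i, e in enumerate(self.enhancers)}
        out: dict = {}
        for iv, gene in self.atlas:
            idx = by_interval.get((iv.chrom, iv.start, iv.end))
            if idx is None:
                raise ValueError(f"atlas interval {iv} is not a known enhancer")
            out.setdefault(gene, []).append(idx)
        return out

    def validate(self, min_tss_distance: int | None = None) -> None:
        for iv in self.enhancers:
            size = self.chrom_sizes.get(iv.chrom)
            if size is None or not (0 <= iv.start < iv.end <= size):
                raise ValueError(f"enhancer {iv} outside chromosome bounds")
        for t in self.tss:
            size = self.chrom_sizes.get(t.chrom)
            if size is None or not (0 <= t.pos < size):
                raise ValueError(f"TSS {t} outside chromosome bounds")
        self.gene_to_enhancers()  # raises on unknown atlas intervals
        if min_tss_distance is not None:
            for iv in self.enhancers:
                for t in self.tss:
                    if t.chrom == iv.chrom and _interval_point_distance(iv, t.pos) < min_tss_distance:
                        raise ValueError(
                            f"enhancer {iv.name} closer than {min_tss_distance} bp to TSS {t.gene_id}"
                        )


def _interval_point_distance(iv: GenomicInterval, pos: int) -> int:
    if pos < iv.start:
        return iv.start - pos
    if pos >= iv.end:
        return pos - (iv.end - 1)
    return 0


@dataclass
class PopulationModel:
    """Per-cell, per-enhancer chromatin-state assignment."""

    annotation: GenomeAnnotation
    config: StateConfig
    states: np.ndarray  # int8, shape (n_cells, n_enhancers), codes into config.states
    seed: int

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    @property
    def cell_ids(self) -> list:
        return [f"cell{i:04d}" for i in range(self.n_cells)]

    def state_of(self, cell: int, enhancer: int) -> str:
        return self.config.states[self.states[cell, enhancer]]

    def state_fraction(self, enhancer: int, state: str) -> float:
        code = self.config.states.index(state)
        return float(np.mean(self.states[:, enhancer] == code))

    @property
    def cell_states(self) -> dict:
        """(cell_id, enhancer_name) -> state; materialized on demand."""
        names = [e.name for e in self.annotation.enhancers]
        cells = self.cell_ids
        return {
            (cells[i], names[j]): self.config.states[self.states[i, j]]
            for i in range(self.n_cells)
            for j in range(len(names))
        }


def make_annotation(
    n_chrom: int = 1,
    chrom_len: int = 1_000_000,
    n_enhancers: int = 10,
    n_genes: int = 10,
    min_tss_distance: int = 10_000,
    cpg_density: int = 8,
    seed: int = 0,
    *,
    enhancer_len: int = 600,
    enhancer_gap: int = 400,
    tss_region_frac: float = 0.3,
    chrom_names: Sequence[str] | None = None,
    max_tries: int = 10_000,
) -> GenomeAnnotation:
    """Lay out a synthetic genome with gene-dense and distal-enhancer compartments.

    TSSs occupy the first ``tss_region_frac`` of each chromosome; enhancers are
    placed at random non-overlapping positions at least ``min_tss_distance``
    beyond that region, so every enhancer is distal to every TSS by
    construction. Deterministic for a fixed seed.
    """
    if chrom_names is None:
        chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    if len(chrom_names) != n_chrom:
        raise ValueError("chrom_names length must equal n_chrom")
    if cpg_density < 1 or cpg_density > enhancer_len // 2:
        raise ValueError(f"cpg_density {cpg_density} unrealizable in {enhancer_len} bp")
    rng = np.random.default_rng(seed)
    chrom_sizes = {c: int(chrom_len) for c in chrom_names}

    # round-robin feature assignment across chromosomes
    gene_chrom = [chrom_names[i % n_chrom] for i in range(n_genes)]
    enh_chrom = [chrom_names[i % n_chrom] for i in range(n_enhancers)]

    tss_hi = int(chrom_len * tss_region_frac)
    enh_lo = tss_hi + min_tss_distance
    enh_hi = chrom_len - enhancer_len
    if tss_hi < 1 or enh_lo > enh_hi:
        raise PlacementError(
            f"chromosome of {chrom_len} bp cannot host TSSs plus enhancers "
            f"{min_tss_distance} bp away (enhancer region [{enh_lo}, {enh_hi}] empty)"
        )

    tss: list[TSS] = []
    for gi in range(n_genes):
        pos = int(rng.integers(0, tss_hi))
        strand = "+" if rng.random() < 0.5 else "-"
        tss.append(TSS(gene_chrom[gi], pos, strand, f"g{gi:04d}"))

    enhancers: list[GenomicInterval] = []
    placed: dict = {c: [] for c in chrom_names}
    for ei in range(n_enhancers):
        chrom = enh_chrom[ei]
        for _ in range(max_tries):
            start = int(rng.integers(enh_lo, enh_hi + 1))
            end = start + enhancer_len
            if all(end + enhancer_gap <= s or e + enhancer_gap <= start
                   for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                enhancers.append(GenomicInterval(chrom, start, end, f"E{ei:04d}"))
                break
        else:
            raise PlacementError(
                f"could not place enhancer {ei} on {chrom} after {max_tries} tries "
                f"(non-overlap with gap {enhancer_gap} bp in [{enh_lo}, {enh_hi}])"
            )

    cpg_positions = {}
    for iv in enhancers:
        pos = rng.choice(np.arange(iv.start, iv.end - 1), size=cpg_density, replace=False)
        cpg_positions[iv.name] = np.sort(pos)

    # each enhancer linked to >=1 gene, preferring genes on the same chromosome
    genes_by_chrom: dict = {}
    for t in tss:
        genes_by_chrom.setdefault(t.chrom, []).append(t.gene_id)
    counters: dict = {c: 0 for c in chrom_names}
    atlas = []
    for iv in enhancers:
        pool = genes_by_chrom.get(iv.chrom) or [t.gene_id for t in tss]
        gene = pool[counters[iv.chrom] % len(pool)]
        counters[iv.chrom] += 1
        atlas.append((iv, gene))

    ann = GenomeAnnotation(chrom_sizes, enhancers, cpg_positions, tss, atlas)
    ann.validate(min_tss_distance=min_tss_distance)
    return ann


def make_population(
    annotation: GenomeAnnotation,
    config: StateConfig,
    n_cells: int,
    seed: int = 0,
) -> PopulationModel:
    """Draw one chromatin state per (cell, enhancer), iid from the mixture."""
    config.validate()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    fracs = np.array([config.state_fractions[s] for s in config.states])
    states = rng.choice(len(fracs), size=(n_cells, len(annotation.enhancers)),
                        p=fracs).astype(np.int8)
    return PopulationModel(annotation, config, states, seed)


def expected_pulldown_methylation(
    config: StateConfig, mark: str, err: ErrorModel | None = None
) -> float:
    """Mixture-law expectation of the per-CpG 5mC fraction in a pull-down.

    Sum over states of P(state | mark present) * meth_prob(state), optionally
    pushed through the error model.
    """
    weights = np.array([config.state_fractions[s] * config.presence(s, mark)
                        for s in config.states])
    if weights.sum() <= 0:
        raise ValueError(f"mark {mark} never present in any populated state")
    probs = np.array([config.meth_prob[s] for s in config.states])
    m = float(weights @ probs / weights.sum())
    if err is not None:
        m = m * (1.0 - err.inappropriate_conv_rate) + (1.0 - m) * err.conv_fail_rate
    return m


def simulate_chip_bs(
    pop: PopulationModel,
    mark: str,
    depth: int,
    read_len: int = 200,
    err: ErrorModel | None = None,
    seed: int = 0,
    *,
    return_accounting: bool = False,
):
    """Emit per-read CpG call records for one chromatin pull-down.

    For each mark-carrying enhancer, ``depth`` reads are produced. Each read
    (i) rejection-samples a cell until one whose state carries the mark is
    accepted, (ii) places a ``read_len`` window uniformly among all windows
    overlapping the enhancer, and (iii) draws one allele methylation state
    for the whole read, Bernoulli(meth_prob[state]), shared by all its CpGs
    (methyltransferases act processively at nucleosome scale, so CpGs on one
    allele agree), then flips each covered CpG independently through the
    error model — discordant ("mixed") reads therefore arise only from
    simulated technical error. Cells whose state lacks the mark never
    contribute reads.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    err = err or ErrorModel()
    config = pop.config
    ann = pop.annotation
    rng = np.random.default_rng(seed)

    presence = np.array([config.presence(s, mark) for s in config.states])
    if not any(presence[code] > 0 and config.state_fractions[config.states[code]] > 0
               for code in range(len(presence))):
        raise ValueError(f"no precipitable material: mark {mark} absent from every state")

    meth = np.array([config.meth_prob[s] for s in config.states])
    records: list[ReadMethRecord] = []
    accounting = {"mark": mark, "depth": depth, "n_emitted": 0,
                  "n_attempted_cells": 0, "skipped_enhancers": []}

    for j, enh in enumerate(ann.enhancers):
        p_cell = presence[pop.states[:, j]]
        if p_cell.max() <= 0:
            accounting["skipped_enhancers"].append(enh.name)
            continue
        accepted: list[int] = []
        attempts = 0
        while len(accepted) < depth:
            need = depth - len(accepted)
            batch = max(16, int(need / max(p_cell.mean(), 1e-6)) + 8)
            cand = rng.integers(0, pop.n_cells, batch)
            keep = cand[rng.random(batch) < p_cell[cand]]
            accepted.extend(keep.tolist())
            attempts += batch
            if attempts > 1000 * depth + 100_000:
                raise RuntimeError(
                    f"rejection sampling stalled for {enh.name} under {mark}"
                )
        cells = np.array(accepted[:depth])
        accounting["n_attempted_cells"] += attempts

        chrom_len = ann.chrom_sizes[enh.chrom]
        lo = max(0, enh.start - read_len + 1)
        hi = min(chrom_len - read_len, enh.end - 1)
        starts = rng.integers(lo, hi + 1, depth)
        cpgs = ann.cpg_positions[enh.name]
        cover = (starts[:, None] <= cpgs[None, :]) & (cpgs[None, :] < starts[:, None] + read_len)
        mp = meth[pop.states[cells, j]]
        allele_m = rng.random(depth) < mp  # one allele state per read
        true_m = np.broadcast_to(allele_m[:, None], (depth, len(cpgs)))
        u = rng.random((depth, len(cpgs)))
        observed = np.where(true_m, u >= err.inappropriate_conv_rate, u < err.conv_fail_rate)

        for i in range(depth):
            rid = f"{mark}:{enh.name}:{i:05d}"
            start = int(starts[i])
            idx = np.flatnonzero(cover[i])
            calls = [CpGCall(enh.chrom, int(cpgs[k]), bool(observed[i, k]), rid) for k in idx]
            records.append(ReadMethRecord(rid, enh.chrom, start, start + read_len, calls))
        accounting["n_emitted"] += depth

    logger.info(
        "simulate_chip_bs(%s): emitted %d reads over %d enhancers "
        "(%d cell draws attempted, %d enhancers skipped)",
        mark, accounting["n_emitted"],
        len(ann.enhancers) - len(accounting["skipped_enhancers"]),
        accounting["n_attempted_cells"], len(accounting["skipped_enhancers"]),
    )
    if return_accounting:
        return records, accounting
    return records


def simulate_spikein(
    template: str = SPIKE_IN_TEMPLATE,
    meth_positions: Sequence[int] | None = None,
    n_reads: int = 10_000,
    err: ErrorModel | None = None,
    seed: int = 0,
    *,
    name: str = "spikein",
):
    """Simulate full-length reads of a spike-in oligonucleotide.

    ``meth_positions`` (default: the template's CpG cytosines) are truly
    methylated; every other cytosine is truly unmethylated. Returns
    ``(calls, truth)`` where truth maps ``(name, offset)`` to the true state,
    ready for :func:`dmescan.methcalls.spikein_accuracy`. Pool calls/truth
    from the template and its reverse complement to exercise both classes of
    a primer-extended amplicon.
    """
    err = err or ErrorModel()
    c_offsets = cytosine_offsets(template)
    if meth_positions is None:
        meth_positions = cpg_offsets(template)
    meth_set = set(int(p) for p in meth_positions)
    bad = meth_set - set(c_offsets)
    if bad:
        raise ValueError(f"meth_positions not at cytosines: {sorted(bad)}")
    truth = {(name, off): (off in meth_set) for off in c_offsets}
    if n_reads == 0:
        return [], truth
    rng = np.random.default_rng(seed)
    true_m = np.array([off in meth_set for off in c_offsets])
    u = rng.random((n_reads, len(c_offsets)))
    observed = np.where(true_m[None, :], u >= err.inappropriate_conv_rate,
                        u < err.conv_fail_rate)
    calls = [
        CpGCall(name, off, bool(observed[i, k]), f"{name}:r{i:05d}")
        for i in range(n_reads)
        for k, off in enumerate(c_offsets)
    ]
    return calls, truth


def simulate_expression(
    pop: PopulationModel,
    base_rate: float = 1.0,
    active_boost: float = 1.0,
    n_umis_per_cell: int = 12_000,
    seed: int = 0,
):
    """Gene x cell UMI counts coupled to enhancer state.

    A gene's sampling rate is multiplied by ``active_boost`` in each cell
    where at least one atlas-linked enhancer is in the active state; genes
    without atlas links keep the base rate everywhere. Per-cell counts are
    multinomial with ``n_umis_per_cell`` draws.
    """
    import pandas as pd

    if base_rate <= 0 or active_boost <= 0:
        raise ValueError("base_rate and active_boost must be positive")
    ann = pop.annotation
    genes = ann.genes
    gene_enh = ann.gene_to_enhancers()
    active_code = pop.config.states.index(ACTIVE) if ACTIVE in pop.config.states else None

    rates = np.full((len(genes), pop.n_cells), float(base_rate))
    if active_code is not None and active_boost != 1.0:
        active = pop.states == active_code  # (cells, enhancers)
        for gi, gene in enumerate(genes):
            idx = gene_enh.get(gene)
            if idx:
                boosted = active[:, idx].any(axis=1)
                rates[gi, boosted] *= active_boost

    rng = np.random.default_rng(seed)
    counts = np.empty_like(rates, dtype=np.int64)
    for c in range(pop.n_cells):
        p = rates[:, c] / rates[:, c].sum()
        counts[:, c] = rng.multinomial(n_umis_per_cell, p)
    return pd.DataFrame(counts, index=genes, columns=pop.cell_ids)
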