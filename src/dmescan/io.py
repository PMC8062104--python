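"""Writers for simulator output in the field's plain-text formats.

The simulator publishes its datasets the way a real pipeline would receive
them: Bismark-extractor-style CpG call files, BED6 for enhancer peaks and
TSSs, a tab-separated enhancer-to-gene atlas, counts as TSV or MatrixMarket,
and a truth JSON holding state assignments and the mixture-law expected
methylation per enhancer and mark.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np

from .methcalls import ReadMethRecord
from .simpop import (
    MARKS,
    ErrorModel,
    GenomicInterval,
    PopulationModel,
    TSS,
    expected_pulldown_methylation,
)


def write_extractor_file(records: Sequence[ReadMethRecord], path) -> None:
    """Bismark-extractor format: read_id, strand, chrom, 1-based pos, Z/z.

    Reads without CpG calls produce no lines (as in real extractor output).
    """
    with open(path, "w") as fh:
        for rec in records:
            for c in rec.calls:
                symbol = "Z" if c.methylated else "z"
                fh.write(f"{c.read_id}\t+\t{c.chrom}\t{c.pos + 1}\t{symbol}\n")


def write_bed6(intervals: Sequence[GenomicInterval], path, strand: str = ".") -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{strand}\n")


def write_tss_bed(tss: Sequence[TSS], path) -> None:
    with open(path, "w") as fh:
        for t in sorted(tss):
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\t{t.gene_id}\t0\t{t.strand}\n")


def write_atlas(atlas: Sequence, path) -> None:
    """Tab-separated enhancer-to-gene links: chrom, start, end, gene_id."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tgene_id\n")
        for iv, gene in atlas:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{gene}\n")


def write_counts_tsv(counts, path) -> None:
    counts.to_csv(path, sep="\t")


def write_counts_mtx(counts, prefix) -> None:
    """MatrixMarket triple: <prefix>.mtx, <prefix>.genes.txt, <prefix>.cells.txt."""
    from scipy import io as spio
    from scipy import sparse

    spio.mmwrite(f"{prefix}.mtx", sparse.csr_matrix(counts.to_numpy()))
    with open(f"{prefix}.genes.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.index)) + "\n")
    with open(f"{prefix}.cells.txt", "w") as fh:
        fh.write("\n".join(map(str, counts.columns)) + "\n")


def write_truth_json(pop: PopulationModel, err: ErrorModel, path) -> None:
    """Ground truth: per-cell state codes and expected 5mC per enhancer per mark."""
    ann = pop.annotation
    config = pop.config
    per_enh = {}
    for j, enh in enumerate(ann.enhancers):
        expected = {}
        for mark in MARKS:
            weights = np.array(
                [pop.state_fraction(j, s) * config.presence(s, mark) for s in config.states]
            )
            if weights.sum() <= 0:
                expected[mark] = None
                continue
            probs = np.array([config.meth_prob[s] for s in config.states])
            m = float(weights @ probs / weights.sum())
            expected[mark] = m * (1 - err.inappropriate_conv_rate) + (1 - m) * err.conv_fail_rate
        per_enh[enh.name] = {
            "state_fractions": {s: pop.state_fraction(j, s) for s in config.states},
            "expected_5mc": expected,
        }
    payload = {
        "seed": pop.seed,
        "states": list(config.states),
        "config": {
            "state_fractions": dict(config.state_fractions),
            "meth_prob": dict(config.meth_prob),
            "mark_presence": {f"{s}|{m}": p for (s, m), p in config.mark_presence.items()},
        },
        "error_model": {
            "conv_fail_rate": err.conv_fail_rate,
            "inappropriate_conv_rate": err.inappropriate_conv_rate,
        },
        "mixture_expected_5mc": {
            mark: _safe_expected(config, mark, err) for mark in MARKS
        },
        "enhancers": per_enh,
        "cell_states": ["".join(str(int(s)) for s in row) for row in pop.states],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def _safe_expected(config, mark, err):
    try:
        return expected_pulldown_methylation(config, mark, err)
    except ValueError:
        return None
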