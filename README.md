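# dmescan

Sequential ChIP-bisulfite (ChIP-BS-seq) analysis of enhancer DNA methylation:
from per-read CpG methylation calls under two enhancer histone marks to
**differentially methylated enhancers (DMEs)**, UMR/LMR state dynamics,
enhancer-to-gene projection, single-cell expression comparisons and TSS
methylation profiles — together with a synthetic cell-population simulator
that makes every stage testable without sequencing data.

## The problem

Bulk bisulfite sequencing averages methylation over cells, so an enhancer
reported at an intermediate ("low-methylated region", LMR, 20–80% 5mC) level
is ambiguous: either every cell is partially methylated there, or the
population mixes cells in different chromatin states. Sequential ChIP-BS-seq
resolves this by measuring methylation only on DNA co-precipitated with a
chosen histone mark. At a given enhancer:

* cells where the enhancer is **active** carry H3K4me1 *and* H3K27ac on
  essentially unmethylated DNA;
* cells where it is being **decommissioned** retain H3K4me1 only, and the DNA
  gains CpG methylation;
* **silent** cells carry neither mark and are never precipitated.

Pulling down the same locus with the two antibodies therefore samples
*different subsets of cells*. If a fraction *f* of cells is decommissioned
(per-CpG methylation *m*<sub>d</sub>) and the rest active (*m*<sub>a</sub>),
the expected 5mC level is a mixture over the states compatible with the mark:

* H3K4me1 pull-down (both states): 𝔼[5mC] = *f·m*<sub>d</sub> + (1−*f*)·*m*<sub>a</sub>
* H3K27ac pull-down (active only): 𝔼[5mC] = *m*<sub>a</sub>

With *f* = 0.5, *m*<sub>d</sub> = 0.8, *m*<sub>a</sub> = 0.02 this gives 41%
vs 2% — a **39-percentage-point** difference at the *same genomic position*,
explainable only by cellular heterogeneity. `dmescan` calls a 200-bp bin a
DME when the two pull-downs differ by ≥ 20 points (a threshold that clears
the 2–5% bisulfite error rate measured by a spike-in control), with the
direction (`K4me1_high` vs `K27ac_high`) carrying the biology.

## Pipeline stages

| module       | role |
|--------------|------|
| `simpop`     | synthetic genome, per-cell enhancer-state mixture, mark-conditional read pull-down, spike-in reads, state-coupled UMI counts |
| `methcalls`  | Bismark-extractor parsing; read classification (C / 5mC / mixed / non-CpG); mixed-read filtering; spike-in accuracy |
| `genomebins` | 200-bp binning; ≥ 30-call coverage and ≥ 10-kb TSS-distance filters; bedGraph/BED I/O |
| `enhancers`  | peak intersection, UMR/LMR/HMR states, DME calling, map correlations, UMR↔LMR transitions, X-vs-autosome distribution |
| `genelink`   | cis-regulatory-atlas projection of DMEs to genes; hypergeometric set overlaps |
| `expression` | cell filtering (> 10,000 UMIs), LogNormalize, variable genes, DME-gene vs control comparisons |
| `tssprofiles`| strand-oriented composite 5mC/C profiles around TSSs; expression-ordered heatmaps and methylation-vs-expression curves |

## Worked example

```python
import numpy as np
from dmescan import simpop, methcalls, genomebins, enhancers, genelink

ann = simpop.make_annotation(n_chrom=2, chrom_len=600_000, n_enhancers=50, n_genes=50, seed=1)
config = simpop.StateConfig.two_state(0.5)          # 50% active, 50% decommissioned
pop = simpop.make_population(ann, config, n_cells=2000, seed=2)
err = simpop.ErrorModel()                           # 2% conversion error, both directions

bins = {}
for i, mark in enumerate(simpop.MARKS):
    reads = simpop.simulate_chip_bs(pop, mark, depth=200, err=err, seed=3 + i)
    kept, counts = methcalls.filter_mixed(reads)
    print(f"{mark}: {counts.total} reads, {counts.fraction('mixed'):.1%} mixed")
    bins[mark] = genomebins.filter_bins(genomebins.bin_calls(kept), tss=ann.tss)

pairs = enhancers.pair_bins(bins["H3K4me1"], bins["H3K27ac"])
dmes = enhancers.call_dmes(pairs, min_diff=20.0)
counts = enhancers.dme_direction_counts(dmes)
print(f"{len(pairs)} dual-covered bins, {len(dmes)} DMEs "
      f"({counts['K4me1_high']} K4me1_high, {counts['K27ac_high']} K27ac_high)")
print(f"mean methylation difference: {np.mean([d.delta for d in dmes]):.1f} points")

atlas = genelink.GeneLinkTable(list(ann.atlas))
print(f"{len(genelink.map_dmes_to_genes(dmes, atlas))} genes linked to DMEs")
```

prints

```
H3K4me1: 10000 reads, 3.3% mixed
H3K27ac: 10000 reads, 3.3% mixed
166 dual-covered bins, 165 DMEs (165 K4me1_high, 0 K27ac_high)
mean methylation difference: 38.2 points
50 genes linked to DMEs
```

Reading it: ~3% of reads have internally discordant CpGs (pure technical
error at the simulated 2% flip rate) and are removed; essentially every bin
covered under both marks is a `K4me1_high` DME; and the recovered difference
(38.2 points) matches the analytic 39-point mixture expectation attenuated by
residual conversion error on single-CpG reads. The same analysis of a
homogeneous population calls < 1% of bins.

A shell-level run of the whole pipeline is available through the `dmescan`
console script (`simulate`, `calls`, `bin`, `dme`, `genes`, `expr`, `tss`);
see `dmescan --help`.

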