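# Methods

## Generative model

The simulator (`simpop`) encodes the chromatin-heterogeneity model that the
analysis is built to detect. A synthetic genome consists of chromosomes with
a gene-dense compartment (the first 30% of each chromosome, holding all
TSSs) and a distal compartment holding non-overlapping enhancers placed at
least `min_tss_distance` (default 10 kb) beyond it, so every enhancer is
distal to every TSS by construction. Each enhancer carries a fixed set of
CpG positions (default 8 in 600 bp — enhancers are CpG-poor, so coverage is
concentrated on few positions). Coordinates are 0-based half-open
throughout; a CpG is identified by its plus-strand C position, with both
strands of the symmetric dinucleotide collapsed onto it.

Each (cell, enhancer) pair independently takes one of three states:

| state          | marks               | per-CpG 5mC | default fraction |
|----------------|---------------------|-------------|------------------|
| active         | H3K4me1 + H3K27ac   | 0.02        | 0.50             |
| decommissioned | H3K4me1 only        | 0.80        | 0.30             |
| silent         | none                | 0.85        | 0.20             |

The state fractions are free parameters of the model, not estimates from
data: published work establishes the *existence* of the mixture, not its
composition. The defaults give a clearly heterogeneous population; analyses
that need a specific mixture (e.g. the half/half two-state population used
in the recovery tests) set it explicitly via `StateConfig.two_state`.
Mark presence is deterministic per state by default (probabilistic presence
is supported through `mark_presence`), matching the subpopulation picture in
which a cell either carries the mark at a locus or does not.

A pull-down for mark *M* emits, per mark-carrying enhancer, `depth` reads.
Each read rejection-samples cells until one whose state carries *M* is
accepted (the accounting — attempts, emitted reads, skipped enhancers — is
returned on request and logged). The read is a single-ended 200-bp window
placed uniformly among all windows overlapping the enhancer. One allele
methylation state is drawn per read, Bernoulli(meth\_prob[state]), and shared
by all CpGs on the read: methyltransferases act processively at nucleosome
scale, so discordant CpGs on a 200-bp fragment are treated as technical
artifacts, not biology. Each covered CpG call is then flipped independently
by the error model (conversion failure: unmethylated read as methylated;
inappropriate conversion: the reverse; both default 0.02, inside the 2–5%
range a spike-in control certifies). Under this model the "mixed" read
fraction is purely error-driven and comes out near 3–4% at the defaults.

Spike-in reads cover the full template; the template's CpG cytosines are
truly methylated and all other cytosines truly unmethylated. The printed
spike-in sequence has only two plus-strand cytosines (both CpG), so the
unmethylated class is exercised on the reverse complement, whose
primer-derived cytosines are unmodified — mirroring how the physical
amplicon is built (methylated dCTP in the central region, unmodified primers).

Expression counts are multinomial per cell (`n_umis_per_cell` draws, default
12,000 so cells pass the strict >10,000-UMI filter). A gene's rate is
multiplied by `active_boost` in cells where at least one atlas-linked
enhancer is active; genes without atlas links keep the base rate, providing
the unlinked background that gene-set comparisons contrast against.

## Analysis choices

**Read classification.** A read is `mixed` if *any* two of its CpGs
disagree (for any discordant read this is equivalent to the adjacent-pair
phrasing). Mixed reads are removed before all methylation summaries;
`non_cpg` reads are kept for class accounting only. Percentages are
reported at 0.1% precision; internal comparisons use unrounded values.

**Binning.** Fixed 200-bp bins (the nucleosomal DNA unit). CpG calls are
assigned by their own position; a read's class increments the single bin
containing its midpoint (a read can therefore contribute calls to two bins
but its read-level count to one). The coverage filter defaults to ≥ 30
total CpG call observations per bin — a distinct-position reading of the
threshold is nearly unsatisfiable in CpG-poor enhancers, but is available
via `use_distinct_positions`. TSS distance is measured from the nearest bin
edge to the TSS point and ties at exactly the threshold are kept.

**DME calling.** Both marks must pass the coverage filter at a bin
("dual coverage"); the difference is in absolute percentage points and the
threshold (default 20) is inclusive. Per-bin methylation is call-weighted
(read-weighted counts are carried alongside for correlation analyses). No
multiple-testing correction is applied: the threshold itself is the error
control, set several-fold above the spike-in-certified error rate.

**States and transitions.** UMR < 20% ≤ LMR ≤ 80% < HMR. Transition
calling between two conditions uses a stricter gain criterion: a bin
becomes LMR only above `shift_min` (default 30%), so bins landing in the
20–30% dead zone are tallied as indeterminate rather than forced into a
state. Both thresholds are configurable.

**Correlations.** Map correlations are computed on log2(count+1) over the
intersection of covered bins, and both Pearson and Spearman matrices are
reported (accounts of the method differ on which is used; computing both
costs nothing).

**Gene linkage and overlaps.** A gene is hit when a DME bin overlaps any of
its atlas intervals (`max_gap` padding available, default 0). The
hypergeometric overlap test requires an explicit universe from the caller
and records it; there is no defensible implicit default.

**Expression.** LogNormalize uses the natural log (the convention of the
single-cell ecosystem the recipe comes from); the base is configurable and
recorded. Dispersion for variable-gene selection is variance/mean of
expm1-back-transformed values, z-scored within 20 equal-frequency
mean-expression bins. Group comparisons use Welch's unequal-variance
t-test on per-gene means, with a seeded, size-matched random control set.

**TSS profiles.** Reads are assigned by midpoint to every TSS window that
contains them, oriented by TSS strand (an unstranded mode exists).
Counts are normalized per million classified (methylated + unmethylated)
reads. The ±1.5-kb promoter core — where active nucleosomes keep DNA
unmethylated — is masked by default only in the methylation-vs-expression
curve, and the mask is configurable.

## Verification strategy and problem sizes

The test suite checks each operation against an independent oracle:
brute-force per-position scans for binning, exhaustive enumeration of all
C(N, n) draws for the hypergeometric test (universes ≤ 20), quadratic scans
for interval intersection, closed-form mixture expectations for pull-down
methylation, and binomial/permutation nulls for stochastic quantities
(always at 3 standard errors with seeded generators).

End-to-end properties run at deliberately modest scale — e.g. 50 enhancers ×
2,000 cells × 200 reads/enhancer for mixture recovery, 200 enhancers at
depth 100 for null calibration, 200 simulation repeats for the type-I-error
check, 10,000 reads for spike-in accuracy — sizes at which the asserted
effects are separated from their nulls by wide margins while the full suite
runs in seconds. The mixed-read filter slightly *sharpens* recovered
differences (it removes error-discordant multi-CpG reads), so the recovery
test compares against an exact conditional expectation: for a read with k
CpGs, P(kept & methylated) = q(1−e\_i)^k + (1−q)e\_f^k and
P(kept & unmethylated) = q·e\_i^k + (1−q)(1−e\_f)^k, weighted by the
observed k distribution.

## What the simulator does and does not emulate

It emulates: mixture-of-states heterogeneity at enhancers, mark-conditional
sampling of cells, CpG sparsity, symmetric bisulfite call errors, spike-in
controls, state-coupled expression, and multi-chromosome layouts (including
an X chromosome for the allelic-asymmetry negative control — the simulator
has no allelic effects, so the X must behave like an autosome).

It does not emulate: sequence-level reads (bases/qualities), alignment or
mapping bias, PCR duplicates, paired-end fragments, copy-number or allelic
asymmetry, chromatin-state correlation between neighbouring enhancers, or
realistic genome-wide CpG landscapes. Passing tests therefore certify the
*analysis logic* under the stated model — they do not certify robustness to
alignment artifacts or to biological correlation structures the model
omits.

## Known limitations

* Enhancer placement uses a compartmentalized layout (genes left, enhancers
  right); distances between enhancers and *their own* target TSSs are not
  calibrated to real enhancer–promoter distance distributions.
* DME calling has no per-bin significance model; bins barely passing the
  coverage floor have ~10-point sampling noise and rely on the 20-point
  threshold for specificity.
* `group_expression_compare` treats genes as exchangeable units; multinomial
  coupling between genes within a cell is ignored (negligible at the gene
  counts used, but real for very small panels).
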