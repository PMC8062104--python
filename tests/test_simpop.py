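"""Simulator: placement constraints, mixture law, spike-in and expression coupling."""

import math

import numpy as np
import pytest

from dmescan import simpop
from dmescan.methcalls import percent_5mc
from dmescan.simpop import (
    ACTIVE,
    DECOMMISSIONED,
    H3K27AC,
    H3K4ME1,
    ErrorModel,
    PlacementError,
    SPIKE_IN_TEMPLATE,
    StateConfig,
    cpg_offsets,
    cytosine_offsets,
    expected_pulldown_methylation,
    make_annotation,
    make_population,
    reverse_complement,
    simulate_chip_bs,
    simulate_expression,
    simulate_spikein,
)

NO_ERROR = ErrorModel(0.0, 0.0)


class TestAnnotation:
    def test_enhancers_distal_to_every_tss(self):
        ann = make_annotation(1, 1_000_000, 10, 10, min_tss_distance=10_000,
                              cpg_density=8, seed=1)
        for iv in ann.enhancers:
            for t in ann.tss:
                if t.chrom == iv.chrom:
                    d = min(abs(t.pos - iv.start), abs(t.pos - (iv.end - 1)))
                    assert d >= 10_000

    def test_deterministic_for_fixed_seed(self):
        a = make_annotation(2, 400_000, 12, 12, seed=5)
        b = make_annotation(2, 400_000, 12, 12, seed=5)
        assert a.enhancers == b.enhancers
        assert a.tss == b.tss
        assert all(np.array_equal(a.cpg_positions[k], b.cpg_positions[k])
                   for k in a.cpg_positions)

    def test_infeasible_distance_raises(self):
        with pytest.raises(PlacementError):
            make_annotation(1, 100_000, 5, 5, min_tss_distance=200_000, seed=1)

    def test_every_enhancer_linked_to_a_gene(self, small_annotation):
        linked = {iv.name for iv, _ in small_annotation.atlas}
        assert linked == {e.name for e in small_annotation.enhancers}

    def test_fixed_cpg_set_per_enhancer(self, small_annotation):
        for iv in small_annotation.enhancers:
            pos = small_annotation.cpg_positions[iv.name]
            assert len(pos) == 8
            assert ((pos >= iv.start) & (pos < iv.end)).all()


class TestPopulation:
    def test_degenerate_mixture_is_uniform(self, small_annotation):
        cfg = StateConfig.two_state(1.0)
        pop = make_population(small_annotation, cfg, 50, seed=3)
        assert (pop.states == cfg.states.index(ACTIVE)).all()

    def test_fractions_converge_binomially(self, small_annotation):
        # binomial oracle: SE of the active fraction at n=10000 is 0.005
        cfg = StateConfig.two_state(0.5)
        pop = make_population(small_annotation, cfg, 10_000, seed=4)
        for j in range(len(small_annotation.enhancers)):
            assert abs(pop.state_fraction(j, ACTIVE) - 0.5) < 0.02

    def test_deterministic(self, small_annotation, two_state_config):
        p1 = make_population(small_annotation, two_state_config, 100, seed=9)
        p2 = make_population(small_annotation, two_state_config, 100, seed=9)
        assert np.array_equal(p1.states, p2.states)

    def test_zero_cells_rejected(self, small_annotation, two_state_config):
        with pytest.raises(ValueError):
            make_population(small_annotation, two_state_config, 0)

    def test_invalid_fractions_rejected(self, small_annotation):
        bad = StateConfig({ACTIVE: 0.6, DECOMMISSIONED: 0.6},
                          {(ACTIVE, H3K4ME1): 1.0}, {ACTIVE: 0.0, DECOMMISSIONED: 0.5})
        with pytest.raises(ValueError, match="sum"):
            make_population(small_annotation, bad, 10)


class TestChipBS:
    def test_mixture_law_h3k4me1(self, two_state_config):
        # analytic: 0.5*0.8 + 0.5*0.02 = 41% before error; checked at high depth
        ann = make_annotation(1, 200_000, 2, 4, seed=21)
        pop = make_population(ann, two_state_config, 4000, seed=22)
        records = simulate_chip_bs(pop, H3K4ME1, depth=10_000, err=NO_ERROR, seed=23)
        calls = [c for r in records for c in r.calls]
        observed = percent_5mc(calls) / 100
        n_reads = sum(1 for r in records if r.calls)
        se = math.sqrt(0.41 * 0.59 / n_reads)  # read-level units: calls share an allele
        assert abs(observed - 0.41) < 3 * se

    def test_mixture_law_h3k27ac(self, two_state_config):
        ann = make_annotation(1, 200_000, 2, 4, seed=21)
        pop = make_population(ann, two_state_config, 4000, seed=22)
        records = simulate_chip_bs(pop, H3K27AC, depth=10_000, err=NO_ERROR, seed=24)
        observed = percent_5mc([c for r in records for c in r.calls]) / 100
        n_reads = sum(1 for r in records if r.calls)
        assert abs(observed - 0.02) < 3 * math.sqrt(0.02 * 0.98 / n_reads)

    def test_expected_pulldown_methylation_closed_form(self, two_state_config):
        assert expected_pulldown_methylation(two_state_config, H3K4ME1) == pytest.approx(0.41)
        assert expected_pulldown_methylation(two_state_config, H3K27AC) == pytest.approx(0.02)
        adj = expected_pulldown_methylation(two_state_config, H3K4ME1, ErrorModel())
        assert adj == pytest.approx(0.41 * 0.96 + 0.02)

    def test_zero_meth_zero_error_all_unmethylated(self, small_annotation):
        cfg = StateConfig.two_state(1.0, meth_active=0.0)
        pop = make_population(small_annotation, cfg, 100, seed=30)
        records = simulate_chip_bs(pop, H3K4ME1, depth=5, err=NO_ERROR, seed=31)
        assert all(not c.methylated for r in records for c in r.calls)

    def test_mark_absent_everywhere_errors(self, small_annotation):
        cfg = StateConfig(
            {DECOMMISSIONED: 1.0}, {(DECOMMISSIONED, H3K4ME1): 1.0}, {DECOMMISSIONED: 0.8}
        )
        pop = make_population(small_annotation, cfg, 20, seed=32)
        with pytest.raises(ValueError, match="no precipitable material"):
            simulate_chip_bs(pop, H3K27AC, depth=5, seed=33)

    def test_read_count_conservation(self, het_population):
        records, acct = simulate_chip_bs(
            het_population, H3K4ME1, depth=7, err=NO_ERROR, seed=34, return_accounting=True
        )
        n_carrying = len(het_population.annotation.enhancers) - len(acct["skipped_enhancers"])
        assert len(records) == acct["n_emitted"] == 7 * n_carrying
        assert acct["n_attempted_cells"] >= acct["n_emitted"]

    def test_deterministic(self, het_population):
        r1 = simulate_chip_bs(het_population, H3K27AC, depth=3, seed=35)
        r2 = simulate_chip_bs(het_population, H3K27AC, depth=3, seed=35)
        assert [(r.read_id, r.start, [(c.pos, c.methylated) for c in r.calls]) for r in r1] == \
               [(r.read_id, r.start, [(c.pos, c.methylated) for c in r.calls]) for r in r2]

    def test_reads_overlap_an_enhancer(self, chip_records, small_annotation):
        enh_by_chrom = {}
        for iv in small_annotation.enhancers:
            enh_by_chrom.setdefault(iv.chrom, []).append(iv)
        for rec in chip_records[H3K4ME1][:500]:
            assert rec.end - rec.start == 200
            assert any(rec.start < iv.end and iv.start < rec.end
                       for iv in enh_by_chrom[rec.chrom])


class TestSpikeIn:
    def test_template_cytosines_all_cpg(self):
        assert cytosine_offsets(SPIKE_IN_TEMPLATE) == cpg_offsets(SPIKE_IN_TEMPLATE) == [29, 54]

    def test_no_error_perfect_truth(self):
        calls, truth = simulate_spikein(n_reads=50, err=NO_ERROR, seed=40)
        for c in calls:
            assert c.methylated == truth[(c.chrom, c.pos)]

    def test_reverse_complement_has_unmethylated_cytosines(self):
        rc = reverse_complement(SPIKE_IN_TEMPLATE)
        assert len(cytosine_offsets(rc)) > len(cpg_offsets(rc)) >= 2

    def test_zero_reads_empty_output(self):
        calls, truth = simulate_spikein(n_reads=0, seed=41)
        assert calls == [] and len(truth) == 2

    def test_non_cytosine_position_rejected(self):
        with pytest.raises(ValueError, match="not at cytosines"):
            simulate_spikein(meth_positions=[0], n_reads=1)  # offset 0 is G

    def test_error_rate_recovered(self):
        # with 2% flips in each direction, ~2% of calls disagree with truth
        calls, truth = simulate_spikein(n_reads=5000, err=ErrorModel(0.02, 0.02), seed=42)
        wrong = np.mean([c.methylated != truth[(c.chrom, c.pos)] for c in calls])
        assert abs(wrong - 0.02) < 3 * math.sqrt(0.02 * 0.98 / len(calls))


class TestExpression:
    def test_deterministic(self, het_population):
        m1 = simulate_expression(het_population, active_boost=2.0, n_umis_per_cell=500, seed=50)
        m2 = simulate_expression(het_population, active_boost=2.0, n_umis_per_cell=500, seed=50)
        assert m1.equals(m2)

    def test_cell_totals_are_exact(self, het_population):
        m = simulate_expression(het_population, n_umis_per_cell=700, seed=51)
        assert (m.sum(axis=0) == 700).all()

    def test_boost_raises_linked_gene_expression_in_active_cells(self, het_population):
        # group-mean oracle: mean counts over active vs non-active cells
        m = simulate_expression(het_population, active_boost=4.0,
                                n_umis_per_cell=5000, seed=52)
        ann = het_population.annotation
        gene, enh_idx = next(
            (g, idx[0]) for g, idx in ann.gene_to_enhancers().items() if idx
        )
        code = het_population.config.states.index(ACTIVE)
        active_cells = het_population.states[:, enh_idx] == code
        counts = m.loc[gene].to_numpy()
        assert counts[active_cells].mean() > 2 * counts[~active_cells].mean()

    def test_null_boost_leaves_genes_exchangeable(self, het_population):
        m = simulate_expression(het_population, active_boost=1.0,
                                n_umis_per_cell=2000, seed=53)
        means = m.mean(axis=1)
        # all genes share one rate; spread is multinomial noise only
        assert means.std() < 0.1 * means.mean()


def test_error_model_bounds():
    with pytest.raises(ValueError):
        ErrorModel(conv_fail_rate=0.7)
    with pytest.raises(ValueError):
        ErrorModel(inappropriate_conv_rate=-0.01)
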