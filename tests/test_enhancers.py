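"""Peak intersection, UMR/LMR states, DME calling and comparative summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmescan import enhancers as enh
from dmescan.genomebins import MethBin
from dmescan.simpop import GenomicInterval


def make_bin(chrom="chr1", start=0, meth=0, unmeth=0, reads_meth=0, reads_unmeth=0):
    return MethBin(chrom, start, n_meth=meth, n_unmeth=unmeth,
                   n_reads_meth=reads_meth, n_reads_unmeth=reads_unmeth)


def pair(pct_a, pct_b, chrom="chr1", start=0):
    return enh.EnhancerBinPair(chrom, start, pct_a, pct_b, 50, 50)


class TestIntersectPeaks:
    def test_partial_overlap_counts(self):
        b = make_bin(start=200, meth=1)
        ann = enh.intersect_peaks([b], [GenomicInterval("chr1", 350, 600, "p")])
        assert ann[b.key][0] is True

    def test_half_open_touch_is_not_overlap(self):
        b = make_bin(start=200, meth=1)
        ann = enh.intersect_peaks([b], [GenomicInterval("chr1", 400, 600, "p")])
        assert ann[b.key][0] is False

    def test_centered_peak_distance_zero(self):
        b = make_bin(start=1000, meth=1)  # midpoint 1100
        peak = GenomicInterval("chr1", 1100 - 1250, 1100 + 1250, "p")
        ann = enh.intersect_peaks([b], [peak])
        assert ann[b.key] == (True, 0)


class TestClassifyState:
    @pytest.mark.parametrize("pct, label", [(5, "UMR"), (45, "LMR"), (95, "HMR"),
                                            (20, "LMR"), (80, "LMR")])
    def test_standard_thresholds(self, pct, label):
        assert enh.classify_state(pct).label == label

    @given(st.floats(0, 100), st.floats(1, 50), st.floats(51, 99))
    def test_partition_complete_and_exclusive(self, pct, umr_max, lmr_max):
        state = enh.classify_state(pct, umr_max, lmr_max)
        expected = "UMR" if pct < umr_max else ("LMR" if pct <= lmr_max else "HMR")
        assert state.label == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            enh.classify_state(101)


class TestCallDmes:
    @pytest.mark.parametrize(
        "pct_a, pct_b, expected",
        [
            (55, 20, (enh.K4ME1_HIGH, 35)),
            (30, 15, None),
            (10, 40, (enh.K27AC_HIGH, -30)),
            (40, 20, (enh.K4ME1_HIGH, 20)),  # threshold inclusive
        ],
    )
    def test_examples(self, pct_a, pct_b, expected):
        dmes = enh.call_dmes([pair(pct_a, pct_b)])
        if expected is None:
            assert dmes == []
        else:
            direction, delta = expected
            assert dmes[0].direction == direction
            assert dmes[0].delta == pytest.approx(delta)

    def test_mark_swap_symmetry(self, rng):
        pairs = [pair(float(a), float(b), start=200 * i)
                 for i, (a, b) in enumerate(rng.uniform(0, 100, (100, 2)))]
        swapped = [enh.EnhancerBinPair(p.chrom, p.bin_start, p.pct_b, p.pct_a,
                                       p.n_calls_b, p.n_calls_a) for p in pairs]
        d1 = enh.call_dmes(pairs)
        d2 = enh.call_dmes(swapped)
        assert sorted(d.delta for d in d1) == sorted(-d.delta for d in d2)
        c1, c2 = enh.dme_direction_counts(d1), enh.dme_direction_counts(d2)
        assert c1[enh.K4ME1_HIGH] == c2[enh.K27AC_HIGH]
        assert c1[enh.K27AC_HIGH] == c2[enh.K4ME1_HIGH]


def series(values, start=0):
    idx = pd.MultiIndex.from_tuples(
        [("chr1", start + 200 * i) for i in range(len(values))],
        names=["chrom", "bin_start"],
    )
    return pd.Series(values, index=idx, dtype=float)


class TestCorrelateMaps:
    def test_self_correlation_unity(self, rng):
        s = series(rng.integers(0, 100, 50))
        res = enh.correlate_maps({"a": s, "b": s.copy()})
        assert res.pearson.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(np.diag(res.pearson), 1.0)

    def test_scalar_multiple_spearman_unity(self, rng):
        s = series(rng.integers(1, 100, 60))
        res = enh.correlate_maps({"a": s, "b": 3 * s})
        assert res.spearman.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_maps_near_zero(self, rng):
        # permutation null oracle: r distribution has sd ~ 1/sqrt(n-1)
        n = 400
        a, b = series(rng.integers(0, 50, n)), series(rng.integers(0, 50, n))
        res = enh.correlate_maps({"a": a, "b": b})
        assert abs(res.pearson.loc["a", "b"]) < 3 / np.sqrt(n - 1)

    def test_too_few_shared_bins(self):
        with pytest.raises(ValueError, match="shared bins"):
            enh.correlate_maps({"a": series([1, 2]), "b": series([3, 4])})

    def test_alignment_uses_intersection(self):
        res = enh.correlate_maps({"a": series(range(10)), "b": series(range(8))})
        assert res.n_bins == 8

    def test_bin_count_series_layers(self):
        b = make_bin(start=200, meth=1, reads_meth=4, reads_unmeth=9)
        assert enh.bin_count_series([b], "5mC").iloc[0] == 4
        assert enh.bin_count_series([b], "C").iloc[0] == 9


class TestStateTransitions:
    def bins(self, pcts, start=0):
        return [make_bin(start=start + 200 * i, meth=int(p), unmeth=100 - int(p))
                for i, p in enumerate(pcts)]

    @pytest.mark.parametrize(
        "p1, p2, transition",
        [(5, 50, "UMR->LMR"), (5, 10, "UMR->UMR"), (50, 15, "LMR->UMR"), (60, 70, "LMR->LMR")],
    )
    def test_transition_rules(self, p1, p2, transition):
        table = enh.state_transitions(self.bins([p1]), self.bins([p2]))
        assert table.counts[transition] == 1
        assert sum(table.counts.values()) == 1

    def test_dead_zone_is_indeterminate(self):
        table = enh.state_transitions(self.bins([5]), self.bins([25]))
        assert sum(table.counts.values()) == 0
        assert table.n_indeterminate == 1

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no bins"):
            enh.state_transitions(self.bins([5]), self.bins([5], start=10_000))

    def test_group_summaries_average_inputs(self):
        table = enh.state_transitions(self.bins([5, 10]), self.bins([50, 60]))
        row = table.summaries.loc["UMR->LMR"]
        assert row.pct_1 == pytest.approx(7.5)
        assert row.pct_2 == pytest.approx(55.0)


class TestChromDistribution:
    def make_dme(self, chrom, start=0):
        return enh.DMECall(chrom, start, 30.0, enh.K4ME1_HIGH)

    def test_concentrated_dmes(self):
        bins = [make_bin(chrom=c, start=0, meth=30) for c in ("chr1", "chr2", "chr3")]
        table, _ = enh.chrom_distribution([self.make_dme("chr1")], bins)
        fr = dict(zip(table.chrom, table.fraction))
        assert fr == {"chr1": 1.0, "chr2": 0.0, "chr3": 0.0}

    def test_empty_dme_set(self):
        bins = [make_bin(chrom="chr1", meth=30)]
        table, report = enh.chrom_distribution([], bins)
        assert (table.fraction == 0).all()
        assert report["x_fraction"] is None

    def test_x_report_fields(self):
        bins = [make_bin(chrom=c, start=200 * i, meth=30)
                for c in ("chr1", "chr2", "chrX") for i in range(10)]
        dmes = [self.make_dme(c, 200 * i) for c in ("chr1", "chr2", "chrX")
                for i in range(5)]
        _, report = enh.chrom_distribution(dmes, bins)
        assert report["x_fraction"] == pytest.approx(0.5)
        assert report["autosome_pooled_fraction"] == pytest.approx(0.5)
        assert abs(report["z_score"]) < 1e-9


class TestDmePeakContext:
    def test_no_dmes_empty_report(self):
        report = enh.dme_peak_context([], [], [])
        assert report["groups"] == {} and report["note"] == "no DMEs"

    def test_single_direction_comparison_skipped(self):
        dme = enh.DMECall("chr1", 200, 30.0, enh.K4ME1_HIGH)
        bins = [make_bin(start=200, meth=10, reads_meth=3, reads_unmeth=2)]
        peaks = [GenomicInterval("chr1", 0, 600, "p")]
        report = enh.dme_peak_context([dme], bins, peaks)
        assert report["comparison"] is None
        assert report["groups"][enh.K4ME1_HIGH]["n"] == 1
        assert report["groups"][enh.K4ME1_HIGH]["median_dist_to_center_b"] == 0.0

    def test_direction_distance_separation(self):
        # K4me1-high DMEs at peak centers, K27ac-high DMEs far away
        peaks = [GenomicInterval("chr1", 0, 600, "p")]
        near = [enh.DMECall("chr1", 200, 30.0, enh.K4ME1_HIGH)] * 5
        far = [enh.DMECall("chr1", 5000 + 200 * i, -30.0, enh.K27AC_HIGH) for i in range(5)]
        bins = [make_bin(start=200)] * 0
        report = enh.dme_peak_context(near + far, bins, peaks)
        g = report["groups"]
        assert g[enh.K4ME1_HIGH]["median_dist_to_center_b"] < \
            g[enh.K27AC_HIGH]["median_dist_to_center_b"]
        assert report["comparison"]["p_value"] < 0.05
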