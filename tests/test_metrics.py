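"""Evaluation statistics: diff-MAD, SNR, pseudo-counts, concordance, overlap test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from offcnv.coverage import make_bins
from offcnv.genome_io import GenomeLayout, IntervalSet
from offcnv.metrics import (
    ProbeSet,
    array_pseudocounts,
    mad_diff,
    random_placement_overlap,
    segment_concordance,
    signal_to_noise,
)
from offcnv.segment import Segment, SegmentSet


class TestMadDiff:
    def test_constant_and_ramp_are_zero(self):
        assert mad_diff(np.full(10, 3.0)) == 0.0
        assert mad_diff(np.arange(10.0)) == 0.0

    def test_hand_enumerated_example(self):
        # diffs of [0,2,1,4,2] are [2,-1,3,-2]; median 0.5; MAD of diffs 2
        got = mad_diff([0.0, 2.0, 1.0, 4.0, 2.0])
        assert got == pytest.approx(1.4826 * 2 / np.sqrt(2))

    def test_estimates_noise_sd(self):
        rng = np.random.default_rng(0)
        v = rng.normal(0, 0.3, 20_000)
        assert mad_diff(v) == pytest.approx(0.3, rel=0.05)

    def test_too_few_values_is_error(self):
        with pytest.raises(ValueError):
            mad_diff([1.0, 2.0])

    @given(
        st.lists(st.floats(-100, 100), min_size=4, max_size=30),
        st.floats(-50, 50),
        st.floats(0.1, 10),
    )
    def test_shift_invariant_scale_equivariant(self, values, shift, scale):
        v = np.asarray(values)
        base = mad_diff(v)
        assert mad_diff(v + shift) == pytest.approx(base, abs=1e-9)
        assert mad_diff(v * scale) == pytest.approx(base * scale, rel=1e-9)


class TestSignalToNoise:
    def _segs(self, mean, chrom="chr6", start=0, end=60_000_000):
        return SegmentSet([Segment(chrom, start, end, 100, mean)])

    @pytest.mark.parametrize(
        "mad,signal,expected",
        [(0.206, 0.722, 3.50), (0.479, -0.626, 1.31)],
    )
    def test_published_profile_arithmetic(self, mad, signal, expected):
        snr = signal_to_noise(self._segs(signal), mad, "chr6", 0, 60_000_000)
        assert round(snr, 2) == expected

    def test_zero_signal(self):
        assert signal_to_noise(self._segs(0.0), 0.5, "chr6", 0, 1000) == 0.0

    def test_largest_overlap_wins(self):
        segs = SegmentSet(
            [Segment("chr1", 0, 1000, 10, 0.2), Segment("chr1", 1000, 10_000, 90, 0.9)]
        )
        assert signal_to_noise(segs, 0.3, "chr1", 500, 5_000) == pytest.approx(0.9 / 0.3)

    def test_errors(self):
        with pytest.raises(ValueError):
            signal_to_noise(self._segs(1.0), 0.0, "chr6", 0, 1000)
        with pytest.raises(ValueError):
            signal_to_noise(self._segs(1.0), 0.5, "chr9", 0, 1000)


class TestArrayPseudocounts:
    layout = GenomeLayout((("chr1", 60_000),))

    def test_probe_at_each_center_both_modes(self):
        bins = make_bins(self.layout, 20_000)
        probes = ProbeSet.from_frame(
            pd.DataFrame({"chrom": "chr1", "position": [10_000, 30_000, 50_000], "intensity": [0.1, 0.2, 0.3]})
        )
        for mode in ("nearest", "mean"):
            np.testing.assert_allclose(array_pseudocounts(probes, bins, mode), [0.1, 0.2, 0.3])

    def test_mean_mode_empty_bin_missing(self):
        bins = make_bins(self.layout, 20_000)
        probes = ProbeSet.from_frame(
            pd.DataFrame({"chrom": "chr1", "position": [10_000], "intensity": [0.5]})
        )
        out = array_pseudocounts(probes, bins, "mean")
        assert out[0] == 0.5 and np.isnan(out[1]) and np.isnan(out[2])

    def test_seven_probes_three_bins_hand_enumeration(self):
        bins = make_bins(self.layout, 20_000)
        pos = np.array([1_000, 5_000, 19_999, 20_000, 29_000, 41_000, 59_000])
        inten = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        probes = ProbeSet.from_frame(pd.DataFrame({"chrom": "chr1", "position": pos, "intensity": inten}))
        # independent enumeration
        centers = (bins.start + bins.end) / 2
        exp_nearest = [inten[np.argmin(np.abs(pos - c))] for c in centers]
        exp_mean = [
            inten[(pos >= s) & (pos < e)].mean() for s, e in zip(bins.start, bins.end)
        ]
        np.testing.assert_allclose(array_pseudocounts(probes, bins, "nearest"), exp_nearest)
        np.testing.assert_allclose(array_pseudocounts(probes, bins, "mean"), exp_mean)

    def test_empty_probe_set_is_error(self):
        bins = make_bins(self.layout, 20_000)
        with pytest.raises(ValueError):
            array_pseudocounts(ProbeSet({}, {}), bins)


class TestSegmentConcordance:
    def _set(self, triples):
        return SegmentSet([Segment("chr1", s, e, (e - s) // 100, m) for s, e, m in triples])

    def test_identical_sets(self):
        a = self._set([(0, 1000, 0.5), (1000, 3000, -0.2)])
        res = segment_concordance(a, a)
        assert res.weighted_euclidean == 0.0
        assert res.weighted_pearson == 1.0
        assert res.total_weight == 3000

    def test_constant_shift(self):
        a = self._set([(0, 1000, 0.5), (1000, 3000, -0.2)])
        b = self._set([(0, 1000, 0.8), (1000, 3000, 0.1)])
        res = segment_concordance(a, b)
        assert res.weighted_euclidean == pytest.approx(0.3)
        assert res.weighted_pearson == pytest.approx(1.0)

    def test_matches_per_bp_expansion_oracle(self):
        a = self._set([(0, 300, 0.1), (300, 700, 0.9), (700, 1200, -0.4)])
        b = self._set([(0, 500, 0.2), (500, 1200, 0.6)])
        res = segment_concordance(a, b)
        # expansion oracle: repeat each overlap's mean pair once per bp
        xs, ys = [], []
        for sa in a:
            for sb in b:
                w = min(sa.end, sb.end) - max(sa.start, sb.start)
                if w > 0:
                    xs += [sa.mean] * w
                    ys += [sb.mean] * w
        xs, ys = np.array(xs), np.array(ys)
        assert res.weighted_euclidean == pytest.approx(np.sqrt(np.mean((xs - ys) ** 2)))
        assert res.weighted_pearson == pytest.approx(np.corrcoef(xs, ys)[0, 1])
        assert res.total_weight == len(xs)

    def test_disjoint_sets_error(self):
        a = self._set([(0, 100, 0.0)])
        b = SegmentSet([Segment("chr2", 0, 100, 1, 0.0)])
        with pytest.raises(ValueError):
            segment_concordance(a, b)


class TestRandomPlacementOverlap:
    def test_whole_genome_annotation(self):
        layout = GenomeLayout((("chr1", 1000),))
        query = IntervalSet({"chr1": [(10, 20), (500, 600)]})
        annotation = IntervalSet({"chr1": [(0, 1000)]})
        obs, sims, p = random_placement_overlap(query, annotation, layout, n_sim=200, seed=1)
        assert obs == 1.0 and np.all(sims == 1.0) and p == 1.0

    def test_empty_annotation(self):
        layout = GenomeLayout((("chr1", 1000),))
        query = IntervalSet({"chr1": [(10, 20)]})
        obs, sims, p = random_placement_overlap(query, IntervalSet(), layout, n_sim=100, seed=1)
        assert obs == 0.0 and np.all(sims == 0.0)

    def test_toy_genome_against_exact_enumeration(self):
        """1 chromosome of 100 bp, annotation [0, 50), one query of length 10:
        exact placement enumeration gives the simulated overlap probability."""
        layout = GenomeLayout((("chr1", 100),))
        annotation = IntervalSet({"chr1": [(0, 50)]})
        # exact enumeration over the 91 valid placements
        hits = sum(1 for s in range(0, 91) if s < 50 and s + 10 > 0)
        exact = hits / 91
        query = IntervalSet({"chr1": [(60, 70)]})
        n_sim = 4000
        obs, sims, p = random_placement_overlap(query, annotation, layout, n_sim=n_sim, seed=7)
        mc_err = 4 * np.sqrt(exact * (1 - exact) / n_sim)
        assert abs(sims.mean() - exact) < mc_err

    def test_oversized_interval_is_error(self):
        with pytest.raises(ValueError):
            random_placement_overlap(
                IntervalSet({"chr1": [(0, 100)]}),
                IntervalSet(),
                GenomeLayout((("chr1", 50),)),
                n_sim=10,
                seed=0,
            )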