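"""GC/mappability annotation, loess correction, filters, log2 normalisation."""

import numpy as np
import pandas as pd
import pytest

from offcnv.coverage import CoverageProfile, make_bins
from offcnv.genome_io import GenomeLayout, IntervalSet
from offcnv.normalize import (
    BinFilterConfig,
    apply_bin_filters,
    gc_fraction_per_bin,
    loess_correct,
    mappability_per_bin,
    median_normalize_log2,
    relative_log2,
)


class TestGcFraction:
    def test_definition_on_known_sequence(self, tmp_path):
        seq = "G" * 20 + "AT" * 10 + "ACGTN" * 4
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + seq + "\n")
        layout = GenomeLayout((("chr1", 60),))
        bins = make_bins(layout, 20)
        gc = gc_fraction_per_bin(fasta, bins)
        np.testing.assert_allclose(gc, [1.0, 0.0, 0.5])

    def test_case_insensitive(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + "gcat" * 5 + "\n")
        bins = make_bins(GenomeLayout((("chr1", 20),)), 20)
        assert gc_fraction_per_bin(fasta, bins)[0] == 0.5

    def test_mostly_n_bin_is_missing(self, tmp_path):
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\n" + "N" * 19 + "G" + "\n")
        bins = make_bins(GenomeLayout((("chr1", 20),)), 20)
        assert np.isnan(gc_fraction_per_bin(fasta, bins)[0])


class TestMappability:
    layout = GenomeLayout((("chr1", 100_000),))

    def test_uniform_track(self):
        bins = make_bins(self.layout, 20_000)
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [100_000], "value": [1.0]})
        np.testing.assert_allclose(mappability_per_bin(track, bins), 1.0)

    def test_absent_bases_count_as_zero(self):
        bins = make_bins(self.layout, 20_000)
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10_000], "value": [1.0]})
        got = mappability_per_bin(track, bins)
        np.testing.assert_allclose(got, [0.5, 0, 0, 0, 0])

    def test_matches_per_base_oracle(self):
        bins = make_bins(self.layout, 20_000)
        rng = np.random.default_rng(8)
        starts = np.sort(rng.choice(100_000 // 50, 30, replace=False)) * 50
        track = pd.DataFrame(
            {
                "chrom": "chr1",
                "start": starts,
                "end": starts + rng.integers(10, 50, 30),
                "value": rng.uniform(0, 1, 30).round(3),
            }
        )
        per_base = np.zeros(100_000)
        for _, r in track.iterrows():
            per_base[int(r["start"]) : int(r["end"])] = r["value"]
        expected = per_base.reshape(5, 20_000).mean(axis=1)
        np.testing.assert_allclose(mappability_per_bin(track, bins), expected, atol=1e-12)

    def test_out_of_range_values_rejected(self):
        bins = make_bins(self.layout, 20_000)
        track = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10], "value": [1.5]})
        with pytest.raises(ValueError):
            mappability_per_bin(track, bins)


class TestLoessCorrect:
    def test_constant_values_unchanged(self):
        rng = np.random.default_rng(0)
        c = rng.uniform(0.3, 0.7, 200)
        out = loess_correct(np.full(200, 5.0), c)
        np.testing.assert_allclose(out, 5.0, rtol=1e-9)

    def test_exponential_bias_flattened(self):
        """An exp(c) trend on a dense covariate grid is corrected to the
        median within 2% relative tolerance."""
        c = np.linspace(0.3, 0.7, 400)
        values = np.exp(c)
        out = loess_correct(values, c)
        med = np.median(values)
        assert np.nanmax(np.abs(out - med) / med) < 0.02

    def test_too_few_pairs_is_error(self):
        with pytest.raises(ValueError, match="pairs"):
            loess_correct(np.ones(10), np.linspace(0, 1, 10))

    def test_missing_covariate_propagates(self):
        rng = np.random.default_rng(1)
        c = rng.uniform(0, 1, 100)
        c[7] = np.nan
        out = loess_correct(np.full(100, 2.0), c)
        assert np.isnan(out[7]) and np.isfinite(np.delete(out, 7)).all()

    def test_median_preserved(self):
        rng = np.random.default_rng(2)
        c = rng.uniform(0.3, 0.7, 300)
        values = np.exp(c) * rng.lognormal(0, 0.1, 300)
        out = loess_correct(values, c)
        assert np.nanmedian(out) == pytest.approx(np.median(values), rel=0.02)


class TestBinFilters:
    def _profile(self):
        layout = GenomeLayout((("chr1", 100_000),))
        bins = make_bins(layout, 20_000)
        prof = CoverageProfile(bins=bins, raw_doc=np.array([10, 10, 0, 10, 10]), x=np.zeros(5))
        prof.comp_doc = prof.raw_doc.astype(float)
        prof.mappability = np.array([1.0, 0.1, 1.0, 1.0, 1.0])
        return prof

    def test_rule_by_rule_enumeration(self):
        prof = self._profile()
        blacklist = IntervalSet({"chr1": [(60_000, 80_000)]})  # bin 3 fully inside
        usable = apply_bin_filters(prof, blacklist)
        # bin1: low mappability; bin2: zero count; bin3: blacklisted
        assert usable.tolist() == [True, False, False, False, True]

    def test_all_clean_all_usable(self):
        prof = self._profile()
        prof.mappability = np.ones(5)
        prof.comp_doc = np.full(5, 3.0)
        assert apply_bin_filters(prof, None).all()

    def test_blacklist_fraction_threshold(self):
        prof = self._profile()
        prof.mappability = np.ones(5)
        prof.comp_doc = np.full(5, 3.0)
        blacklist = IntervalSet({"chr1": [(0, 5_000)]})  # 25% of bin 0
        assert not apply_bin_filters(prof, blacklist)[0]
        cfg = BinFilterConfig(blacklist_overlap_max=0.5)
        assert apply_bin_filters(prof, blacklist, cfg)[0]


class TestMedianLog2:
    layout = GenomeLayout((("chr1", 60_000),))

    def test_equal_values_give_zero(self):
        bins = make_bins(self.layout, 20_000)
        out = median_normalize_log2(np.full(3, 7.0), np.ones(3, bool), bins)
        np.testing.assert_allclose(out, 0.0)

    def test_powers_of_two(self):
        bins = make_bins(self.layout, 20_000)
        out = median_normalize_log2(np.array([1.0, 2.0, 4.0]), np.ones(3, bool), bins)
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])

    def test_output_median_is_zero_over_usable_autosomal(self):
        layout = GenomeLayout((("chr1", 200_000), ("chrX", 100_000)))
        bins = make_bins(layout, 20_000)
        rng = np.random.default_rng(3)
        values = rng.lognormal(3, 0.4, len(bins))
        usable = rng.random(len(bins)) > 0.2
        usable[bins.autosomal_mask()][:1] = True  # ensure at least one
        out = median_normalize_log2(values, usable, bins)
        sel = usable & bins.autosomal_mask()
        assert np.median(out[sel]) == pytest.approx(0.0, abs=1e-12)

    def test_sex_chromosome_state_does_not_shift_baseline(self):
        layout = GenomeLayout((("chr1", 200_000), ("chrX", 200_000)))
        bins = make_bins(layout, 20_000)
        values = np.where(bins.autosomal_mask(), 100.0, 50.0)  # one X copy
        out = median_normalize_log2(values, np.ones(len(bins), bool), bins)
        assert out[bins.autosomal_mask()][0] == pytest.approx(0.0)
        assert out[~bins.autosomal_mask()][0] == pytest.approx(-1.0)

    def test_no_usable_autosomal_bins_is_error(self):
        bins = make_bins(self.layout, 20_000)
        with pytest.raises(ValueError):
            median_normalize_log2(np.ones(3), np.zeros(3, bool), bins)


class TestRelativeLog2:
    def test_identity_and_shift(self):
        a = np.array([1.0, 0.2, np.nan])
        assert relative_log2(a, a)[0] == 0.0
        got = relative_log2(np.array([1.0]), np.array([0.2]))
        assert got[0] == pytest.approx(0.8)

    def test_missing_propagates(self):
        got = relative_log2(np.array([1.0, np.nan]), np.array([np.nan, 1.0]))
        assert np.isnan(got).all()

    def test_grid_mismatch_is_error(self):
        with pytest.raises(ValueError):
            relative_log2(np.zeros(3), np.zeros(4))
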