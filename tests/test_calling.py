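"""CNV calling threshold geometry, classification and karyotype subtraction."""

import numpy as np
import pytest

from sccnv.calling import (CNVCall, ExpectedKaryotype, call_cnvs,
                           isochromosome_karyotype, reciprocal_overlap,
                           subtract_expected)
from sccnv.copynumber import ScaledProfile
from sccnv.genome import MB, GenomeBuild, make_bin_grid


def _scaled_copy(values, profile_factory, bin_size, chrom_len=None, name="chr1",
                 excluded=None):
    n = len(values)
    chrom_len = chrom_len or n * bin_size
    g = GenomeBuild(chromosomes=((name, chrom_len, chrom_len // 2),))
    grid = make_bin_grid(g, bin_size, gc_source=lambda c, s, e: np.full(len(s), 0.4))
    vals = np.asarray(values, dtype=float).copy()
    if excluded is not None:
        object.__setattr__(grid, "excluded", np.asarray(excluded, dtype=bool))
        vals[np.asarray(excluded)] = np.nan
    prof = profile_factory(grid, vals, stage="scaled")
    return ScaledProfile(sample_id="cell", profile=prof, segmentation=None,
                         segment_copy=np.array([]), scaling_factor=2.0,
                         sse=0.0, sse_curve=np.empty((0, 2)))


BASE = {"chr1": 2.0}


class TestCallingThresholds:
    def test_sixteen_half_mb_bins_make_an_8mb_gain(self, profile_factory):
        vals = np.full(100, 2.0)
        vals[20:36] = 2.7  # 16 bins * 0.5 Mb = 8 Mb: both minima met exactly
        calls = call_cnvs(_scaled_copy(vals, profile_factory, 500_000), BASE)
        assert len(calls) == 1
        c = calls[0]
        assert c.direction == "gain" and c.size == 8 * MB and c.n_bins == 16

    def test_fifteen_half_mb_bins_fail_the_size_rule(self, profile_factory):
        vals = np.full(100, 2.0)
        vals[20:35] = 2.7  # 15 bins = 7.5 Mb < 8 Mb although >= 8 bins
        assert call_cnvs(_scaled_copy(vals, profile_factory, 500_000), BASE) == []

    def test_seven_vs_eight_consecutive_1mb_bins(self, profile_factory):
        vals = np.full(60, 2.0)
        vals[10:17] = 1.2  # 7 bins: below the run minimum
        assert call_cnvs(_scaled_copy(vals, profile_factory, 1_000_000), BASE) == []
        vals[10:18] = 1.2  # 8 bins, 8 Mb
        calls = call_cnvs(_scaled_copy(vals, profile_factory, 1_000_000), BASE)
        assert len(calls) == 1
        assert calls[0].direction == "loss" and calls[0].size == 8 * MB

    def test_relaxed_gain_threshold_applies_only_at_coarsest_bins(self, profile_factory):
        # copy 2.58 is a gain at 2.5 Mb bins (+0.55) but not at 1 Mb (+0.65)
        vals25 = np.full(40, 2.0)
        vals25[10:18] = 2.58  # 8 bins * 2.5 Mb = 20 Mb
        calls = call_cnvs(_scaled_copy(vals25, profile_factory, 2_500_000), BASE)
        assert len(calls) == 1 and calls[0].direction == "gain"
        assert calls[0].size == 20 * MB

        vals1 = np.full(60, 2.0)
        vals1[10:30] = 2.58
        assert call_cnvs(_scaled_copy(vals1, profile_factory, 1_000_000), BASE) == []

    def test_loss_threshold_is_065_at_all_bin_sizes(self, profile_factory):
        vals = np.full(40, 2.0)
        vals[10:18] = 1.45  # dev -0.55: not a loss even at 2.5 Mb bins
        assert call_cnvs(_scaled_copy(vals, profile_factory, 2_500_000), BASE) == []

    def test_loss_on_male_x_uses_baseline_one(self, profile_factory):
        vals = np.full(60, 1.0)
        vals[20:35] = 0.1  # dev -0.9 from baseline 1
        scaled = _scaled_copy(vals, profile_factory, 1_000_000, name="chrX")
        calls = call_cnvs(scaled, {"chrX": 1.0})
        assert len(calls) == 1 and calls[0].direction == "loss"

    def test_masked_bins_bridge_runs_but_do_not_count(self, profile_factory):
        vals = np.full(60, 2.0)
        vals[10:22] = 2.8
        excluded = np.zeros(60, dtype=bool)
        excluded[15] = True  # splits the run into 5 + 6 usable bins, 11 total
        calls = call_cnvs(_scaled_copy(vals, profile_factory, 1_000_000,
                                       excluded=excluded), BASE)
        assert len(calls) == 1
        assert calls[0].n_bins == 11  # masked bin bridged, not counted


class TestClassification:
    def test_whole_chromosome_gain_is_trisomy(self, profile_factory):
        vals = np.full(50, 3.0)
        calls = call_cnvs(_scaled_copy(vals, profile_factory, 1_000_000), BASE)
        assert len(calls) == 1
        c = calls[0]
        assert c.cnv_class == "whole_chromosome" and c.label == "trisomy"
        assert c.start_terminal and c.end_terminal

    def test_interstitial_call_is_segmental_non_terminal(self, profile_factory):
        vals = np.full(120, 2.0)
        vals[60:70] = 2.8  # 60.5-69.5 Mb style interior gain
        calls = call_cnvs(_scaled_copy(vals, profile_factory, 1_000_000), BASE)
        c = calls[0]
        assert c.cnv_class == "segmental" and not c.terminal

    def test_call_reaching_chromosome_end_is_terminal(self, profile_factory):
        vals = np.full(60, 2.0)
        vals[45:] = 1.2
        calls = call_cnvs(_scaled_copy(vals, profile_factory, 1_000_000), BASE)
        c = calls[0]
        assert c.terminal and c.end_terminal and not c.start_terminal


class TestSubtractExpected:
    def _call(self, chrom, start_mb, end_mb, direction):
        return CNVCall(cell_id="c", chrom=chrom, start=int(start_mb * MB),
                       end=int(end_mb * MB), direction=direction,
                       mean_copy=2.0, n_bins=10)

    def test_arm_loss_matches_expected_isochromosome(self):
        g = GenomeBuild(chromosomes=(("chr20", 64_000_000, 28_000_000),))
        expected = isochromosome_karyotype(g, "chr20")
        call = self._call("chr20", 0, 26, "loss")
        matched, additional = subtract_expected([call], expected)
        assert matched == [call] and additional == []

    def test_unrelated_gain_is_additional(self):
        g = GenomeBuild(chromosomes=(("chr20", 64_000_000, 28_000_000),
                                     ("chr3", 198_000_000, 91_000_000),))
        expected = isochromosome_karyotype(g, "chr20")
        call = self._call("chr3", 60.5, 69.5, "gain")
        matched, additional = subtract_expected([call], expected)
        assert matched == [] and additional == [call]

    def test_direction_mismatch_is_additional(self):
        g = GenomeBuild(chromosomes=(("chr20", 64_000_000, 28_000_000),))
        expected = ExpectedKaryotype(intervals=[("chr20", 28_000_000, 64_000_000, "loss")])
        call = self._call("chr20", 28, 64, "gain")
        _, additional = subtract_expected([call], expected)
        assert additional == [call]


class TestCallInvariants:
    def test_emitted_calls_respect_minima_on_random_profiles(self, profile_factory):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = 80
            vals = np.full(n, 2.0)
            # random rectangular perturbations of random width and height
            for _ in range(rng.integers(1, 4)):
                w = int(rng.integers(1, 30))
                s = int(rng.integers(0, n - w))
                vals[s:s + w] += rng.choice([-1.0, -0.7, 0.7, 1.0])
            scaled = _scaled_copy(vals, profile_factory, 1_000_000)
            for c in call_cnvs(scaled, BASE):
                assert c.n_bins >= 8
                assert c.size >= 8 * MB
                dev = vals[c.start // MB:c.end // MB] - 2.0
                if c.direction == "gain":
                    assert np.all(dev >= 0.65)
                else:
                    assert np.all(dev <= -0.65)

    def test_calls_are_maximal(self, profile_factory):
        vals = np.full(60, 2.0)
        vals[10:25] = 2.9
        scaled = _scaled_copy(vals, profile_factory, 1_000_000)
        c = call_cnvs(scaled, BASE)[0]
        left, right = c.start // MB - 1, c.end // MB
        assert vals[left] - 2.0 < 0.65 and vals[right] - 2.0 < 0.65


def test_reciprocal_overlap_is_symmetric_and_bounded():
    assert reciprocal_overlap(0, 10, 5, 15) == pytest.approx(0.5)
    assert reciprocal_overlap(5, 15, 0, 10) == pytest.approx(0.5)
    assert reciprocal_overlap(0, 10, 20, 30) == 0.0
    assert reciprocal_overlap(0, 10, 0, 10) == 1.0
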