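"""Synthetic-data generator: rate model, determinism, cohort structure."""

import numpy as np
import pytest

from sccnv.genome import GenomeBuild, make_bin_grid
from sccnv.simulate import (SimCellSpec, SimConfig, copy_vector, simulate_bulk,
                            simulate_cell, simulate_population)


@pytest.fixture(scope="module")
def small_genome():
    return GenomeBuild(chromosomes=(
        ("chr1", 100_000_000, 50_000_000),
        ("chr20", 64_000_000, 28_000_000),
        ("chrX", 50_000_000, 25_000_000),
    ))


@pytest.fixture(scope="module")
def small_grid(small_genome):
    return make_bin_grid(small_genome, 1_000_000)


def _config(small_genome, **kw):
    kw.setdefault("gc_slope", 0.0)
    cfg = SimConfig(genome=small_genome, **kw)
    cfg.dispersion = dict(cfg.dispersion)
    return cfg


class TestSimulateCell:
    def test_same_seed_reproduces_counts_bit_exactly(self, small_genome, small_grid):
        cfg = _config(small_genome)
        spec = SimCellSpec(cell_id="c", quality_tier="mid", total_reads=10**6)
        a = simulate_cell(spec, cfg, small_grid, np.random.default_rng(7))
        b = simulate_cell(spec, cfg, small_grid, np.random.default_rng(7))
        assert np.array_equal(a.counts, b.counts)

    def test_flat_diploid_counts_match_multinomial_moments(self, small_genome, small_grid):
        cfg = _config(small_genome)
        cfg.dispersion["high"] = 0.0
        spec = SimCellSpec(cell_id="c", quality_tier="high", total_reads=10**6,
                           karyotype=[("chrX", 0, 50_000_000, 2)])  # all-diploid
        counts = simulate_cell(spec, cfg, small_grid, np.random.default_rng(0))
        n_usable = small_grid.usable.sum()
        p = 1 / n_usable
        expect = 10**6 * p
        sd = np.sqrt(10**6 * p * (1 - p))
        assert counts.total == 10**6
        assert np.all(np.abs(counts.counts[small_grid.usable] - expect) < 5 * sd)
        assert np.all(counts.counts[~small_grid.usable] == 0)

    def test_copy_three_bins_get_1_5x_reads(self, small_genome, small_grid):
        cfg = _config(small_genome)
        cfg.dispersion["high"] = 0.0
        spec = SimCellSpec(cell_id="c", quality_tier="high", total_reads=4 * 10**6,
                           karyotype=[("chr1", 0, 50_000_000, 3),
                                      ("chrX", 0, 50_000_000, 2)])
        counts = simulate_cell(spec, cfg, small_grid, np.random.default_rng(1))
        gained = (small_grid.chrom == "chr1") & (small_grid.end <= 50_000_000) \
            & small_grid.usable
        normal = (small_grid.chrom == "chr1") & (small_grid.start >= 50_000_000) \
            & small_grid.usable
        ratio = counts.counts[gained].mean() / counts.counts[normal].mean()
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_all_zero_rates_error(self, small_genome, small_grid):
        cfg = _config(small_genome)
        spec = SimCellSpec(cell_id="c", quality_tier="high", total_reads=1000,
                           karyotype=[(c, 0, 10**9, 0) for c, _, _ in
                                      small_genome.chromosomes])
        with pytest.raises(ValueError, match="all-zero"):
            simulate_cell(spec, cfg, small_grid, np.random.default_rng(0))


class TestSimulatePopulation:
    def test_exact_carrier_count(self, small_genome, small_grid):
        cfg = _config(small_genome, carrier_fraction=40 / 56, extra_cnv_rate=0.0,
                      reads_mean=2e5, reads_sd=0, seed=3)
        truth = simulate_population(cfg, 56, grid=small_grid)
        assert sum(s.carrier for s in truth.specs) == 40
        for s in truth.specs:
            if s.carrier:
                assert {(c, cp) for c, _, _, cp in s.karyotype} == {("chr20", 1), ("chr20", 3)}

    def test_zero_extra_rate_gives_no_extras(self, small_genome, small_grid):
        cfg = _config(small_genome, extra_cnv_rate=0.0, reads_mean=2e5, reads_sd=0)
        truth = simulate_population(cfg, 10, grid=small_grid)
        assert all(s.extras == [] for s in truth.specs)

    def test_extras_avoid_centromeres_sex_chroms_and_iso_chrom(self, small_genome, small_grid):
        cfg = _config(small_genome, extra_cnv_rate=2.0, reads_mean=2e5, reads_sd=0,
                      extra_size_range=(8e6, 30e6), seed=5)
        truth = simulate_population(cfg, 20, grid=small_grid)
        extras = [e for s in truth.specs for e in s.extras]
        assert extras, "expected some injected CNVs"
        for chrom, start, end, copy in extras:
            assert chrom == "chr1"  # only non-iso autosome in this genome
            cen = small_genome.centromeres[chrom]
            assert end <= cen or start >= cen  # never spans the centromere
            assert copy in (1, 3)

    def test_same_seed_reproduces_truthset(self, small_genome, small_grid):
        cfg = _config(small_genome, seed=11, reads_mean=2e5, reads_sd=0)
        a = simulate_population(cfg, 8, grid=small_grid)
        b = simulate_population(cfg, 8, grid=small_grid)
        assert all(np.array_equal(x.counts, y.counts)
                   for x, y in zip(a.counts, b.counts))
        assert [s.karyotype for s in a.specs] == [s.karyotype for s in b.specs]


class TestSimulateBulk:
    def test_pure_carrier_population_halves_parm_rate(self, small_genome, small_grid):
        cfg = _config(small_genome, carrier_fraction=1.0, extra_cnv_rate=0.0,
                      reads_mean=2e5, reads_sd=0, seed=2)
        truth = simulate_population(cfg, 10, grid=small_grid)
        bulk = simulate_bulk(truth, 4 * 10**6, np.random.default_rng(3))
        parm = (small_grid.chrom == "chr20") & (small_grid.end <= 28_000_000) \
            & small_grid.usable
        qarm = (small_grid.chrom == "chr20") & (small_grid.start >= 28_000_000) \
            & small_grid.usable
        auto = (small_grid.chrom == "chr1") & small_grid.usable
        assert bulk.counts[parm].mean() / bulk.counts[auto].mean() == pytest.approx(0.5, rel=0.05)
        assert bulk.counts[qarm].mean() / bulk.counts[auto].mean() == pytest.approx(1.5, rel=0.05)

    def test_mosaic_mixture_rate_is_between_pure_states(self, small_genome, small_grid):
        cfg = _config(small_genome, carrier_fraction=40 / 56, extra_cnv_rate=0.0,
                      reads_mean=2e5, reads_sd=0, seed=4)
        truth = simulate_population(cfg, 56, grid=small_grid)
        bulk = simulate_bulk(truth, 4 * 10**6, np.random.default_rng(5))
        parm = (small_grid.chrom == "chr20") & (small_grid.end <= 28_000_000) \
            & small_grid.usable
        auto = (small_grid.chrom == "chr1") & small_grid.usable
        # mixture expectation: (2 - 40/56)/2 = 0.643 of the diploid rate
        ratio = bulk.counts[parm].mean() / bulk.counts[auto].mean()
        assert ratio == pytest.approx((2 - 40 / 56) / 2, rel=0.03)


def test_copy_vector_overrides_baseline(small_grid):
    copies = copy_vector([("chr20", 0, 28_000_000, 1)], small_grid, sex="XY")
    parm = (small_grid.chrom == "chr20") & (small_grid.end <= 28_000_000)
    assert np.all(copies[parm] == 1)
    assert np.all(copies[small_grid.chrom == "chrX"] == 1)  # XY baseline
    assert np.all(copies[small_grid.chrom == "chr1"] == 2)
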