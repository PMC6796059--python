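import numpy as np
import pytest

from sccnv.genome import BinCounts, GenomeBuild, make_bin_grid


@pytest.fixture
def toy_genome():
    """One 10 Mb chromosome, centromere mid-way, no exclusions."""
    return GenomeBuild(chromosomes=(("chr1", 10_000_000, 5_000_000),))


@pytest.fixture
def toy_grid(toy_genome):
    return make_bin_grid(toy_genome, 1_000_000)


@pytest.fixture
def two_chrom_genome():
    return GenomeBuild(chromosomes=(
        ("chr1", 100_000_000, 50_000_000),
        ("chr2", 60_000_000, 30_000_000),
    ))


@pytest.fixture
def flat_gc():
    """GC source callable giving a constant 0.40 everywhere."""
    return lambda chrom, start, end: np.full(len(start), 0.40)


def make_profile_from_values(grid, values, sample_id="cell", stage="normalized"):
    """Helper: wrap raw ratio values (one per bin) into a CopyProfile."""
    from sccnv.normalization import CopyProfile

    values = np.asarray(values, dtype=float)
    mask = grid.usable & np.isfinite(values)
    vals = np.where(mask, values, np.nan)
    return CopyProfile(sample_id=sample_id, grid=grid, stage=stage,
                       values=vals, mask=mask)


@pytest.fixture
def profile_factory():
    return make_profile_from_values
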