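"""Synthetic single-cell and bulk bin-count generator with known truth.

Emulates the statistical structure of shallow whole-genome sequencing of
whole-genome-amplified single cells:

* per-bin relative rate  r_i = c_i * (1 + slope*(gc_i - 0.40)) * a_i, where
  c_i is the cell's true copy at bin i and a_i ~ Gamma(1/d, d) is a
  multiplicative amplification factor with tier-specific dispersion d
  (marginally negative-binomial counts);
* read counts multinomial over usable bins with a per-cell total drawn from
  Normal(3.9e6, 1.3e6) truncated at 1e5, matching typical per-cell yields;
* a mosaic population in which a fixed fraction of cells carries an
  isochromosome (one-copy p-arm loss + one-copy q-arm gain on chr20) and
  each cell independently gains Poisson-distributed extra mega-base CNVs.

Quality tiers (high/mid/low/fail) map to dispersions calibrated so that
cells are typically analysable at 0.5/1/2.5 Mb bins or fail QC respectively.
All randomness flows from a single seeded generator; regenerating with the
same config and seed reproduces counts bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copynumber import expected_copy
from .genome import MB, BinCounts, BinGrid, GenomeBuild, default_genome

#: quality tier -> gamma mixing variance of the per-bin amplification factor
TIER_DISPERSION: dict[str, float] = {"high": 0.002, "mid": 0.021, "low": 0.074, "fail": 0.42}

DEFAULT_TIER_PROPORTIONS: dict[str, float] = {"high": 0.2, "mid": 0.45, "low": 0.25, "fail": 0.10}


@dataclass
class SimCellSpec:
    """Ground truth for one synthetic cell."""

    cell_id: str
    quality_tier: str
    total_reads: int
    carrier: bool = False
    # intervals overriding the baseline copy: (chrom, start bp, end bp, copy)
    karyotype: list[tuple[str, int, int, int]] = field(default_factory=list)
    # the subset of karyotype injected as "extra" CNVs (not the isochromosome)
    extras: list[tuple[str, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.quality_tier not in TIER_DISPERSION:
            raise ValueError(f"unknown quality tier {self.quality_tier!r}")
        for chrom, start, end, copy in self.karyotype:
            if start >= end or copy < 0:
                raise ValueError(f"invalid karyotype interval {chrom}:{start}-{end} copy {copy}")


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    genome: GenomeBuild = field(default_factory=default_genome)
    sex: str = "XY"
    iso_chrom: str = "chr20"
    carrier_fraction: float = 40 / 56
    extra_cnv_rate: float = 0.5          # Poisson mean per cell
    extra_size_range: tuple[float, float] = (8 * MB, 100 * MB)  # log-uniform
    gc_slope: float = 1.0                # relative rate per unit GC above 0.40
    dispersion: dict[str, float] = field(default_factory=lambda: dict(TIER_DISPERSION))
    tier_proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TIER_PROPORTIONS))
    reads_mean: float = 3.9e6
    reads_sd: float = 1.3e6
    reads_min: int = 100_000
    seed: int = 0


@dataclass
class TruthSet:
    """Simulator output: specs plus generated counts, with provenance."""

    config: SimConfig
    specs: list[SimCellSpec]
    counts: list[BinCounts]

    def spec_for(self, cell_id: str) -> SimCellSpec:
        return next(s for s in self.specs if s.cell_id == cell_id)


def copy_vector(spec_karyotype, grid: BinGrid, sex: str = "XY") -> np.ndarray:
    """True copy per bin: sex baseline with karyotype-interval overrides
    (a bin takes an interval's copy when its midpoint falls inside)."""
    baseline = expected_copy(grid.genome, sex)
    copies = np.array([baseline[c] for c in grid.chrom], dtype=float)
    mid = (grid.start + grid.end) / 2.0
    for chrom, start, end, copy in spec_karyotype:
        sel = (grid.chrom == chrom) & (mid >= start) & (mid < end)
        copies[sel] = copy
    return copies


def simulate_cell(spec: SimCellSpec, config: SimConfig, grid: BinGrid,
                  rng: np.random.Generator) -> BinCounts:
    """Generate one cell's bin counts under the rate model."""
    copies = copy_vector(spec.karyotype, grid, config.sex)
    copies = np.nan_to_num(copies, nan=0.0)
    rate = copies * (1.0 + config.gc_slope * (grid.gc - 0.40))
    rate = np.clip(rate, 0.0, None)
    d = config.dispersion[spec.quality_tier]
    if d > 0:
        rate = rate * rng.gamma(shape=1.0 / d, scale=d, size=grid.n_bins)
    rate[~grid.usable] = 0.0
    total_rate = rate.sum()
    if total_rate <= 0:
        raise ValueError(f"{spec.cell_id}: all-zero rates")
    counts = rng.multinomial(spec.total_reads, rate / total_rate)
    return BinCounts(sample_id=spec.cell_id, grid=grid, counts=counts)


def _draw_total_reads(config: SimConfig, rng: np.random.Generator) -> int:
    return int(max(config.reads_min, rng.normal(config.reads_mean, config.reads_sd)))


def _assign_tiers(n_cells: int, proportions: dict[str, float],
                  rng: np.random.Generator) -> list[str]:
    tiers = sorted(proportions)
    weights = np.array([proportions[t] for t in tiers], dtype=float)
    weights /= weights.sum()
    counts = np.floor(weights * n_cells).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    frac = weights * n_cells - counts
    for i in np.argsort(-frac)[: n_cells - counts.sum()]:
        counts[i] += 1
    assigned = [t for t, k in zip(tiers, counts) for _ in range(k)]
    return list(rng.permutation(assigned))


# Injected breakpoints stay at least this far from arm boundaries: inside the
# masked pericentromeric bins localization is undefined, and within one
# minimum segment (5 bins) of a telomere a breakpoint cannot be resolved by
# the segmenter, so placing truth there would make it unrecoverable by design.
ARM_MARGIN = 6_000_000


def _place_extra_cnv(config: SimConfig, rng: np.random.Generator,
                     occupied: list[tuple[str, int, int]]) -> tuple[str, int, int, int] | None:
    """One random extra CNV: log-uniform size, inside a single autosomal arm
    (never spanning a centromere, never on the isochromosome's chromosome or
    the sex chromosomes), not overlapping previously placed intervals."""
    autosomes = [c for c, _, _ in config.genome.chromosomes
                 if c not in (config.iso_chrom, "chrX", "chrY", "X", "Y")]
    lo, hi = config.extra_size_range
    for _ in range(50):
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        chrom = autosomes[rng.integers(len(autosomes))]
        arm = "p" if rng.random() < 0.5 else "q"
        a, b = config.genome.arm_interval(chrom, arm)
        a += ARM_MARGIN
        b -= ARM_MARGIN
        if b - a <= size:
            continue
        start = int(rng.integers(a, b - size))
        end = start + size
        if any(c == chrom and start < e and end > s for c, s, e in occupied):
            continue
        copy = 3 if rng.random() < 0.5 else 1
        return chrom, start, end, copy
    return None


def simulate_population(config: SimConfig, n_cells: int,
                        rng: np.random.Generator | None = None,
                        grid: BinGrid | None = None) -> TruthSet:
    """Generate a mosaic cohort with exact carrier count round(f * n_cells).

    Counts are generated on ``grid`` (default: the 0.5 Mb grid of the
    config's genome); coarser bin sizes are derived downstream by count
    aggregation, so amplification noise averages down with bin size exactly
    as it would in resequenced data.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if grid is None:
        from .genome import make_bin_grid

        grid = make_bin_grid(config.genome, 500_000)

    n_carriers = int(round(config.carrier_fraction * n_cells))
    carrier_flags = np.zeros(n_cells, dtype=bool)
    carrier_flags[:n_carriers] = True
    carrier_flags = rng.permutation(carrier_flags)
    tiers = _assign_tiers(n_cells, config.tier_proportions, rng)

    p_arm = config.genome.arm_interval(config.iso_chrom, "p")
    q_arm = config.genome.arm_interval(config.iso_chrom, "q")
    iso = [(config.iso_chrom, p_arm[0], p_arm[1], 1),
           (config.iso_chrom, q_arm[0], q_arm[1], 3)]

    specs: list[SimCellSpec] = []
    counts: list[BinCounts] = []
    for i in range(n_cells):
        karyotype: list[tuple[str, int, int, int]] = list(iso) if carrier_flags[i] else []
        extras: list[tuple[str, int, int, int]] = []
        occupied: list[tuple[str, int, int]] = []
        for _ in range(rng.poisson(config.extra_cnv_rate)):
            cnv = _place_extra_cnv(config, rng, occupied)
            if cnv is not None:
                extras.append(cnv)
                occupied.append(cnv[:3])
        karyotype.extend(extras)
        spec = SimCellSpec(
            cell_id=f"cell_{i + 1:03d}", quality_tier=tiers[i],
            total_reads=_draw_total_reads(config, rng),
            carrier=bool(carrier_flags[i]), karyotype=karyotype, extras=extras)
        specs.append(spec)
        counts.append(simulate_cell(spec, config, grid, rng))
    return TruthSet(config=config, specs=specs, counts=counts)


def simulate_bulk(truth: TruthSet, total_reads: int,
                  rng: np.random.Generator, dispersion: float = 0.0) -> BinCounts:
    """Bulk counts as the equal-weight mixture of the member cells.

    The per-bin rate is the mean of the cells' copy-weighted GC-biased rates
    with no per-cell amplification noise (bulk DNA is not WGA material); a
    mild gamma dispersion can be added.
    """
    if not truth.specs:
        raise ValueError("empty truth set")
    grid = truth.counts[0].grid
    config = truth.config
    rate = np.zeros(grid.n_bins)
    for spec in truth.specs:
        copies = np.nan_to_num(copy_vector(spec.karyotype, grid, config.sex), nan=0.0)
        rate += copies * (1.0 + config.gc_slope * (grid.gc - 0.40))
    rate /= len(truth.specs)
    rate = np.clip(rate, 0.0, None)
    if dispersion > 0:
        rate = rate * rng.gamma(1.0 / dispersion, dispersion, size=grid.n_bins)
    rate[~grid.usable] = 0.0
    counts = rng.multinomial(total_reads, rate / rate.sum())
    return BinCounts(sample_id="bulk", grid=grid, counts=counts)
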