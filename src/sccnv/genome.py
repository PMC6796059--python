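"""Genome model, fixed-width bin grids and per-bin read counting.

The coordinate frame for the whole pipeline is a grid of fixed-width bins
(0.5, 1 or 2.5 Mb by default) tiling each chromosome.  Bins that overlap
hard-to-sequence regions (by default half the bin or more) are flagged
``excluded`` and masked from every downstream stage rather than zeroed,
so they cannot bias the GC fit.

All coordinates are 0-based half-open base pairs internally; reports render
positions in Mb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MB = 1_000_000

# GRCh38 chromosome lengths (bp) and approximate centromere midpoints (bp).
# Public assembly constants; centromere positions are rounded to 0.1 Mb and
# used only to split arms and to seed the default exclusion mask.
GRCH38_CHROMOSOMES: tuple[tuple[str, int, int], ...] = (
    ("chr1", 248_956_422, 123_400_000),
    ("chr2", 242_193_529, 93_900_000),
    ("chr3", 198_295_559, 90_900_000),
    ("chr4", 190_214_555, 50_000_000),
    ("chr5", 181_538_259, 48_800_000),
    ("chr6", 170_805_979, 59_800_000),
    ("chr7", 159_345_973, 60_100_000),
    ("chr8", 145_138_636, 45_200_000),
    ("chr9", 138_394_717, 43_000_000),
    ("chr10", 133_797_422, 39_800_000),
    ("chr11", 135_086_622, 53_400_000),
    ("chr12", 133_275_309, 35_500_000),
    ("chr13", 114_364_328, 17_700_000),
    ("chr14", 107_043_718, 17_200_000),
    ("chr15", 101_991_189, 19_000_000),
    ("chr16", 90_338_345, 36_800_000),
    ("chr17", 83_257_441, 25_100_000),
    ("chr18", 80_373_285, 18_500_000),
    ("chr19", 58_617_616, 26_200_000),
    ("chr20", 64_444_167, 28_100_000),
    ("chr21", 46_709_983, 12_000_000),
    ("chr22", 50_818_468, 15_000_000),
    ("chrX", 156_040_895, 60_600_000),
    ("chrY", 57_227_415, 10_400_000),
)


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered chromosomes with lengths, centromere midpoints and exclusions.

    ``excluded_regions`` holds hard-to-sequence intervals (BED-like,
    0-based half-open) that are masked out of the analysis.
    """

    chromosomes: tuple[tuple[str, int, int], ...]
    excluded_regions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length, cen in self.chromosomes:
            if length <= 0:
                raise ValueError(f"{name}: non-positive length {length}")
            if not (0 < cen < length):
                raise ValueError(f"{name}: centromere {cen} outside (0, {length})")
        lengths = dict(self.lengths.items())
        for chrom, start, end in self.excluded_regions:
            if chrom not in lengths:
                raise ValueError(f"excluded region on unknown chromosome {chrom!r}")
            if not (0 <= start < end <= lengths[chrom]):
                raise ValueError(f"excluded region {chrom}:{start}-{end} outside chromosome")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c[0]: c[1] for c in self.chromosomes}

    @property
    def centromeres(self) -> dict[str, int]:
        return {c[0]: c[2] for c in self.chromosomes}

    def merged_exclusions(self, chrom: str) -> list[tuple[int, int]]:
        """Exclusions on one chromosome, sorted and merged."""
        ivs = sorted((s, e) for c, s, e in self.excluded_regions if c == chrom)
        merged: list[tuple[int, int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def arm_interval(self, chrom: str, arm: str) -> tuple[int, int]:
        """(start, end) in bp of the p or q arm."""
        cen = self.centromeres[chrom]
        if arm == "p":
            return 0, cen
        if arm == "q":
            return cen, self.lengths[chrom]
        raise ValueError(f"unknown arm {arm!r}")


def default_genome(centromere_halfwidth: int = 2_500_000) -> GenomeBuild:
    """GRCh38-like build whose exclusion mask covers pericentromeric DNA.

    The published difficult-to-sequence list is not redistributable, so the
    default mask excludes ``centromere_mid +/- centromere_halfwidth`` on each
    chromosome; any BED3 can be supplied instead.
    """
    excl = tuple(
        (name, max(0, cen - centromere_halfwidth), min(length, cen + centromere_halfwidth))
        for name, length, cen in GRCH38_CHROMOSOMES
    )
    return GenomeBuild(chromosomes=GRCH38_CHROMOSOMES, excluded_regions=excl)


def read_genome_table(path, exclusions_bed=None) -> GenomeBuild:
    """Read a genome table TSV (chrom, length, centromere_mid) and optional BED3."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length", "centromere_mid"])
    chroms = tuple((str(r.chrom), int(r.length), int(r.centromere_mid)) for r in df.itertuples())
    excl: tuple[tuple[str, int, int], ...] = ()
    if exclusions_bed is not None:
        bed = pd.read_csv(exclusions_bed, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2], names=["chrom", "start", "end"])
        excl = tuple((str(r.chrom), int(r.start), int(r.end)) for r in bed.itertuples())
    return GenomeBuild(chromosomes=chroms, excluded_regions=excl)


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width bins tiling a genome, with GC fraction and exclusion flags.

    Arrays are parallel over bins, ordered by chromosome then start.  The last
    bin of a chromosome may be narrower than ``bin_size``.
    """

    genome: GenomeBuild
    bin_size: int
    chrom: np.ndarray      # str per bin
    start: np.ndarray      # int bp
    end: np.ndarray        # int bp
    gc: np.ndarray         # float in [0, 1]
    excluded: np.ndarray   # bool

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def usable(self) -> np.ndarray:
        return ~self.excluded

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": self.chrom, "start": self.start, "end": self.end,
            "gc": self.gc, "excluded": self.excluded,
        })


def synthetic_gc_track(chrom: np.ndarray, start: np.ndarray, end: np.ndarray) -> np.ndarray:
    """Deterministic smooth GC landscape for grids without a reference sequence.

    Mimics the isochore-scale structure of the human genome: a genome-wide mean
    near 0.41 with slow multi-megabase waves, bounded to [0.30, 0.60].  Purely
    positional and reproducible (no RNG), so a grid always gets the same track.
    """
    mid = (np.asarray(start, dtype=float) + np.asarray(end, dtype=float)) / 2.0
    # stable small phase per chromosome from its name
    phases = np.array([sum(ord(c) for c in str(ch)) % 17 for ch in chrom], dtype=float)
    gc = (0.41
          + 0.05 * np.sin(2 * np.pi * mid / (71 * MB) + phases)
          + 0.03 * np.sin(2 * np.pi * mid / (13 * MB) + 2.1 * phases))
    return np.clip(gc, 0.30, 0.60)


def make_bin_grid(genome: GenomeBuild, bin_size: int, gc_source=None,
                  exclusion_fraction: float = 0.5) -> BinGrid:
    """Tile the genome into fixed-width bins and attach GC and exclusion flags.

    Parameters
    ----------
    genome : GenomeBuild
    bin_size : int
        Bin width in bp; must not exceed the smallest chromosome.
    gc_source : None, callable or array
        ``None`` uses the deterministic synthetic GC track; a callable is
        invoked as ``gc_source(chrom, start, end)`` arrays; an array must give
        one GC fraction per bin.
    exclusion_fraction : float
        A bin is flagged excluded when at least this fraction of it overlaps
        the merged excluded regions (default 0.5).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    smallest = min(length for _, length, _ in genome.chromosomes)
    if bin_size > smallest:
        raise ValueError(f"bin_size {bin_size} exceeds smallest chromosome ({smallest} bp)")

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    excluded: list[bool] = []
    for name, length, _ in genome.chromosomes:
        excl = genome.merged_exclusions(name)
        pos = 0
        while pos < length:
            stop = min(pos + bin_size, length)
            width = stop - pos
            overlap = sum(min(stop, e) - max(pos, s) for s, e in excl
                          if s < stop and e > pos)
            chroms.append(name)
            starts.append(pos)
            ends.append(stop)
            excluded.append(overlap >= exclusion_fraction * width)
            pos = stop

    chrom_arr = np.array(chroms, dtype=object)
    start_arr = np.array(starts, dtype=np.int64)
    end_arr = np.array(ends, dtype=np.int64)
    if gc_source is None:
        gc = synthetic_gc_track(chrom_arr, start_arr, end_arr)
    elif callable(gc_source):
        gc = np.asarray(gc_source(chrom_arr, start_arr, end_arr), dtype=float)
    else:
        gc = np.asarray(gc_source, dtype=float)
    if len(gc) != len(start_arr):
        raise ValueError(f"GC track has {len(gc)} values for {len(start_arr)} bins")
    if np.any((gc < 0) | (gc > 1)) or np.any(~np.isfinite(gc)):
        raise ValueError("GC fractions must lie in [0, 1]")

    return BinGrid(genome=genome, bin_size=int(bin_size), chrom=chrom_arr,
                   start=start_arr, end=end_arr, gc=gc,
                   excluded=np.array(excluded, dtype=bool))


@dataclass
class BinCounts:
    """Per-bin read counts for one sample on a given grid."""

    sample_id: str
    grid: BinGrid
    counts: np.ndarray  # non-negative int per bin

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.grid.n_bins:
            raise ValueError(
                f"{self.sample_id}: {len(self.counts)} counts for {self.grid.n_bins} bins")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.sample_id}: negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def count_reads(alignments, grid: BinGrid, min_mapping_quality: int = 20,
                sample_id: str | None = None, on_unknown_chrom: str = "warn") -> BinCounts:
    """Count primary mapped reads into grid bins by leftmost aligned position.

    ``alignments`` is a path to a SAM/BAM file or an open
    :class:`pysam.AlignmentFile`.  Unmapped, secondary, supplementary and
    duplicate reads are skipped, as are reads below ``min_mapping_quality``.
    Each passing read increments exactly one bin.
    """
    import pysam

    close = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        close = True
    if on_unknown_chrom not in ("warn", "error"):
        raise ValueError("on_unknown_chrom must be 'warn' or 'error'")

    # per-chromosome offset of its first bin; all bins except the terminal one
    # have width bin_size, so position // bin_size indexes within a chromosome
    offsets: dict[str, tuple[int, int]] = {}
    for name in grid.genome.names:
        idx = grid.chrom_index(name)
        if len(idx):
            offsets[name] = (int(idx[0]), len(idx))

    counts = np.zeros(grid.n_bins, dtype=np.int64)
    n_pass = n_skip = 0
    warned: set[str] = set()
    try:
        for read in alignments:
            if (read.is_unmapped or read.is_secondary or read.is_supplementary
                    or read.is_duplicate or read.mapping_quality < min_mapping_quality):
                n_skip += 1
                continue
            chrom = read.reference_name
            if chrom not in offsets:
                if on_unknown_chrom == "error":
                    raise ValueError(f"alignment on chromosome {chrom!r} absent from grid")
                if chrom not in warned:
                    log.warning("skipping reads on %s: not in grid", chrom)
                    warned.add(chrom)
                n_skip += 1
                continue
            off, nbins = offsets[chrom]
            j = min(read.reference_start // grid.bin_size, nbins - 1)
            counts[off + j] += 1
            n_pass += 1
    finally:
        if close:
            alignments.close()

    log.info("counted %d reads into bins (%d skipped)", n_pass, n_skip)
    return BinCounts(sample_id=sample_id or "sample", grid=grid, counts=counts)


def write_bin_counts(counts: BinCounts, path) -> None:
    """Write a bin-count TSV: chrom, start, end, count (0-based half-open)."""
    df = pd.DataFrame({
        "chrom": counts.grid.chrom, "start": counts.grid.start,
        "end": counts.grid.end, "count": counts.counts,
    })
    df.to_csv(path, sep="\t", index=False)


def read_bin_counts(path, grid: BinGrid, sample_id: str | None = None) -> BinCounts:
    """Read a bin-count TSV and validate it against the active grid."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "count"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"{path}: expected header {required}, found {list(df.columns[:4])}")
    bad = df.index[~np.isfinite(pd.to_numeric(df["count"], errors="coerce"))]
    if len(bad):
        raise ValueError(f"{path}: malformed count at line {int(bad[0]) + 2}")
    if (df["count"] < 0).any():
        line = int(df.index[df["count"] < 0][0]) + 2
        raise ValueError(f"{path}: negative count at line {line}")
    if len(df) != grid.n_bins:
        raise ValueError(f"{path}: {len(df)} rows for a grid of {grid.n_bins} bins")
    mismatch = (df["chrom"].to_numpy(dtype=object) != grid.chrom) | \
               (df["start"].to_numpy() != grid.start) | (df["end"].to_numpy() != grid.end)
    if mismatch.any():
        i = int(np.flatnonzero(mismatch)[0])
        raise ValueError(
            f"{path}: bin {df['chrom'][i]}:{df['start'][i]}-{df['end'][i]} does not match "
            f"grid bin {grid.chrom[i]}:{grid.start[i]}-{grid.end[i]}")
    sid = sample_id if sample_id is not None else str(path)
    return BinCounts(sample_id=sid, grid=grid, counts=df["count"].to_numpy())


def aggregate_counts(counts: BinCounts, coarse_grid: BinGrid) -> BinCounts:
    """Sum fine-grid counts into a coarser grid on the same genome.

    The coarse bin size must be an integer multiple of the fine bin size.
    A coarse bin is excluded on the coarse grid's own flags; its count is the
    sum of all overlapping fine-bin counts.
    """
    if coarse_grid.bin_size % counts.grid.bin_size != 0:
        raise ValueError("coarse bin size must be a multiple of the fine bin size")
    out = np.zeros(coarse_grid.n_bins, dtype=np.int64)
    for name in counts.grid.genome.names:
        fi = counts.grid.chrom_index(name)
        ci = coarse_grid.chrom_index(name)
        if not len(fi) or not len(ci):
            continue
        ratio = coarse_grid.bin_size // counts.grid.bin_size
        target = np.minimum(np.arange(len(fi)) // ratio, len(ci) - 1)
        np.add.at(out, ci[0] + target, counts.counts[fi])
    return BinCounts(sample_id=counts.sample_id, grid=coarse_grid, counts=out)
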