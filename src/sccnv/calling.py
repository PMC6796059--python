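"""CNV calling from scaled copy profiles.

Calls are maximal runs of consecutive usable bins deviating from the
per-chromosome baseline copy (2 for autosomes, 1 for X and Y in an XY cell)
by at least the calling threshold: +0.65 for gains at 0.5 and 1 Mb bins,
+0.55 for gains at 2.5 Mb bins, and -0.65 for losses at all bin sizes.  A
run becomes a call only when it holds at least 8 qualifying bins AND spans
at least the minimum genomic size (8 Mb at 0.5/1 Mb bins, 20 Mb at 2.5 Mb
bins).  Masked bins inside a run do not break consecutiveness but do not
count toward the 8-bin minimum.

Thresholds are deviations from the baseline rather than absolute copies, so
losses remain callable on the single-copy male X.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .copynumber import ScaledProfile
from .genome import MB, GenomeBuild

#: bin size (bp) -> gain threshold above baseline
GAIN_THRESHOLDS: dict[int, float] = {500_000: 0.65, 1_000_000: 0.65, 2_500_000: 0.55}
LOSS_THRESHOLD = 0.65  # below baseline, all bin sizes
MIN_RUN_BINS = 8
#: bin size (bp) -> minimum genomic span (bp)
MIN_SIZES: dict[int, int] = {500_000: 8 * MB, 1_000_000: 8 * MB, 2_500_000: 20 * MB}

WHOLE_CHROM_FRACTION = 0.95


@dataclass
class CNVCall:
    """One called aberration in one cell (coordinates bp, 0-based half-open)."""

    cell_id: str
    chrom: str
    start: int
    end: int
    direction: str                 # "gain" | "loss"
    mean_copy: float
    n_bins: int
    cnv_class: str = "segmental"   # "segmental" | "whole_chromosome"
    terminal: bool = False
    start_terminal: bool = False
    end_terminal: bool = False

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def size_mb(self) -> float:
        return round(self.size / MB, 1)

    @property
    def label(self) -> str:
        if self.cnv_class == "whole_chromosome":
            return "trisomy" if self.direction == "gain" else "monosomy"
        return f"segmental {self.direction}"


@dataclass
class ExpectedKaryotype:
    """Known aberrations of a line, e.g. the arm-level loss + gain of an
    isochromosome; intervals are (chrom, start bp, end bp, direction)."""

    intervals: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        for chrom, start, end, direction in self.intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            if direction not in ("gain", "loss"):
                raise ValueError(f"unknown direction {direction!r}")


def isochromosome_karyotype(genome: GenomeBuild, chrom: str = "chr20") -> ExpectedKaryotype:
    """Arm-level loss of the p-arm and reciprocal gain of the q-arm."""
    p = genome.arm_interval(chrom, "p")
    q = genome.arm_interval(chrom, "q")
    return ExpectedKaryotype(intervals=[(chrom, p[0], p[1], "loss"),
                                        (chrom, q[0], q[1], "gain")])


def call_cnvs(scaled: ScaledProfile, baseline: dict[str, float],
              gain_thresholds: dict[int, float] | None = None,
              loss_threshold: float = LOSS_THRESHOLD,
              min_run_bins: int = MIN_RUN_BINS,
              min_sizes: dict[int, int] | None = None) -> list[CNVCall]:
    """Emit classified CNV calls from a copy-space profile.

    The run condition is evaluated on per-bin copy values (after
    segment-median replacement these align with segment boundaries).
    """
    gain_thresholds = dict(GAIN_THRESHOLDS if gain_thresholds is None else gain_thresholds)
    min_sizes = dict(MIN_SIZES if min_sizes is None else min_sizes)
    bin_size = scaled.grid.bin_size
    if bin_size not in gain_thresholds or bin_size not in min_sizes:
        raise ValueError(f"no calling thresholds configured for bin size {bin_size}")
    gain_t = gain_thresholds[bin_size]
    min_size = min_sizes[bin_size]

    calls: list[CNVCall] = []
    for chrom in scaled.grid.genome.names:
        base = baseline.get(chrom)
        if base is None or not np.isfinite(base):
            continue  # masked chromosome (e.g. Y in an XX cell)
        idx = scaled.grid.chrom_index(chrom)
        use = idx[scaled.mask[idx]]
        if len(use) == 0:
            continue
        dev = scaled.copy_values[use] - base
        state = np.zeros(len(use), dtype=np.int8)
        state[dev >= gain_t] = 1
        state[dev <= -loss_threshold] = -1
        # maximal runs over the usable-bin sequence: masked bins between
        # usable bins are bridged implicitly
        boundaries = np.flatnonzero(np.diff(state)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [len(use)]))
        for a, b in zip(starts, ends):
            if state[a] == 0:
                continue
            n_bins = b - a
            span_start = int(scaled.grid.start[use[a]])
            span_end = int(scaled.grid.end[use[b - 1]])
            if n_bins < min_run_bins or span_end - span_start < min_size:
                continue
            call = CNVCall(
                cell_id=scaled.sample_id, chrom=chrom,
                start=span_start, end=span_end,
                direction="gain" if state[a] > 0 else "loss",
                mean_copy=float(np.mean(scaled.copy_values[use[a:b]])),
                n_bins=int(n_bins))
            calls.append(classify_call(call, scaled))
    return calls


def classify_call(call: CNVCall, scaled: ScaledProfile) -> CNVCall:
    """Fill in cnv_class and terminal flags for a call.

    A call is whole-chromosome when it covers at least 95% of the
    chromosome's usable bins (centromeric gaps prevent literal full
    coverage); an endpoint is terminal when it coincides with the outer edge
    of the chromosome's first or last usable bin.
    """
    idx = scaled.grid.chrom_index(call.chrom)
    use = idx[scaled.mask[idx]]
    in_call = (scaled.grid.start[use] >= call.start) & (scaled.grid.end[use] <= call.end)
    whole = in_call.sum() >= WHOLE_CHROM_FRACTION * len(use)
    start_term = call.start == int(scaled.grid.start[use[0]])
    end_term = call.end == int(scaled.grid.end[use[-1]])
    return replace(call,
                   cnv_class="whole_chromosome" if whole else "segmental",
                   start_terminal=bool(start_term), end_terminal=bool(end_term),
                   terminal=bool(start_term or end_term))


def reciprocal_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    return min(inter / (a_end - a_start), inter / (b_end - b_start))


def matches_expected(call: CNVCall, expected: ExpectedKaryotype,
                     min_overlap: float = 0.5) -> bool:
    return any(call.chrom == chrom and call.direction == direction
               and reciprocal_overlap(call.start, call.end, start, end) >= min_overlap
               for chrom, start, end, direction in expected.intervals)


def subtract_expected(calls: list[CNVCall], expected: ExpectedKaryotype,
                      min_overlap: float = 0.5) -> tuple[list[CNVCall], list[CNVCall]]:
    """Split calls into (matched, additional) against an expected karyotype.

    A call matches when it shares chromosome and direction with an expected
    interval and their reciprocal overlap is at least ``min_overlap``.
    """
    matched = [c for c in calls if matches_expected(c, expected, min_overlap)]
    additional = [c for c in calls if not matches_expected(c, expected, min_overlap)]
    return matched, additional
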