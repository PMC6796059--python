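"""GC normalization and outlier smoothing of binned read counts.

Single-cell whole-genome-amplified libraries show a strong, smooth dependence
of read depth on bin GC content.  The correction fits a locally weighted
regression (lowess, span 0.3) of log2(count + 0.5) on GC fraction over usable
bins, subtracts the fit, and re-centres the profile so the genome-wide median
ratio is exactly 1.  A pseudocount of 0.5 keeps zero-count bins defined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import BinCounts, BinGrid

STAGES = ("raw", "normalized", "smoothed", "segmented", "scaled")


@dataclass
class CopyProfile:
    """One cell's per-bin values moving through the pipeline.

    ``values`` are in median-normalized ratio space (genome median == 1)
    until the copy-scaling stage multiplies them into copy space.  Masked
    bins (grid exclusions plus normalization drop-outs) are NaN and never
    consumed downstream.
    """

    sample_id: str
    grid: BinGrid
    stage: str
    values: np.ndarray   # float per bin, NaN on masked bins
    mask: np.ndarray     # bool, True = usable

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.values) != self.grid.n_bins or len(self.mask) != self.grid.n_bins:
            raise ValueError("values/mask length must equal the number of grid bins")

    @property
    def log2_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log2(self.values)

    @property
    def usable_values(self) -> np.ndarray:
        return self.values[self.mask]


def gc_normalize(counts: BinCounts, gc_low: float = 0.28, gc_high: float = 0.68,
                 span: float = 0.3, min_usable_bins: int = 100) -> CopyProfile:
    """Remove the GC trend from bin counts and return a median-1 ratio profile.

    Bins flagged excluded on the grid are masked from the start; bins with
    zero counts at extreme GC (< ``gc_low`` or > ``gc_high``) are masked as
    amplification drop-outs rather than treated as losses.
    """
    grid = counts.grid
    gc = grid.gc
    mask = grid.usable.copy()
    mask &= ~((counts.counts == 0) & ((gc < gc_low) | (gc > gc_high)))
    if np.any(~np.isfinite(gc[mask])):
        raise ValueError("GC values missing on usable bins")

    usable_positive = int(np.sum(mask & (counts.counts > 0)))
    if usable_positive < min_usable_bins:
        raise ValueError(
            f"{counts.sample_id}: only {usable_positive} usable bins with reads "
            f"(need >= {min_usable_bins})")

    log2c = np.log2(counts.counts + 0.5)
    if np.ptp(gc[mask]) < 1e-9:  # constant GC: nothing to fit
        fit = np.full(int(mask.sum()), np.mean(log2c[mask]))
    else:
        fit = lowess(log2c[mask], gc[mask], frac=span, return_sorted=False)
    resid = np.full(grid.n_bins, np.nan)
    resid[mask] = log2c[mask] - fit

    ratio = np.full(grid.n_bins, np.nan)
    ratio[mask] = 2.0 ** resid[mask]
    med = np.median(ratio[mask])
    if not np.isfinite(med) or med <= 0:
        raise ValueError(f"{counts.sample_id}: degenerate profile, zero median")
    ratio[mask] /= med

    return CopyProfile(sample_id=counts.sample_id, grid=grid, stage="normalized",
                       values=ratio, mask=mask)


def smooth_outliers(profile: CopyProfile, trim_sd: float = 3.0,
                    smoothing_window: int = 10) -> CopyProfile:
    """Winsorize isolated single-bin outliers toward their running median.

    Works on log2 ratios per chromosome.  A bin is an outlier when it deviates
    from the running median of its window by more than ``trim_sd`` robust
    (MAD-based) standard deviations; it is shrunk to the running median plus or
    minus ``trim_sd`` sd.  Only isolated bins are touched — a bin whose
    immediate usable neighbour deviates in the same direction is part of a run
    (a genuine CNV) and is left alone.
    """
    if profile.stage not in ("normalized", "smoothed"):
        raise ValueError(f"smooth_outliers expects a normalized profile, got {profile.stage!r}")

    values = profile.values.copy()
    half = max(1, smoothing_window // 2)
    for chrom in profile.grid.genome.names:
        idx = profile.grid.chrom_index(chrom)
        use = idx[profile.mask[idx]]
        if len(use) < 3:
            continue
        x = np.log2(values[use])
        n = len(x)
        run_med = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            run_med[i] = np.median(x[lo:hi])
        dev = x - run_med
        sd = 1.4826 * np.median(np.abs(dev))
        if sd <= 0:
            continue
        out = np.abs(dev) > trim_sd * sd
        for i in np.flatnonzero(out):
            neighbours = [j for j in (i - 1, i + 1) if 0 <= j < n]
            # isolated: no adjacent bin deviating the same way beyond the trim
            # threshold (adjacent co-deviating bins form a run, i.e. a CNV)
            if any(np.sign(dev[j]) == np.sign(dev[i]) and np.abs(dev[j]) > trim_sd * sd
                   for j in neighbours):
                continue
            x[i] = run_med[i] + np.sign(dev[i]) * trim_sd * sd
        values[use] = 2.0 ** x

    return replace(profile, stage="smoothed", values=values)
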