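"""Scaling a segmented ratio profile to absolute copy numbers.

The segmented profile lives in median-normalized ratio space; the absolute
copy number of a single cell is recovered by finding the continuous scaling
factor *s* (copies per unit ratio) that minimizes the segment-weighted
sum-of-squares distance between scaled segment medians and the nearest
integers:

    SSE(s) = sum_over_segments  n_bins * (s * m - round(s * m))^2

scanned over a grid of candidate scalings (default [1.5, 3.0] in steps of
0.001, bracketing a diploid-modal genome).  Ties are broken by the candidate
closest to 2.0.  Because the scaling, not the per-segment value, is fitted,
mosaic mixtures naturally land at non-integer copies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeBuild
from .normalization import CopyProfile
from .segmentation import Segmentation


@dataclass
class ScaledProfile:
    """Copy-space view of one cell: per-bin and per-segment copies."""

    sample_id: str
    profile: CopyProfile          # stage "scaled", per-bin copy values
    segmentation: Segmentation
    segment_copy: np.ndarray      # s * median_ratio per segment
    scaling_factor: float
    sse: float
    sse_curve: np.ndarray         # (n_candidates, 2): scaling, SSE

    @property
    def grid(self):
        return self.profile.grid

    @property
    def copy_values(self) -> np.ndarray:
        return self.profile.values

    @property
    def mask(self) -> np.ndarray:
        return self.profile.mask


def fit_copy_scaling(profile: CopyProfile, seg: Segmentation,
                     search: tuple[float, float] = (1.5, 3.0),
                     step: float = 0.001) -> ScaledProfile:
    """Fit the integer-clustering scaling factor and move the profile to copy space.

    ``profile`` may be at stage ``segmented`` (bins already replaced by
    segment medians) or any earlier ratio-space stage; the SSE is always
    computed on the segment medians, weighted by segment size in bins.
    """
    if not seg.segments:
        raise ValueError("empty segmentation: nothing to scale")
    medians = np.array([s.median_value for s in seg.segments])
    weights = np.array([s.n_bins for s in seg.segments], dtype=float)

    candidates = np.arange(search[0], search[1] + step / 2, step)
    scaled = candidates[:, None] * medians[None, :]
    sse = (weights[None, :] * (scaled - np.round(scaled)) ** 2).sum(axis=1)

    best = np.min(sse)
    tied = np.flatnonzero(sse <= best + 1e-12)
    s_opt = float(candidates[tied[np.argmin(np.abs(candidates[tied] - 2.0))]])

    values = profile.values * s_opt
    scaled_profile = CopyProfile(sample_id=profile.sample_id, grid=profile.grid,
                                 stage="scaled", values=values, mask=profile.mask)
    return ScaledProfile(
        sample_id=profile.sample_id, profile=scaled_profile, segmentation=seg,
        segment_copy=medians * s_opt, scaling_factor=s_opt, sse=float(best),
        sse_curve=np.column_stack([candidates, sse]))


def expected_copy(genome: GenomeBuild, sex: str) -> dict[str, float]:
    """Baseline copy per chromosome: autosomes 2; for XY both X and Y are 1;
    for XX the X is 2 and the Y is masked (NaN, never called)."""
    if sex not in ("XY", "XX"):
        raise ValueError(f"unknown sex label {sex!r} (expected 'XY' or 'XX')")
    baseline: dict[str, float] = {}
    for name, _, _ in genome.chromosomes:
        if name in ("chrX", "X"):
            baseline[name] = 1.0 if sex == "XY" else 2.0
        elif name in ("chrY", "Y"):
            baseline[name] = 1.0 if sex == "XY" else float("nan")
        else:
            baseline[name] = 2.0
    return baseline
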