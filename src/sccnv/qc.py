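"""Bin-size quality control by integer clustering of per-bin copies.

A well-amplified cell has per-bin copy values tightly grouped around the
integers 1, 2 and 3.  The clustering fraction is the share of usable bins
whose copy value lies within +/-0.25 of one of those integers (closed
window).  A sample is analysable at a bin size when its fraction strictly
exceeds the size-specific threshold: >0.80 at 0.5 Mb, >0.62 at 1 Mb,
>0.58 at 2.5 Mb; the smallest admissible bin size is chosen, or the sample
fails QC outright.

Fractions are scored on per-bin copies after outlier smoothing but before
segment-median replacement — segment medians would cluster trivially and
defeat the check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copynumber import ScaledProfile

MB = 1_000_000

#: bin size (bp) -> strict clustering-fraction threshold
DEFAULT_THRESHOLDS: dict[int, float] = {500_000: 0.80, 1_000_000: 0.62, 2_500_000: 0.58}

#: integer copies that count as clustered
CLUSTER_INTEGERS: tuple[int, ...] = (1, 2, 3)

CLUSTER_WINDOW = 0.25


@dataclass
class QCResult:
    sample_id: str
    fractions: dict[int, float]          # bin size bp -> clustering fraction
    thresholds: dict[int, float]
    chosen_bin_size: int | None          # None means FAIL
    pass_flags: dict[int, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return self.chosen_bin_size is not None


def clustering_fraction(scaled: ScaledProfile) -> float:
    """Fraction of usable bins with copy within +/-0.25 of 1, 2 or 3."""
    copies = scaled.copy_values[scaled.mask]
    if len(copies) == 0:
        raise ValueError(f"{scaled.sample_id}: no usable bins")
    near = np.zeros(len(copies), dtype=bool)
    for k in CLUSTER_INTEGERS:
        near |= np.abs(copies - k) <= CLUSTER_WINDOW
    return float(np.mean(near))


def select_bin_size(fractions: dict[int, float],
                    thresholds: dict[int, float] | None = None,
                    sample_id: str = "sample") -> QCResult:
    """Pick the smallest bin size whose fraction strictly exceeds its threshold.

    Requires a fraction for every configured bin size (the pipeline runs all
    three per sample).  Returns a FAIL result (``chosen_bin_size=None``) when
    no size passes.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    missing = [b for b in thresholds if b not in fractions]
    if missing:
        raise ValueError(f"missing clustering fraction for bin size(s) {sorted(missing)}")
    flags = {b: fractions[b] > thresholds[b] for b in sorted(thresholds)}
    chosen = next((b for b in sorted(thresholds) if flags[b]), None)
    return QCResult(sample_id=sample_id, fractions={b: fractions[b] for b in sorted(thresholds)},
                    thresholds=thresholds, chosen_bin_size=chosen, pass_flags=flags)
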