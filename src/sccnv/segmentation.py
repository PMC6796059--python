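"""Circular binary segmentation (CBS) of normalized copy profiles.

Each chromosome is segmented independently.  At every step the algorithm
finds the circular arc of usable bins maximizing a two-sample t-like
statistic between the arc and its complement, validates the split with a
permutation p-value, and recurses.  A split is only made when the p-value is
below ``alpha`` and every resulting piece holds at least ``min_bins`` bins
(default 5 bins, alpha 0.05).  Permutations are drawn from an explicit seeded
generator, with sequential early stopping: permutation sampling stops as soon
as enough exceedances have accrued to rule out significance.

A numba-compiled kernel is used for the O(n^2) arc scan when numba is
available; a vectorized numpy path gives identical results otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .normalization import CopyProfile

log = logging.getLogger(__name__)

try:  # pragma: no cover - exercised indirectly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _best_arc_kernel(S, n):  # pragma: no cover - numba
    """Max t-like statistic over all arcs (i, j]; returns (stat, i, j).

    Ties are broken by the earliest (leftmost, then shortest) arc, which is
    the scan order."""
    best = -1.0
    bi = -1
    bj = -1
    total = S[n]
    for i in range(0, n):
        jmax = n if i > 0 else n - 1
        for j in range(i + 1, jmax + 1):
            k = j - i
            m_in = (S[j] - S[i]) / k
            m_out = (total - S[j] + S[i]) / (n - k)
            stat = abs(m_in - m_out) * math.sqrt(k * (n - k) / n)
            if stat > best + 1e-12:
                best = stat
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def _arc_exceeds_kernel(S, n, threshold):  # pragma: no cover - numba
    """True when any arc statistic reaches ``threshold`` (early exit)."""
    total = S[n]
    for i in range(0, n):
        jmax = n if i > 0 else n - 1
        for j in range(i + 1, jmax + 1):
            k = j - i
            m_in = (S[j] - S[i]) / k
            m_out = (total - S[j] + S[i]) / (n - k)
            if abs(m_in - m_out) * math.sqrt(k * (n - k) / n) >= threshold:
                return True
    return False


def _arc_indices(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays (i, j, k) of all arc cut pairs for a piece of n bins."""
    i_idx, j_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    k = j_idx - i_idx
    ok = (k >= 1) & (k <= n - 1)
    ii, jj = np.nonzero(ok)
    return ii, jj, (jj - ii)


def _best_arc_numpy(S: np.ndarray, n: int):
    ii, jj, kk = _arc_indices(n)
    m_in = (S[jj] - S[ii]) / kk
    m_out = (S[n] - S[jj] + S[ii]) / (n - kk)
    stat = np.abs(m_in - m_out) * np.sqrt(kk * (n - kk) / n)
    best = np.max(stat)
    a = int(np.flatnonzero(stat >= best - 1e-12)[0])
    return float(stat[a]), int(ii[a]), int(jj[a])


def _best_arc(x: np.ndarray):
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    if _HAVE_NUMBA:
        return _best_arc_kernel(S, n)
    return _best_arc_numpy(S, n)


def _arc_exceeds(x: np.ndarray, threshold: float) -> bool:
    n = len(x)
    S = np.concatenate(([0.0], np.cumsum(x)))
    if _HAVE_NUMBA:
        return bool(_arc_exceeds_kernel(S, n, threshold))
    stat, _, _ = _best_arc_numpy(S, n)
    return stat >= threshold


def _split_significant(x: np.ndarray, obs: float, alpha: float,
                       n_permutations: int, rng: np.random.Generator) -> bool:
    """Sequential permutation test: is P(max arc stat >= obs) < alpha?

    Counts permuted profiles whose maximal arc statistic reaches the observed
    one and stops as soon as the count can no longer stay below
    ``alpha * n_permutations``.
    """
    needed = int(math.ceil(alpha * n_permutations))  # exceedances that kill the split
    count = 0
    done = 0
    block = 64
    while done < n_permutations:
        b = min(block, n_permutations - done)
        perms = rng.permuted(np.tile(x, (b, 1)), axis=1)
        for row in perms:
            if _arc_exceeds(row, obs):
                count += 1
                if count >= needed:
                    return False
        done += b
    return count < needed


@dataclass(frozen=True)
class Segment:
    chrom: str
    first_bin: int   # global grid index of the first usable bin
    last_bin: int    # global grid index of the last usable bin (inclusive)
    n_bins: int      # usable bins in the segment
    median_value: float  # median ratio (normalized space)
    bin_index: np.ndarray  # global grid indices of the usable bins


@dataclass
class Segmentation:
    sample_id: str
    segments: list[Segment]

    def to_frame(self, grid):
        import pandas as pd

        rows = [{
            "chrom": s.chrom,
            "start": int(grid.start[s.first_bin]),
            "end": int(grid.end[s.last_bin]),
            "n_bins": s.n_bins,
            "median_ratio": s.median_value,
            "median_log2": float(np.log2(s.median_value)) if s.median_value > 0 else np.nan,
        } for s in self.segments]
        return pd.DataFrame(rows)


def segment_cbs(profile: CopyProfile, alpha: float = 0.05, min_bins: int = 5,
                n_permutations: int = 10_000, seed: int = 0) -> Segmentation:
    """Segment a smoothed (or normalized) profile per chromosome with CBS.

    Returns a :class:`Segmentation` whose segments partition the usable bins
    of every chromosome.  A chromosome with fewer than ``min_bins`` usable
    bins forms a single segment (with a logged warning).  Deterministic for a
    given ``seed``.
    """
    if profile.stage not in ("normalized", "smoothed"):
        raise ValueError(f"segment_cbs expects a smoothed profile, got {profile.stage!r}")
    rng = np.random.default_rng(seed)
    segments: list[Segment] = []

    for chrom in profile.grid.genome.names:
        idx = profile.grid.chrom_index(chrom)
        use = idx[profile.mask[idx]]
        if len(use) == 0:
            continue
        x = np.log2(np.maximum(profile.values[use], 1e-12))
        if len(use) < min_bins:
            log.warning("%s: only %d usable bins, single segment", chrom, len(use))
            pieces = [(0, len(use))]
        else:
            pieces = _segment_piece(x, 0, len(x), min_bins, alpha, n_permutations, rng)
        for lo, hi in pieces:
            sub = use[lo:hi]
            segments.append(Segment(
                chrom=chrom, first_bin=int(sub[0]), last_bin=int(sub[-1]),
                n_bins=hi - lo,
                median_value=float(np.median(profile.values[sub])),
                bin_index=sub))
    return Segmentation(sample_id=profile.sample_id, segments=segments)


def _segment_piece(x: np.ndarray, lo: int, hi: int, min_bins: int, alpha: float,
                   n_permutations: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Recursive CBS on x[lo:hi]; returns ordered (lo, hi) pieces."""
    n = hi - lo
    if n < 2 * min_bins:
        return [(lo, hi)]
    piece = x[lo:hi]
    # centre and scale by a robust sd so the permutation statistic is
    # location/scale free (location equivariance of the split statistic)
    centred = piece - np.mean(piece)
    diffs = np.diff(centred)
    sd = np.median(np.abs(diffs)) / (0.6745 * math.sqrt(2)) if len(diffs) else 0.0
    if sd <= 0:
        sd = np.std(centred)
    if sd <= 0:  # perfectly flat piece
        return [(lo, hi)]
    z = centred / sd
    stat, i, j = _best_arc(z)
    if stat < 0:
        return [(lo, hi)]
    # the split is not made when either circular piece (arc or complement)
    # would fall below the minimum segment size
    k = j - i
    if k < min_bins or n - k < min_bins:
        return [(lo, hi)]
    if not _split_significant(z, stat, alpha, n_permutations, rng):
        return [(lo, hi)]
    # a cut that would strand a terminal sliver below the minimum is dropped
    # (the sliver stays merged with the adjacent segment); the other cut of
    # the arc is kept
    cuts = sorted({c for c in (i, j)
                   if min_bins <= c <= n - min_bins})
    if not cuts:
        return [(lo, hi)]
    bounds = [0] + cuts + [n]
    out: list[tuple[int, int]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.extend(_segment_piece(x, lo + a, lo + b, min_bins, alpha, n_permutations, rng))
    return out


def apply_segment_medians(profile: CopyProfile, seg: Segmentation) -> CopyProfile:
    """Replace each usable bin's ratio by its segment's median ratio."""
    if seg.sample_id != profile.sample_id:
        log.warning("segmentation %s applied to profile %s", seg.sample_id, profile.sample_id)
    values = profile.values.copy()
    seen = np.zeros(profile.grid.n_bins, dtype=bool)
    for s in seg.segments:
        if s.bin_index.max() >= profile.grid.n_bins:
            raise IndexError("segment bin index out of range for this profile")
        values[s.bin_index] = s.median_value
        seen[s.bin_index] = True
    if not np.array_equal(seen, profile.mask):
        missing = int(np.sum(profile.mask & ~seen))
        if missing:
            raise ValueError(f"segmentation does not cover {missing} usable bins")
    return replace(profile, stage="segmented", values=values)
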