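# Methods

## Scope and model

`sccnv` estimates integer copy numbers from binned read depth of shallow
whole-genome sequencing of single, whole-genome-amplified (WGA) cells, and
aggregates per-cell calls into population mosaicism statistics.  The unit of
analysis is a fixed-width genomic bin (0.5, 1 or 2.5 Mb); read depth per bin
is treated as proportional to local copy number, modulated by a smooth GC
bias and by multiplicative, locus-specific WGA amplification noise.  Bins
overlapping hard-to-sequence regions (by default, half the bin or more) are
masked throughout — masked, not zeroed, so they cannot bend the GC fit.

Coordinates are 0-based half-open base pairs internally; reports print Mb to
one decimal.  The genome model is a GRCh38-like table of chromosome lengths
and centromere midpoints packaged as constants; any table and exclusion BED
can be substituted.  The published list of difficult-to-sequence regions is
not redistributable, so the default exclusion mask is the pericentromeric
±2.5 Mb of each chromosome.

## Per-cell chain

**GC normalization.** A lowess regression (span 0.3) of log2(count + 0.5)
on bin GC fraction over usable bins is subtracted and the profile re-centred
to genome median ratio 1.  The 0.5 pseudocount keeps zero-count bins
defined.  Zero-count bins at extreme GC (< 0.28 or > 0.68) are masked as
amplification drop-outs rather than read as losses.  The lowess fit is
robust to aberrations occupying a minority of bins; profiles in which most
of the genome is aberrant (chaotic cells) may show mild regional bias.  At
least 100 usable bins with reads are required.

**Outlier smoothing.** On log2 ratios per chromosome, a bin deviating from
the running median of its 10-bin window by more than 3 robust
(median-absolute-deviation-based) standard deviations is winsorized to the
running median ± 3 SD — but only if isolated: a neighbour co-deviating
beyond the same threshold marks a run, i.e. a potential CNV, which is never
eroded.  The operation is idempotent.

**Segmentation.** Circular binary segmentation, per chromosome, on log2
ratios.  Each recursion step finds the circular arc maximizing
|mean_in − mean_out| · sqrt(k(n−k)/n) over all arcs (ties: leftmost, then
shortest), and accepts the split when (a) both the arc and its complement
hold at least `min_bins` = 5 bins and (b) the permutation p-value is below
α = 0.05.  The permutation test permutes the (centred, robustly scaled)
piece, with sequential early stopping: sampling ends as soon as the
exceedance count reaches ⌈α·N⌉, which cannot change the accept/reject
decision.  A cut that would strand a terminal sliver of fewer than
`min_bins` bins is dropped individually (the sliver stays merged with the
adjacent segment) rather than vetoing the whole split — otherwise an
aberration ending within 5 bins of a telomere would suppress its own
detection.  Consequence: breakpoints closer than 5 bins to a chromosome end
are reported at the chromosome end.  Permutation count is explicit
configuration (the pipeline default is 2 000; the per-operation default is
10 000) and the generator is seeded, so segmentation is deterministic.  The
O(n²) arc scan is numba-compiled when numba is available, with an
equivalent vectorized numpy path otherwise.

After segmentation every usable bin is replaced by its segment's median
ratio (numpy median: mean of the two middle order statistics for even
segments).

**Copy scaling.** The scaling factor s (copies per unit median-normalized
ratio) minimizes SSE(s) = Σ_segments n_bins · (s·m − round(s·m))² on a grid
s ∈ [1.5, 3.0], step 0.001; ties are resolved toward s = 2.  The interval
brackets diploid-modal genomes and excludes the degenerate near-zero and
large-s solutions; it is configuration for other ploidies.  Weighting is by
segment size in bins (per-bin weighting would be equivalent after segment
medians; the SSE is defined on segments because those are the fitted
levels).  Because a continuous s is fitted and the per-segment values are
not rounded, a mosaic mixture (e.g. a p-arm lost in 71 % of cells of a bulk
sample) scales to a non-integer copy (≈ 1.29) — the diagnostic signature of
mosaicism in bulk data.

**Bin-size QC.** The clustering fraction is the share of usable bins whose
per-bin copy lies within the closed window ±0.25 of an integer in {1, 2, 3};
values near 0 or ≥ 4 never count.  It is computed on the smoothed,
pre-segment-median profile scaled by the fitted s — segment medians would
cluster trivially and defeat the check.  A bin size is admissible when the
fraction strictly exceeds its threshold (0.80 / 0.62 / 0.58 at
0.5 / 1 / 2.5 Mb); the smallest admissible size is used, else the cell is
excluded.  All fractions and thresholds are reported per cell.

**Calling.** Per-bin copies (after segment-median replacement, so runs align
with segment boundaries) are compared with the per-chromosome baseline:
autosomes 2; X and Y 1 in an XY cell; in an XX cell the X baseline is 2 and
Y is masked entirely.  Thresholds are deviations from baseline — +0.65 for
gains (relaxed to +0.55 at 2.5 Mb bins, where averaging compresses
amplitudes) and −0.65 for losses at every bin size — so losses remain
callable on the single-copy male X.  A maximal qualifying run becomes a call
when it holds ≥ 8 usable bins and spans ≥ 8 Mb (20 Mb at 2.5 Mb bins).
Masked bins inside a run bridge it without counting toward the 8.  Calls
covering ≥ 95 % of a chromosome's usable bins are whole-chromosome
(trisomy/monosomy); an endpoint coinciding with the outer edge of the
chromosome's first or last usable bin is terminal.

**Expected-karyotype subtraction and carrier status.** A call matches an
expected interval (e.g. the i(20q) arm loss or gain) when chromosome and
direction agree and reciprocal overlap is ≥ 0.5.  A cell is a carrier when
at least one call matches at least one expected interval — the either-arm
rule, chosen because arm events of an isochromosome can drop out of calling
individually while the cell still visibly carries the aberration.
Unmatched calls are "additional".

**Fragile sites.** Breakpoints are the outer bin edges of non-terminal call
ends (resolution one bin); terminal ends and whole-chromosome calls
contribute none.  Each breakpoint takes the nearest catalogued site:
`within` (inside the interval, distance 0), `proximal` (nearest boundary
≤ 2.5 Mb — one bin at the coarsest size), else `none`; ties go to the first
site in sorted order.  The catalogue is any BED4; a synthetic stand-in is
packaged for tests because the curated human fragile-site database is not
redistributable.

**Cohort summary.** Carrier fraction uses QC-passing ("analysed") cells as
denominator.  Additional calls are tabulated by class; cells with ≥ 4
aberrations are flagged complex and ≥ 10 chaotic.  Recurrence groups collect
calls sharing chromosome, direction and pairwise reciprocal overlap ≥ 0.5
across cells.  Bulk predictions use the mixture identity
(1−f)·c_base + f·c_carrier.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated; it emulates the statistical structure of WGA sWGS, not any
particular dataset.

* Per-bin relative rate r_i = c_i · (1 + slope·(gc_i − 0.40)) · a_i with
  copy c_i from the cell's karyotype, linear GC bias (default slope 1.0,
  i.e. ±10 % over a ±0.10 GC range) and a_i ~ Gamma(1/d, d) multiplicative
  amplification noise (marginally negative-binomial counts).  Counts are
  multinomial over usable bins.
* Per-cell totals ~ Normal(3.9 × 10⁶, 1.3 × 10⁶) truncated at 10⁵,
  matching typical per-cell sWGS yields.
* Quality tiers map to dispersions d = 0.002 / 0.021 / 0.074 / 0.42
  (high/mid/low/fail), calibrated once from the Gaussian window arithmetic
  of the QC metric so that tiers are typically analysable at 0.5 / 1 /
  2.5 Mb or fail QC, respectively.  Counts are generated on the 0.5 Mb grid
  and summed into coarser grids, so noise averages down with bin size as in
  resequenced data.
* Cohorts carry the isochromosome (20p copy 1, 20q copy 3) in exactly
  round(f·n) cells (default f = 40/56); each cell adds
  Poisson(0.5)-distributed extra CNVs with log-uniform sizes 8–100 Mb and
  copy change ±1, placed inside a single autosomal arm, never on the
  isochromosome's chromosome or the sex chromosomes, never overlapping each
  other, and at least 6 Mb clear of centromeres and telomeres — inside the
  masked pericentromere breakpoint localization is undefined, and within
  one minimum segment of a telomere a breakpoint is unresolvable by design,
  so truth placed there could not be recovered by any min-5-bin segmenter.
* Bulk samples are equal-weight mixtures of the member cells' rate vectors
  without per-cell amplification noise (bulk DNA is not WGA material).
* One seeded generator drives everything; same config + seed reproduces
  counts bit-exactly.

What the generator does **not** emulate: real mappability structure beyond
the binary exclusion mask, correlated (wave) noise along the genome,
GC-dependent dropout beyond the linear bias, replication-timing signal, or
sub-bin breakpoint placement.  Passing tests therefore demonstrate correct
recovery under the assumed noise model, not performance on any particular
sequencing platform.

## Numerical choices and edge cases

* Median-ratio normalization pins the modal (assumed diploid) state at
  ratio 1; genomes where the majority state is not the baseline will scale
  to that majority state.
* The robust SD inside CBS comes from the median absolute first difference
  (÷ 0.6745·√2); perfectly flat pieces fall back to the plain SD and, when
  still zero, are left unsplit.
* Chromosomes with fewer than `min_bins` usable bins form a single segment
  with a logged warning.
* QC windows are closed (|c − k| ≤ 0.25) and threshold comparisons strict
  (fraction > threshold), so a fraction exactly at a threshold fails.
* Grid search for s reports the full SSE curve for diagnostics; refining
  the step tenfold moves s by less than one coarse step.
* Per-cell, per-bin-size CBS seeds are derived from the run seed and the
  cell id, so results do not depend on the order in which cells or bin
  sizes are processed.

## Problem sizes used in the validation suite

The end-to-end checks run a 56-cell cohort (40 carriers, high/mid quality
tiers, 2 000 CBS permutations) on the full 24-chromosome grid — about three
minutes on one core — and verify carrier recovery within ±2 cells and
≥ 95 % recall of injected ≥ 12 Mb CNVs with outer-breakpoint error ≤ 2
bins.  Breakpoint recovery is scored on the union of overlapping
same-direction calls, since CBS may carve a borderline noise trough out of
the middle of a long aberration while still localizing its ends.  CBS is
additionally validated against an exhaustive least-squares single
changepoint oracle (200 two-level signals; ≥ 98 % boundary agreement within
one bin) and for α-control on pure noise (500 null profiles; excess-segment
rate ≤ 3α).

## Known limitations

* Sub-minimum aberrations (e.g. ~1 Mb recurrent amplicons) are invisible by
  construction of the calling thresholds.
* No subclonal deconvolution within a cell: each cell is one genome.
* The lowess GC fit assumes aberrations occupy a minority of bins; chaotic
  genomes can bias it regionally.
* Fragile-site annotation inherits one-bin breakpoint resolution; `within`
  versus `proximal` near site boundaries is correspondingly coarse.
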