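"""End-to-end orchestration: counts -> QC -> calls -> cohort report.

``run_cell`` executes the per-cell chain (GC normalization, outlier
smoothing, CBS, segment medians, copy scaling) at all configured bin sizes,
lets QC choose the smallest admissible bin size, and calls CNVs at that bin
size only.  ``run_cohort`` aggregates per-cell results into mosaicism
statistics.  Cells failing any stage are recorded and do not stop the run;
fractions use the analysed (QC-passing) cells as denominator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .calling import (GAIN_THRESHOLDS, LOSS_THRESHOLD, MIN_RUN_BINS, MIN_SIZES,
                      CNVCall, ExpectedKaryotype, call_cnvs, isochromosome_karyotype,
                      subtract_expected)
from .cohort import CohortSummary, bulk_expected_copy, mosaicism_fraction, recurrence_scan, tabulate_cohort
from .copynumber import ScaledProfile, expected_copy, fit_copy_scaling
from .fragile import BreakpointAnnotation, annotate_breakpoints, load_fragile_sites
from .genome import BinCounts, BinGrid, GenomeBuild, aggregate_counts, default_genome, make_bin_grid
from .normalization import gc_normalize, smooth_outliers
from .qc import DEFAULT_THRESHOLDS, QCResult, clustering_fraction, select_bin_size
from .segmentation import apply_segment_medians, segment_cbs

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genome: GenomeBuild = field(default_factory=default_genome)
    sex: str = "XY"
    bin_sizes: tuple[int, ...] = (500_000, 1_000_000, 2_500_000)
    alpha: float = 0.05
    min_bins: int = 5
    n_permutations: int = 2_000
    seed: int = 0
    gc_span: float = 0.3
    smoothing_window: int = 10
    trim_sd: float = 3.0
    qc_thresholds: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    gain_thresholds: dict[int, float] = field(default_factory=lambda: dict(GAIN_THRESHOLDS))
    loss_threshold: float = LOSS_THRESHOLD
    min_run_bins: int = MIN_RUN_BINS
    min_sizes: dict[int, int] = field(default_factory=lambda: dict(MIN_SIZES))
    expected: ExpectedKaryotype | None = None
    match_overlap: float = 0.5
    fragile_sites_path: str | None = None

    _grids: dict[int, BinGrid] = field(default_factory=dict, repr=False)

    def grid(self, bin_size: int) -> BinGrid:
        if bin_size not in self._grids:
            self._grids[bin_size] = make_bin_grid(self.genome, bin_size)
        return self._grids[bin_size]

    def expected_or_default(self) -> ExpectedKaryotype:
        return self.expected or isochromosome_karyotype(self.genome)

    def to_dict(self) -> dict:
        return {
            "sex": self.sex, "bin_sizes": list(self.bin_sizes), "alpha": self.alpha,
            "min_bins": self.min_bins, "n_permutations": self.n_permutations,
            "seed": self.seed, "gc_span": self.gc_span,
            "smoothing_window": self.smoothing_window, "trim_sd": self.trim_sd,
            "qc_thresholds": {str(k): v for k, v in self.qc_thresholds.items()},
            "gain_thresholds": {str(k): v for k, v in self.gain_thresholds.items()},
            "loss_threshold": self.loss_threshold, "min_run_bins": self.min_run_bins,
            "min_sizes": {str(k): v for k, v in self.min_sizes.items()},
            "match_overlap": self.match_overlap,
            "fragile_sites_path": self.fragile_sites_path,
        }


@dataclass
class CellResult:
    cell_id: str
    status: str                        # "ok" | "fail" | "error"
    qc: QCResult | None = None
    chosen_bin_size: int | None = None
    scaled: ScaledProfile | None = None
    calls: list[CNVCall] = field(default_factory=list)
    matched: list[CNVCall] = field(default_factory=list)
    additional: list[CNVCall] = field(default_factory=list)
    annotations: list[BreakpointAnnotation] = field(default_factory=list)
    error: str = ""

    @property
    def analysed(self) -> bool:
        return self.status == "ok"


def _cell_seed(base_seed: int, cell_id: str, bin_size: int) -> int:
    h = 0
    for ch in f"{cell_id}:{bin_size}":
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return (base_seed * 7_919 + h) % 2_147_483_647


def scale_at_bin_size(counts: BinCounts, config: RunConfig):
    """Run normalization, smoothing, CBS, segment medians and copy scaling
    for one cell at one bin size.  Returns (scaled, smoothed profile)."""
    profile = gc_normalize(counts, span=config.gc_span)
    smoothed = smooth_outliers(profile, trim_sd=config.trim_sd,
                               smoothing_window=config.smoothing_window)
    seg = segment_cbs(smoothed, alpha=config.alpha, min_bins=config.min_bins,
                      n_permutations=config.n_permutations,
                      seed=_cell_seed(config.seed, counts.sample_id, counts.grid.bin_size))
    segmented = apply_segment_medians(smoothed, seg)
    return fit_copy_scaling(segmented, seg), smoothed


def run_cell(counts: BinCounts, config: RunConfig,
             fragile_sites=None) -> CellResult:
    """Per-cell pipeline from fine-grid counts (smallest configured bin size).

    Coarser bin sizes are derived by summing the fine-grid counts.  QC
    fractions are scored on per-bin copies of the smoothed (pre-median)
    profile; calling runs only at the QC-chosen bin size.
    """
    cell_id = counts.sample_id
    try:
        fractions: dict[int, float] = {}
        scaled_by_size: dict[int, ScaledProfile] = {}
        for bin_size in sorted(config.bin_sizes):
            cts = counts if bin_size == counts.grid.bin_size else \
                aggregate_counts(counts, config.grid(bin_size))
            scaled, smoothed = scale_at_bin_size(cts, config)
            # QC is scored on smoothed per-bin values scaled into copy space
            from dataclasses import replace

            qc_profile = replace(scaled, profile=replace(
                smoothed, stage="scaled",
                values=smoothed.values * scaled.scaling_factor))
            fractions[bin_size] = clustering_fraction(qc_profile)
            scaled_by_size[bin_size] = scaled
        qc = select_bin_size(fractions, config.qc_thresholds, sample_id=cell_id)
        if not qc.passed:
            return CellResult(cell_id=cell_id, status="fail", qc=qc)

        chosen = qc.chosen_bin_size
        scaled = scaled_by_size[chosen]
        baseline = expected_copy(config.genome, config.sex)
        calls = call_cnvs(scaled, baseline,
                          gain_thresholds=config.gain_thresholds,
                          loss_threshold=config.loss_threshold,
                          min_run_bins=config.min_run_bins,
                          min_sizes=config.min_sizes)
        matched, additional = subtract_expected(calls, config.expected_or_default(),
                                                config.match_overlap)
        annotations = annotate_breakpoints(calls, fragile_sites) if fragile_sites else []
        return CellResult(cell_id=cell_id, status="ok", qc=qc, chosen_bin_size=chosen,
                          scaled=scaled, calls=calls, matched=matched,
                          additional=additional, annotations=annotations)
    except Exception as exc:  # cohort runs continue past broken cells
        log.warning("cell %s failed: %s", cell_id, exc)
        return CellResult(cell_id=cell_id, status="error", error=str(exc))


@dataclass
class CohortResult:
    cells: list[CellResult]
    n_analysed: int
    n_failed: int
    carrier_count: int
    carrier_fraction: float
    summary: CohortSummary
    recurrent_groups: list[list[CNVCall]]
    bulk_predictions: dict[str, float]


def run_cohort(counts_list: list[BinCounts], config: RunConfig,
               out_dir=None) -> CohortResult:
    """Run every cell, then aggregate mosaicism statistics over analysed cells."""
    if not counts_list:
        raise ValueError("empty cohort")
    sites = load_fragile_sites(config.fragile_sites_path) if config.fragile_sites_path else None
    cells = [run_cell(c, config, fragile_sites=sites) for c in counts_list]
    analysed = [c for c in cells if c.analysed]
    log.info("attrition: %d cells in, %d analysable, %d failed QC or errored",
             len(cells), len(analysed), len(cells) - len(analysed))
    if not analysed:
        raise ValueError("no cell passed QC")

    expected = config.expected_or_default()
    calls_by_cell = {c.cell_id: c.calls for c in analysed}
    n_carriers, n_cells, fraction = mosaicism_fraction(calls_by_cell, expected,
                                                       config.match_overlap)
    additional_by_cell = {c.cell_id: c.additional for c in analysed}
    summary = tabulate_cohort(additional_by_cell, n_cells_analysed=n_cells)
    recurrent = recurrence_scan([c for r in analysed for c in r.additional],
                                config.match_overlap)
    predictions = {
        f"{chrom}:{start}-{end}:{direction}": bulk_expected_copy(
            fraction, 1.0 if direction == "loss" else 3.0)
        for chrom, start, end, direction in expected.intervals}

    result = CohortResult(cells=cells, n_analysed=n_cells,
                          n_failed=len(cells) - len(analysed),
                          carrier_count=n_carriers, carrier_fraction=fraction,
                          summary=summary, recurrent_groups=recurrent,
                          bulk_predictions=predictions)
    if out_dir is not None:
        write_cohort_report(result, config, out_dir)
    return result


def write_cohort_report(result: CohortResult, config: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.per_cell.to_csv(out / "additional_cnvs.tsv", sep="\t", index=False)
    qc_rows = []
    for c in result.cells:
        row = {"sample_id": c.cell_id, "status": c.status}
        if c.qc is not None:
            for b, f in c.qc.fractions.items():
                row[f"fraction_{b / 1e6:g}Mb"] = round(f, 4)
            row["chosen"] = c.qc.chosen_bin_size or "FAIL"
        qc_rows.append(row)
    import pandas as pd

    pd.DataFrame(qc_rows).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    report = {
        "n_cells_in": len(result.cells),
        "n_analysed": result.n_analysed,
        "n_failed": result.n_failed,
        "carrier_count": result.carrier_count,
        "carrier_fraction": result.carrier_fraction,
        "n_cells_with_additional": result.summary.n_cells_with_additional,
        "n_additional_cnvs": result.summary.n_additional_cnvs,
        "counts_by_class": result.summary.counts_by_class,
        "bulk_predictions": result.bulk_predictions,
        "config": config.to_dict(),
    }
    (out / "cohort_report.json").write_text(json.dumps(report, indent=2))
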