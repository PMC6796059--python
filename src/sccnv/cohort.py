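"""Cohort-level mosaicism statistics and bulk copy-number prediction.

Aggregates per-cell CNV calls into carrier fractions, class counts and
recurrence groups, and predicts the copy number a bulk (population-average)
experiment would report for a mosaic aberration:

    bulk copy = (1 - f) * c_base + f * c_carrier

where ``f`` is the carrier fraction.  A 71% carrier fraction for a one-copy
arm loss therefore predicts a bulk arm copy of 2 - 0.714 = 1.29 — the reason
mosaic aberrations fail to reach integer copies in bulk profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calling import CNVCall, ExpectedKaryotype, matches_expected, reciprocal_overlap
from .fragile import BreakpointAnnotation
from .genome import MB

COMPLEX_MIN_ABERRATIONS = 4
CHAOTIC_MIN_ABERRATIONS = 10


@dataclass
class CohortSummary:
    n_cells_analysed: int
    n_cells_with_additional: int
    n_additional_cnvs: int
    counts_by_class: dict[str, int]
    complex_cells: list[str]        # >= 4 aberrations
    chaotic_cells: list[str]        # >= 10 aberrations
    per_cell: pd.DataFrame = field(repr=False, default=None)


@dataclass(frozen=True)
class BulkPrediction:
    region: str
    carrier_fraction: float
    carrier_copy: float
    baseline_copy: float

    @property
    def predicted_copy(self) -> float:
        return (1 - self.carrier_fraction) * self.baseline_copy \
            + self.carrier_fraction * self.carrier_copy


def mosaicism_fraction(calls_by_cell: dict[str, list[CNVCall]],
                       query: ExpectedKaryotype,
                       min_overlap: float = 0.5) -> tuple[int, int, float]:
    """(n_carriers, n_cells, fraction): a cell is a carrier when at least one
    of its calls matches at least one query interval (either-arm rule for
    isochromosomes)."""
    if not calls_by_cell:
        raise ValueError("empty cohort")
    n_carriers = sum(
        1 for calls in calls_by_cell.values()
        if any(matches_expected(c, query, min_overlap) for c in calls))
    n_cells = len(calls_by_cell)
    return n_carriers, n_cells, n_carriers / n_cells


def bulk_expected_copy(f: float, c_carrier: float, c_base: float = 2.0) -> float:
    """Population-mixture copy number: (1-f)*c_base + f*c_carrier."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"carrier fraction {f} outside [0, 1]")
    return (1 - f) * c_base + f * c_carrier


def tabulate_cohort(calls_by_cell: dict[str, list[CNVCall]],
                    n_cells_analysed: int | None = None) -> CohortSummary:
    """Tabulate (additional) calls per cell: class counts, burden and
    complex/chaotic flags.

    ``calls_by_cell`` should already contain only the calls of interest
    (e.g. after subtracting the expected karyotype); cells without calls may
    be present with empty lists and count toward the denominator.
    """
    if n_cells_analysed is None:
        n_cells_analysed = len(calls_by_cell)
    rows = []
    counts = {"segmental gain": 0, "segmental loss": 0, "trisomy": 0, "monosomy": 0}
    complex_cells, chaotic_cells = [], []
    n_total = 0
    for cell_id, calls in calls_by_cell.items():
        for c in calls:
            counts[c.label] += 1
            n_total += 1
            rows.append({
                "cell": cell_id, "chrom": c.chrom,
                "start_mb": round(c.start / MB, 1), "end_mb": round(c.end / MB, 1),
                "size_mb": c.size_mb, "direction": c.direction, "class": c.cnv_class,
                "terminal": ("T" if c.terminal else "-"),
                "mean_copy": round(c.mean_copy, 2) if np.isfinite(c.mean_copy) else "",
            })
        if len(calls) >= CHAOTIC_MIN_ABERRATIONS:
            chaotic_cells.append(cell_id)
        if len(calls) >= COMPLEX_MIN_ABERRATIONS:
            complex_cells.append(cell_id)
    n_with = sum(1 for calls in calls_by_cell.values() if calls)
    return CohortSummary(
        n_cells_analysed=n_cells_analysed, n_cells_with_additional=n_with,
        n_additional_cnvs=n_total, counts_by_class=counts,
        complex_cells=complex_cells, chaotic_cells=chaotic_cells,
        per_cell=pd.DataFrame(rows))


def recurrence_scan(calls: list[CNVCall],
                    min_overlap: float = 0.5) -> list[list[CNVCall]]:
    """Group concordant calls across cells: same chromosome and direction,
    reciprocal overlap >= ``min_overlap``.  Returns groups of size >= 2."""
    groups: list[list[CNVCall]] = []
    for call in calls:
        placed = False
        for group in groups:
            ref = group[0]
            if (call.chrom == ref.chrom and call.direction == ref.direction
                    and all(reciprocal_overlap(call.start, call.end, g.start, g.end)
                            >= min_overlap for g in group)):
                group.append(call)
                placed = True
                break
        if not placed:
            groups.append([call])
    return [g for g in groups if len(g) >= 2]


# ---------------------------------------------------------------------------
# packaged per-cell CNV table fixture

def load_reference_cnv_table(path=None) -> tuple[dict[str, list[CNVCall]],
                                                 list[BreakpointAnnotation]]:
    """Load the packaged per-cell CNV table (13 cells, 50 CNVs).

    The TSV transcribes the published per-cell call list of the VUB02_iso20
    line — cell, chromosome, interval (Mb), direction, class, terminal flags
    and fragile-site assignment per non-terminal end.  Returns calls grouped
    by cell plus the breakpoint annotations implied by the fragile-site
    columns ('.' marks a terminal end with no breakpoint).
    """
    if path is None:
        path = resources.files("sccnv.data") / "table1_cnvs.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"cell": str}, keep_default_na=False)

    calls_by_cell: dict[str, list[CNVCall]] = {}
    annotations: list[BreakpointAnnotation] = []
    for row in df.itertuples():
        start = int(round(float(row.start_mb) * MB))
        end = int(round(float(row.end_mb) * MB))
        call = CNVCall(
            cell_id=row.cell, chrom=row.chrom, start=start, end=end,
            direction=row.direction, mean_copy=float("nan"),
            n_bins=0, cnv_class=row.cnv_class,
            start_terminal=bool(int(row.start_terminal)),
            end_terminal=bool(int(row.end_terminal)),
            terminal=bool(int(row.start_terminal)) or bool(int(row.end_terminal)))
        calls_by_cell.setdefault(row.cell, []).append(call)
        for which, pos, site in (("start", start, row.fragile_start),
                                 ("end", end, row.fragile_end)):
            if site == ".":  # terminal end: not a breakpoint
                continue
            status = "none" if site == "none" else "within"
            annotations.append(BreakpointAnnotation(
                cell_id=row.cell, chrom=row.chrom, breakpoint=pos, which_end=which,
                status=status, site_name="" if status == "none" else site, distance=0))
    return calls_by_cell, annotations
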