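"""Annotation of CNV breakpoints against a fragile-site catalogue.

Each non-terminal breakpoint (the outer bin edge of a call at either end) is
related to the nearest catalogued fragile site: ``within`` when the
coordinate lies inside the site interval, ``proximal`` when the nearest
boundary is within 2.5 Mb (one bin at the coarsest bin size), else ``none``.
Terminal ends — chromosome termini of terminal or whole-chromosome calls —
are not breakpoints and are excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .calling import CNVCall
from .genome import MB

PROXIMITY_BP = int(2.5 * MB)


@dataclass(frozen=True)
class FragileSite:
    name: str
    chrom: str
    start: int
    end: int


@dataclass(frozen=True)
class BreakpointAnnotation:
    cell_id: str
    chrom: str
    breakpoint: int       # bp
    which_end: str        # "start" | "end"
    status: str           # "within" | "proximal" | "none"
    site_name: str        # "" when status is "none"
    distance: int         # bp to nearest site boundary; 0 when within


def load_fragile_sites(path) -> list[FragileSite]:
    """Read a BED4 fragile-site file (chrom, start, end, name; 0-based
    half-open), validate rows, sort per chromosome and merge overlapping
    records that share a name."""
    sites: list[FragileSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            chrom, s, e, name = parts[:4]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            sites.append(FragileSite(name=name, chrom=chrom, start=start, end=end))

    merged: list[FragileSite] = []
    for site in sorted(sites, key=lambda x: (x.chrom, x.start, x.end)):
        prev = merged[-1] if merged else None
        if (prev and prev.chrom == site.chrom and prev.name == site.name
                and site.start <= prev.end):
            merged[-1] = FragileSite(prev.name, prev.chrom, prev.start,
                                     max(prev.end, site.end))
        else:
            merged.append(site)
    return merged


def _nearest_site(pos: int, sites: list[FragileSite]) -> tuple[FragileSite | None, int]:
    """Nearest site to a coordinate on one chromosome (sites sorted by start).

    Distance is 0 inside a site; ties broken by first site in sorted order.
    """
    best: FragileSite | None = None
    best_d = -1
    for site in sites:
        if site.start <= pos < site.end:
            return site, 0
        d = site.start - pos if pos < site.start else pos - site.end + 1
        if best is None or d < best_d:
            best, best_d = site, d
    return best, best_d


def annotate_breakpoints(calls: list[CNVCall], sites: list[FragileSite],
                         proximity: int = PROXIMITY_BP) -> list[BreakpointAnnotation]:
    """Annotate every non-terminal breakpoint of every call.

    Breakpoint coordinates are the call's outer bin edges, so resolution is
    one bin.  Whole-chromosome calls contribute no breakpoints.
    """
    by_chrom: dict[str, list[FragileSite]] = {}
    for s in sorted(sites, key=lambda x: (x.chrom, x.start)):
        by_chrom.setdefault(s.chrom, []).append(s)

    annotations: list[BreakpointAnnotation] = []
    for call in calls:
        if call.cnv_class == "whole_chromosome":
            continue
        ends = []
        if not call.start_terminal:
            ends.append(("start", call.start))
        if not call.end_terminal:
            ends.append(("end", call.end))
        for which, pos in ends:
            site, dist = _nearest_site(pos, by_chrom.get(call.chrom, []))
            if site is not None and dist == 0:
                status, name = "within", site.name
            elif site is not None and dist <= proximity:
                status, name = "proximal", site.name
            else:
                status, name, dist = "none", "", max(dist, 0)
            annotations.append(BreakpointAnnotation(
                cell_id=call.cell_id, chrom=call.chrom, breakpoint=pos,
                which_end=which, status=status, site_name=name, distance=int(dist)))
    return annotations


def fragile_fraction(annotations: list[BreakpointAnnotation]) -> tuple[int, int, float]:
    """(n_within, n_breakpoints, fraction within); proximal counted separately
    via :func:`proximal_count`."""
    n = len(annotations)
    if n == 0:
        raise ValueError("no breakpoints to summarize")
    within = sum(1 for a in annotations if a.status == "within")
    return within, n, within / n


def proximal_count(annotations: list[BreakpointAnnotation]) -> int:
    return sum(1 for a in annotations if a.status == "proximal")


def annotations_to_frame(annotations: list[BreakpointAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": a.cell_id, "chrom": a.chrom, "breakpoint_bp": a.breakpoint,
        "which_end": a.which_end, "status": a.status, "site": a.site_name,
        "distance": a.distance,
    } for a in annotations])
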