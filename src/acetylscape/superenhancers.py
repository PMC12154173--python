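"""ROSE-style super-enhancer calling.

Peaks are stitched when their gap is at most 12.5 kb, after removing
promoter-proximal signal (peaks fully inside a TSS +/- 2.5 kb window are
dropped; partially overlapping peaks are trimmed so only distal signal
contributes). Stitched regions are ranked by aggregate signal; both axes of
the rank/signal curve are rescaled to [0, 1] and the cutoff is placed where
a line of slope 1 is tangent to the rescaled curve - the standard
tangent-slope-one elbow. Regions above the cutoff are super-enhancers (SE),
the rest typical enhancers (TE).

TSS exclusion applies only at the constituent-peak stage: stitched spans
that end up covering a TSS are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval, Peak, PeakSet

__all__ = [
    "StitchedRegion",
    "SuperEnhancerCall",
    "stitch",
    "rank_and_cut",
    "assign_genes",
    "reproducible_ses",
    "filter_differential_overlaps",
]

STITCH_DISTANCE = 12_500
TSS_EXCLUSION = 2_500


@dataclass
class StitchedRegion:
    interval: GenomicInterval
    constituents: list[str]
    total_signal: float
    rank: int = 0  # 1 = highest signal, assigned by rank_and_cut


@dataclass
class SuperEnhancerCall:
    region: StitchedRegion
    label: str  # "SE" or "TE"
    cutoff_signal: float
    associated_genes: list[str] = field(default_factory=list)
    assigned: bool = True


def _subtract_windows(start: int, end: int, windows: list[tuple[int, int]]):
    """Segments of [start, end) not covered by any window."""
    segments = [(start, end)]
    for ws, we in windows:
        nxt = []
        for s, e in segments:
            if we <= s or ws >= e:
                nxt.append((s, e))
                continue
            if s < ws:
                nxt.append((s, ws))
            if we < e:
                nxt.append((we, e))
        segments = nxt
        if not segments:
            break
    return segments


def stitch(ps: PeakSet, genes: Sequence[GeneModel],
           stitch_dist: int = STITCH_DISTANCE,
           tss_excl: int = TSS_EXCLUSION) -> list[StitchedRegion]:
    """Stitch peaks within ``stitch_dist`` bp after TSS-window exclusion.

    Peaks fully contained in any [tss - tss_excl, tss + tss_excl] window are
    removed; peaks partially overlapping a window are trimmed to their
    distal remainder with signal scaled by the retained fraction. The gap is
    measured end-to-next-start; merging is transitive. Idempotent: stitching
    the output again changes nothing.
    """
    tss_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(
            (g.tss - tss_excl, g.tss + tss_excl))

    kept: list[Peak] = []
    for p in ps:
        windows = [
            w for w in tss_by_chrom.get(p.interval.chrom, [])
            if w[0] < p.interval.end and p.interval.start < w[1]
        ]
        if not windows:
            kept.append(p)
            continue
        segments = _subtract_windows(p.interval.start, p.interval.end, windows)
        orig_len = p.interval.length
        for j, (s, e) in enumerate(segments):
            suffix = "" if len(segments) == 1 else f"/{j}"
            kept.append(Peak(
                GenomicInterval(p.interval.chrom, s, e),
                p.id + suffix,
                p.signal * (e - s) / orig_len,
                p.sample,
            ))

    kept.sort(key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    regions: list[StitchedRegion] = []
    cur: list[Peak] = []

    def flush():
        if not cur:
            return
        regions.append(StitchedRegion(
            GenomicInterval(cur[0].interval.chrom,
                            min(p.interval.start for p in cur),
                            max(p.interval.end for p in cur)),
            [p.id for p in cur],
            float(sum(p.signal for p in cur)),
        ))

    cur_end = None
    for p in kept:
        if cur and (p.interval.chrom != cur[0].interval.chrom
                    or p.interval.start - cur_end > stitch_dist):
            flush()
            cur = []
        cur.append(p)
        cur_end = p.interval.end if cur_end is None or len(cur) == 1 \
            else max(cur_end, p.interval.end)
    flush()
    return regions


def rank_and_cut(regions: Sequence[StitchedRegion]) -> list[SuperEnhancerCall]:
    """Rank stitched regions by signal and split SE/TE at the curve elbow.

    Regions are sorted ascending by total signal; rank and signal are each
    rescaled to [0, 1] and the cutoff is placed at the tangency point of a
    slope-1 line with the rescaled curve - the point minimizing the number
    of curve points strictly below the slope-1 line through it, which is
    where the curve's slope passes 1. SE means strictly above the cutoff
    signal. If all signals are equal (no elbow on a linear curve) no region
    is called SE and a warning is emitted. Rank 1 is the highest-signal
    region.
    """
    regions = sorted(regions, key=lambda r: (r.total_signal,
                                             r.interval.chrom, r.interval.start))
    n = len(regions)
    if n == 0:
        return []
    signals = np.array([r.total_signal for r in regions], dtype=float)
    for i, r in enumerate(regions):
        r.rank = n - i
    if n < 2 or signals[-1] == signals[0]:
        warnings.warn("degenerate ranking (constant signal): no super-enhancers")
        cutoff = signals[-1]
        return [SuperEnhancerCall(r, "TE", float(cutoff)) for r in regions]
    x = np.arange(n) / (n - 1)
    y = (signals - signals[0]) / (signals[-1] - signals[0])
    # tangent-slope-1 criterion: the cutoff is the point whose slope-1 line
    # leaves the fewest curve points strictly below it (the tangency point
    # where the rescaled curve's slope passes 1)
    below = (y[None, :] < y[:, None] + (x[None, :] - x[:, None])).sum(axis=1)
    cutoff = signals[int(np.argmin(below))]
    return [
        SuperEnhancerCall(r, "SE" if r.total_signal > cutoff else "TE",
                          float(cutoff))
        for r in regions
    ]


def _region_tss_distance(region: GenomicInterval, tss: int) -> int:
    if region.start <= tss < region.end:
        return 0
    return min(abs(tss - region.start), abs(tss - (region.end - 1)))


def assign_genes(calls: Sequence[SuperEnhancerCall], genes: Sequence[GeneModel],
                 within: int | None = None) -> list[SuperEnhancerCall]:
    """Associate each region with the gene whose TSS is nearest.

    Distance is 0 when the TSS lies inside the region; ties break toward the
    lower gene_id. With ``within`` set (e.g. 50_000), every gene whose TSS
    lies within that distance is appended after the nearest one. Regions on
    chromosomes without genes are flagged unassigned.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for c in calls:
        gs = by_chrom.get(c.region.interval.chrom)
        if not gs:
            c.associated_genes = []
            c.assigned = False
            continue
        dists = sorted(
            (( _region_tss_distance(c.region.interval, g.tss), g.gene_id) for g in gs)
        )
        nearest = dists[0][1]
        assoc = [nearest]
        if within is not None:
            assoc += [gid for d, gid in dists[1:] if d <= within]
        c.associated_genes = assoc
        c.assigned = True
    return list(calls)


def reproducible_ses(calls_d1: Sequence[SuperEnhancerCall],
                     calls_d2: Sequence[SuperEnhancerCall]):
    """Donor-1 SEs overlapping (>= 1 bp) a donor-2 SE, plus unique genes.

    Returns ``(ses, unique_genes)`` where ``unique_genes`` deduplicates the
    associated-gene lists across the retained set (sorted for determinism).
    """
    d2 = [c.region.interval for c in calls_d2 if c.label == "SE"]
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in d2:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    kept = []
    for c in calls_d1:
        if c.label != "SE":
            continue
        for iv in by_chrom.get(c.region.interval.chrom, []):
            if c.region.interval.overlaps(iv):
                kept.append(c)
                break
    genes = sorted({g for c in kept for g in c.associated_genes})
    return kept, genes


def filter_differential_overlaps(calls: Sequence[SuperEnhancerCall],
                                 diff_peaks: PeakSet) -> list[SuperEnhancerCall]:
    """Optional filter removing calls that overlap differential peaks.

    Off by default in the pipeline; provided because some downstream
    workflows exclude enhancers confounded by differential enrichment.
    """
    by_chrom = {}
    for p in diff_peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    out = []
    for c in calls:
        if any(c.region.interval.overlaps(iv)
               for iv in by_chrom.get(c.region.interval.chrom, [])):
            continue
        out.append(c)
    return out


def calls_to_dataframe(calls: Sequence[SuperEnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [c.region.interval.chrom for c in calls],
        "start": [c.region.interval.start for c in calls],
        "end": [c.region.interval.end for c in calls],
        "rank": [c.region.rank for c in calls],
        "total_signal": [c.region.total_signal for c in calls],
        "label": [c.label for c in calls],
        "cutoff_signal": [c.cutoff_signal for c in calls],
        "n_constituents": [len(c.region.constituents) for c in calls],
        "associated_genes": [",".join(c.associated_genes) for c in calls],
    })
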