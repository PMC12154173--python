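"""Integrative analytics linking acetylation dynamics to transcription.

This module carries the headline analyses: exclusive attribution of
differential regions to TSS / super-enhancer / typical-enhancer / other
compartments, strand-oriented TSS metaprofiles with area-under-curve
reduction summaries, per-gene enhancer landscapes, SE-hypoacetylation
rates, per-compartment linkage of hypoacetylated regions to downregulated
genes, the four-way epigenetic explanation of downregulation, and the
strongest-peak origin analysis of hypoacetylation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    distance_bin,
    nearest_tss_table,
)
from .superenhancers import StitchedRegion, SuperEnhancerCall

__all__ = [
    "TssProfile",
    "AucRecord",
    "attribute_regions",
    "composition_fractions",
    "tss_metaprofile",
    "auc_reduction",
    "enhancer_landscape",
    "se_hypo_fraction",
    "downreg_link_rate",
    "explain_downregulation",
    "top_peak_origin",
]

TSS_WINDOW = 5_000
EXPLANATION_CLASSES = ("TSS_only", "TSS_and_SE", "SE_only", "unexplained")


@dataclass
class TssProfile:
    """Average signal in fixed bins around the TSS, strand-oriented.

    ``bin_centers`` run from -window to +window in gene-relative
    orientation (negative = upstream); ``values`` are mean per-bp signal
    density over the gene set.
    """

    gene_set: str
    timepoint: str
    bin_centers: np.ndarray
    values: np.ndarray
    n_genes: int

    def auc(self) -> float:
        binsize = float(self.bin_centers[1] - self.bin_centers[0]) \
            if len(self.bin_centers) > 1 else 1.0
        return float(np.trapezoid(self.values, dx=binsize))


@dataclass
class AucRecord:
    gene_set: str
    timepoint: str
    auc: float
    reduction_vs_baseline: float | None  # percent; None when baseline AUC is 0


# ---------------------------------------------------------------------------
# Region attribution (donut composition)


def _spans_by_chrom(regions) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for r in regions:
        iv = r.interval if isinstance(r, StitchedRegion) else r.region.interval
        out.setdefault(iv.chrom, []).append(iv)
    return out


def attribute_regions(peaks: PeakSet, se_calls, te_calls,
                      genes: Sequence[GeneModel],
                      tss_window: int = TSS_WINDOW,
                      precedence: tuple = ("TSS", "SE", "TE")) -> pd.DataFrame:
    """Attribute each peak to exactly one compartment.

    Default precedence TSS > SE > TE > other: a peak whose midpoint lies
    within +/- ``tss_window`` of any TSS is "TSS"; otherwise overlap with an
    SE span wins over a TE span; anything else is "other". Also carries the
    nearest-TSS gene and distance bin for each peak.
    """
    nt = nearest_tss_table(peaks, genes)
    se_spans = _spans_by_chrom(se_calls)
    te_spans = _spans_by_chrom(te_calls)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, [])
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
    tss_by_chrom = {c: np.asarray(v, dtype=float) for c, v in tss_by_chrom.items()}

    cats = []
    for p in peaks:
        mid = p.interval.midpoint
        chrom = p.interval.chrom
        checks = {
            "TSS": lambda: chrom in tss_by_chrom
            and np.abs(tss_by_chrom[chrom] - mid).min() <= tss_window,
            "SE": lambda: any(p.interval.overlaps(iv)
                              for iv in se_spans.get(chrom, [])),
            "TE": lambda: any(p.interval.overlaps(iv)
                              for iv in te_spans.get(chrom, [])),
        }
        cat = "other"
        for name in precedence:
            if checks[name]():
                cat = name
                break
        cats.append(cat)
    out = nt.copy()
    out["category"] = cats
    return out


def composition_fractions(attribution: pd.DataFrame) -> dict:
    """Fraction of peaks per compartment; sums to 1 over a non-empty set."""
    if len(attribution) == 0:
        return {}
    frac = attribution["category"].value_counts(normalize=True)
    return {c: float(frac.get(c, 0.0)) for c in ("TSS", "SE", "TE", "other")}


# ---------------------------------------------------------------------------
# TSS metaprofiles and AUC


def tss_metaprofile(peaks: PeakSet, genes: Sequence[GeneModel],
                    gene_ids: Sequence[str], label: str = "",
                    window: int = TSS_WINDOW, binsize: int = 100,
                    timepoint: str = "") -> TssProfile:
    """Average per-bp signal density in bins of a +/- window around the TSS.

    Each peak contributes its signal spread uniformly over its interval
    (density = signal / length); each gene's profile is oriented by strand
    so that negative bins are upstream. Genes lacking any overlapping
    signal contribute zeros. ``window`` must be a multiple of ``binsize``.
    """
    if window % binsize != 0:
        raise ValueError("window must be a multiple of binsize")
    wanted = [g for g in genes if g.gene_id in set(gene_ids)]
    if not wanted:
        raise ValueError("empty gene set for metaprofile")
    nbins = 2 * window // binsize
    total = np.zeros(nbins)
    by_chrom = peaks.by_chrom()
    for g in wanted:
        lo, hi = g.tss - window, g.tss + window
        prof = np.zeros(nbins)
        for p in by_chrom.get(g.chrom, []):
            if p.interval.end <= lo or p.interval.start >= hi:
                continue
            density = p.signal / p.interval.length
            # distribute over the bins this peak overlaps
            s = max(p.interval.start, lo)
            e = min(p.interval.end, hi)
            b0 = (s - lo) // binsize
            b1 = (e - 1 - lo) // binsize
            for b in range(b0, b1 + 1):
                bs, be = lo + b * binsize, lo + (b + 1) * binsize
                ov = min(e, be) - max(s, bs)
                if ov > 0:
                    prof[b] += density * ov / binsize
        if g.strand == "-":
            prof = prof[::-1]
        total += prof
    centers = np.arange(-window + binsize / 2, window, binsize)
    return TssProfile(label, timepoint, centers, total / len(wanted), len(wanted))


def auc_reduction(profiles: dict, baseline_key="0h") -> list[AucRecord]:
    """Trapezoidal AUC per profile and percent reduction vs baseline.

    ``profiles`` maps timepoint -> :class:`TssProfile` for one gene set.
    reduction = 100 * (1 - auc_t / auc_0); negative values (gains) are
    reported signed. A zero baseline AUC flags every reduction undefined.
    """
    if baseline_key not in profiles:
        raise ValueError(f"baseline profile {baseline_key!r} missing")
    base = profiles[baseline_key].auc()
    records = []
    for tp, prof in profiles.items():
        a = prof.auc()
        red = None if base == 0 else 100.0 * (1.0 - a / base)
        records.append(AucRecord(prof.gene_set, tp, a, red))
    return records


# ---------------------------------------------------------------------------
# Enhancer landscape


def enhancer_landscape(gene_id: str, peaks: PeakSet,
                       genes: Sequence[GeneModel],
                       tss_window: int = TSS_WINDOW) -> PeakSet:
    """All non-TSS peaks assigned (by nearest TSS) to a gene.

    A peak belongs to the landscape when its nearest TSS is this gene's and
    its midpoint lies outside every +/- ``tss_window`` TSS window.
    """
    if gene_id not in {g.gene_id for g in genes}:
        raise KeyError(f"unknown gene {gene_id!r}")
    nt = nearest_tss_table(peaks, genes)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_by_chrom = {c: np.asarray(v, float) for c, v in tss_by_chrom.items()}
    keep = []
    for p, gid in zip(peaks, nt["gene_id"]):
        if gid != gene_id:
            continue
        arr = tss_by_chrom.get(p.interval.chrom)
        if arr is not None and np.abs(arr - p.interval.midpoint).min() <= tss_window:
            continue
        keep.append(p.id)
    return peaks.subset(keep)


# ---------------------------------------------------------------------------
# SE / downregulation linkage


def se_hypo_fraction(se_calls: Sequence[SuperEnhancerCall], hypo_peaks: PeakSet,
                     genes: Sequence[GeneModel],
                     tss_window: int = TSS_WINDOW):
    """Fraction of SEs overlapping >= 1 hypoacetylated non-TSS region.

    Returns ``(fraction, hypo_se_calls)``; fraction is None (flagged) when
    there are no SEs. Hypo peaks whose midpoint falls inside a TSS window
    are ignored - the question is about distal SE constituents.
    """
    ses = [c for c in se_calls if c.label == "SE"]
    if not ses:
        return None, []
    tss_by_chrom: dict[str, list[float]] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_arr = {c: np.asarray(v, float) for c, v in tss_by_chrom.items()}
    distal = []
    for p in hypo_peaks:
        arr = tss_arr.get(p.interval.chrom)
        if arr is not None and np.abs(arr - p.interval.midpoint).min() <= tss_window:
            continue
        distal.append(p)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in distal:
        by_chrom.setdefault(p.interval.chrom, []).append(p.interval)
    hypo_ses = [
        c for c in ses
        if any(c.region.interval.overlaps(iv)
               for iv in by_chrom.get(c.region.interval.chrom, []))
    ]
    return len(hypo_ses) / len(ses), hypo_ses


def downreg_link_rate(hypo_attribution: pd.DataFrame, down_genes,
                      hypo_se_calls: Sequence[SuperEnhancerCall] = (),
                      expressed_genes=None) -> dict:
    """Percent of hypoacetylated regions per compartment linked to a down gene.

    ``hypo_attribution`` is the :func:`attribute_regions` output restricted
    to hypoacetylated peaks; TSS and TE regions are linked to their
    nearest-TSS gene. SE linkage is computed over ``hypo_se_calls`` (the
    hypoacetylated SEs) through their associated genes, mirroring the
    region-level SE analysis. With ``expressed_genes`` set, the denominator
    is restricted to regions/SEs linked to genes in that set (the
    expressed-only variant). Empty compartments yield None (flagged).
    """
    down = set(down_genes)
    rates: dict[str, float | None] = {}
    for cat in ("TSS", "TE"):
        sub = hypo_attribution[hypo_attribution["category"] == cat]
        if expressed_genes is not None:
            sub = sub[sub["gene_id"].isin(set(expressed_genes))]
        rates[cat] = None if len(sub) == 0 else float(
            100.0 * sub["gene_id"].isin(down).mean())
    ses = list(hypo_se_calls)
    if expressed_genes is not None:
        expressed = set(expressed_genes)
        ses = [c for c in ses if any(g in expressed for g in c.associated_genes)]
    if not ses:
        rates["SE"] = None
    else:
        linked = sum(1 for c in ses if any(g in down for g in c.associated_genes))
        rates["SE"] = 100.0 * linked / len(ses)
    return rates


def explain_downregulation(down_genes, hypo_attribution: pd.DataFrame,
                           hypo_se_genes) -> tuple[pd.DataFrame, dict]:
    """Four-way epigenetic explanation of each downregulated gene.

    A gene has TSS evidence when a hypoacetylated region attributed to the
    TSS compartment links to it (nearest TSS); SE evidence when it is among
    the genes associated with a hypoacetylated super-enhancer. Classes
    TSS_only / TSS_and_SE / SE_only / unexplained are mutually exclusive
    and exhaustive; proportions over all down genes are returned alongside.
    """
    tss_hit = set(
        hypo_attribution.loc[hypo_attribution["category"] == "TSS", "gene_id"])
    se_hit = set(hypo_se_genes)
    rows = []
    for g in down_genes:
        t, s = g in tss_hit, g in se_hit
        if t and s:
            cls = "TSS_and_SE"
        elif t:
            cls = "TSS_only"
        elif s:
            cls = "SE_only"
        else:
            cls = "unexplained"
        rows.append({"gene_id": g, "class": cls})
    df = pd.DataFrame(rows, columns=["gene_id", "class"])
    n = len(df)
    props = {c: (float((df["class"] == c).sum() / n) if n else 0.0)
             for c in EXPLANATION_CLASSES}
    return df, props


# ---------------------------------------------------------------------------
# Strongest-peak origin


def top_peak_origin(baseline: PeakSet, hypo_ids, n_top: int) -> dict:
    """Where does hypoacetylation come from in the baseline signal ranking?

    Returns the fraction of hypoacetylated peaks found among the ``n_top``
    strongest baseline peaks, the converse fraction of the top ``n_top``
    that are hypoacetylated, and the count of hypo peaks absent from the
    baseline catalog (new peaks, excluded and flagged).
    """
    if n_top > len(baseline):
        raise ValueError(f"n_top={n_top} exceeds catalog size {len(baseline)}")
    order = sorted(baseline, key=lambda p: (-p.signal, p.id))
    top_ids = {p.id for p in order[:n_top]}
    catalog_ids = {p.id for p in baseline}
    hypo = [h for h in hypo_ids if h in catalog_ids]
    excluded = len(list(hypo_ids)) - len(hypo)
    in_top = sum(1 for h in hypo if h in top_ids)
    return {
        "fraction_hypo_from_top": (in_top / len(hypo)) if hypo else None,
        "fraction_top_hypo": in_top / n_top if n_top else None,
        "n_hypo": len(hypo),
        "n_top": n_top,
        "n_excluded_new": excluded,
    }
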