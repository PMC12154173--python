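"""End-to-end pipeline: simulate or ingest, test, stitch, attribute, report.

Stages run in a fixed order - ingest/simulate, RNA differential, per-timepoint
ChIP differential, per-donor super-enhancer calling, region attribution, TSS
metaprofiles, linkage/classification - writing every intermediate table under
the run directory and finishing with a deterministic ``report.json``. With an
identical config and seed the report is reproducible bit-for-bit (timings go
to the log only, never into the report).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    GenomicInterval,
    Peak,
    PeakSet,
    coverage_per_mb,
    shared_peaks,
)
from .differential import (
    CountMatrix,
    classify_genes,
    classify_peaks,
    mean_rpkm_per_condition,
    nb_test,
    select_unchanged_reference,
)
from .integration import (
    attribute_regions,
    auc_reduction,
    composition_fractions,
    downreg_link_rate,
    explain_downregulation,
    se_hypo_fraction,
    top_peak_origin,
    tss_metaprofile,
)
from .simulate import SimConfig, read_dataset, simulate_dataset, write_dataset
from .superenhancers import (
    assign_genes,
    calls_to_dataframe,
    rank_and_cut,
    reproducible_ses,
    stitch,
)

logger = logging.getLogger("acetylscape")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """All pipeline parameters; every threshold defaults to the study's value."""

    mode: str = "simulate"           # "simulate" or "files"
    input_dir: str | None = None     # required in files mode
    seed: int | None = None          # required in simulate mode
    padj_threshold: float = 0.05
    peak_lfc_threshold: float = 1.0   # fold change > 2
    gene_lfc_threshold: float = 0.8
    rpkm_threshold: float = 1.0
    stitch_distance: int = 12_500
    tss_exclusion: int = 2_500
    tss_window: int = 5_000
    profile_window: int = 5_000
    profile_binsize: int = 100
    unchanged_k: int = 600
    top_n_fraction: float = 0.09     # strongest-peak pool as a catalog fraction
    top_small_fraction: float = 0.009  # "most extensively acetylated" pool
    min_shared_overlap: int = 1
    attribution_precedence: tuple = ("TSS", "SE", "TE")
    filter_se_differential: bool = False
    sim: dict = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        d = dict(self.sim)
        d.setdefault("seed", self.seed)
        return SimConfig.from_dict(d)


def validate_config(raw: dict) -> RunConfig:
    """Type- and range-check a raw (YAML) config; reject unknown keys.

    Every violation is collected and reported with its field path in a
    single ValueError.
    """
    errs = []
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    for k in sorted(unknown):
        errs.append(f"{k}: unknown key")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in known})
    if isinstance(cfg.attribution_precedence, list):
        cfg.attribution_precedence = tuple(cfg.attribution_precedence)
    if cfg.mode not in ("simulate", "files"):
        errs.append(f"mode: must be 'simulate' or 'files', got {cfg.mode!r}")
    if cfg.mode == "simulate" and cfg.seed is None and "seed" not in cfg.sim:
        errs.append("seed: required in simulate mode")
    if cfg.mode == "files" and not cfg.input_dir:
        errs.append("input_dir: required in files mode")
    for name in ("padj_threshold", "rpkm_threshold"):
        v = getattr(cfg, name)
        if not (0 < v) or (name == "padj_threshold" and v >= 1):
            errs.append(f"{name}: out of range ({v})")
    for name in ("peak_lfc_threshold", "gene_lfc_threshold"):
        if getattr(cfg, name) < 0:
            errs.append(f"{name}: must be >= 0")
    for name in ("stitch_distance", "tss_exclusion", "tss_window",
                 "profile_window", "profile_binsize", "unchanged_k",
                 "min_shared_overlap"):
        if getattr(cfg, name) <= 0:
            errs.append(f"{name}: must be positive")
    if not (0 < cfg.top_n_fraction <= 1):
        errs.append("top_n_fraction: must be in (0, 1]")
    if cfg.profile_window % cfg.profile_binsize != 0:
        errs.append("profile_window: must be a multiple of profile_binsize")
    if set(cfg.attribution_precedence) != {"TSS", "SE", "TE"}:
        errs.append("attribution_precedence: must be a permutation of TSS/SE/TE")
    if errs:
        raise ValueError("invalid config: " + "; ".join(errs))
    if cfg.sim:
        d = dict(cfg.sim)
        d.setdefault("seed", cfg.seed)
        SimConfig.from_dict(d)  # raises on bad sim keys
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _signal_peakset(template: PeakSet, signal: pd.Series,
                    drop_zero: bool = True) -> PeakSet:
    peaks = []
    for p in template:
        s = float(signal.get(p.id, 0.0))
        if drop_zero and s <= 0:
            continue
        peaks.append(Peak(p.interval, p.id, s, p.sample))
    return PeakSet(peaks, mark=template.mark, genome_size=template.genome_size)


def run(cfg: RunConfig, outdir) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t_start = time.perf_counter()
    status = {"stage": "ingest"}
    try:
        report = _run_stages(cfg, outdir, status)
    except Exception as exc:
        logger.error("stage %s failed: %s", status["stage"], exc)
        raise RuntimeError(
            f"pipeline aborted in stage {status['stage']!r}: {exc}") from exc
    finally:
        logger.info("total %.1fs", time.perf_counter() - t_start)
        logger.removeHandler(handler)
        handler.close()
    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def _run_stages(cfg: RunConfig, outdir: Path, status: dict | None = None) -> dict:
    status = status if status is not None else {}

    def tic():
        return time.perf_counter()

    # ---- stage: ingest / simulate -------------------------------------
    status["stage"] = "ingest"
    t0 = tic()
    if cfg.mode == "simulate":
        ds = simulate_dataset(cfg.sim_config())
        write_dataset(ds, outdir / "dataset")
    else:
        ds = read_dataset(cfg.input_dir)
    genes = ds.genes
    timepoints = [t for t in ds.config.timepoints]
    treated = [t for t in timepoints if t > 0]
    logger.info("ingest: %d genes, %d peaks, %d catalogs (%.1fs)",
                len(genes), len(ds.template), len(ds.catalogs), tic() - t0)

    # ---- stage: RNA differential --------------------------------------
    status["stage"] = "rna"
    t0 = tic()
    rna_cm = CountMatrix.from_multiindex(ds.rna_counts, lengths=ds.gene_lengths)
    rna_res = nb_test(rna_cm, "vehicle", "butyrate")
    rna_rpkm = mean_rpkm_per_condition(rna_cm)
    rna_res = classify_genes(rna_res, rna_rpkm,
                             padj_threshold=cfg.padj_threshold,
                             lfc_threshold=cfg.gene_lfc_threshold,
                             rpkm_threshold=cfg.rpkm_threshold)
    down_genes = rna_res.index[rna_res.category == "down"].tolist()
    up_genes = rna_res.index[rna_res.category == "up"].tolist()
    k = min(cfg.unchanged_k,
            int((rna_rpkm.max(axis=1) > cfg.rpkm_threshold).sum()))
    unchanged_ref = select_unchanged_reference(rna_res, rna_rpkm, k=k,
                                               rpkm_threshold=cfg.rpkm_threshold)
    expressed = rna_rpkm.index[rna_rpkm.max(axis=1) > cfg.rpkm_threshold].tolist()
    rna_res.to_csv(outdir / "rna_differential.tsv", sep="\t", index=False)
    logger.info("rna: %d down, %d up, %d expressed (%.1fs)",
                len(down_genes), len(up_genes), len(expressed), tic() - t0)

    # ---- stage: ChIP differential per timepoint -----------------------
    status["stage"] = "chip"
    t0 = tic()
    chip_res = {}
    new_peaks = {}
    for t in treated:
        cols = [c for c in ds.chip_counts.columns if c[1] in ("0h", f"{t}h")]
        cm = CountMatrix.from_multiindex(ds.chip_counts[cols])
        res = nb_test(cm, "0h", f"{t}h")
        res = classify_peaks(res, padj_threshold=cfg.padj_threshold,
                             lfc_threshold=cfg.peak_lfc_threshold)
        born = (res.mean_a == 0) & (res.mean_b > 0)
        res.loc[born, "category"] = "new"
        new_peaks[t] = res.index[born].tolist()
        chip_res[t] = res
        res.to_csv(outdir / f"chip_differential_{t}h.tsv", sep="\t", index=False)
    logger.info("chip differential over %s (%.1fs)", treated, tic() - t0)

    # baseline (0 h) per-peak signal: mean normalized counts across donors
    from .differential import size_factors
    chip_cm_all = CountMatrix.from_multiindex(ds.chip_counts)
    try:
        # restrict to features observed in every sample (excludes born peaks)
        sf = size_factors(chip_cm_all.counts)
    except ValueError:
        sf = size_factors(chip_cm_all.counts, pseudo_reference=True)
    chip_norm = chip_cm_all.counts / sf
    chip_norm.columns = ds.chip_counts.columns
    baseline_signal = chip_norm.xs("0h", axis=1, level="timepoint").mean(axis=1)
    baseline_peaks = _signal_peakset(ds.template, baseline_signal)

    # ---- stage: super-enhancers per donor at baseline ------------------
    status["stage"] = "superenhancers"
    t0 = tic()
    donors = sorted({c[0] for c in ds.chip_counts.columns})
    donor_calls = {}
    for d in donors:
        sig = chip_norm[(d, "0h")]
        ps = _signal_peakset(ds.template, sig)
        regions = stitch(ps, genes, stitch_dist=cfg.stitch_distance,
                         tss_excl=cfg.tss_exclusion)
        calls = rank_and_cut(regions)
        assign_genes(calls, genes)
        donor_calls[d] = calls
        calls_to_dataframe(calls).to_csv(
            outdir / f"stitched_{d}.tsv", sep="\t", index=False)
    if len(donors) >= 2:
        rep_ses, rep_se_genes = reproducible_ses(donor_calls[donors[0]],
                                                 donor_calls[donors[1]])
    else:
        rep_ses = [c for c in donor_calls[donors[0]] if c.label == "SE"]
        rep_se_genes = sorted({g for c in rep_ses for g in c.associated_genes})
    te_calls = [c for c in donor_calls[donors[0]] if c.label == "TE"]
    calls_to_dataframe(rep_ses).to_csv(
        outdir / "reproducible_ses.tsv", sep="\t", index=False)
    logger.info("SEs: %s per donor, %d reproducible, %d genes (%.1fs)",
                {d: sum(c.label == "SE" for c in calls)
                 for d, calls in donor_calls.items()},
                len(rep_ses), len(rep_se_genes), tic() - t0)

    # ---- stage: attribution of differential regions --------------------
    status["stage"] = "attribution"
    t0 = tic()
    attribution = {}
    donut = {}
    for t in treated:
        res = chip_res[t]
        rows = {}
        for cat in ("hypo", "hyper"):
            ids = res.index[res.category == cat].tolist()
            if not ids:
                rows[cat] = {}
                continue
            attr = attribute_regions(baseline_peaks.subset(ids), rep_ses,
                                     te_calls, genes,
                                     tss_window=cfg.tss_window,
                                     precedence=cfg.attribution_precedence)
            attribution[(t, cat)] = attr
            attr.to_csv(outdir / f"attribution_{cat}_{t}h.tsv",
                        sep="\t", index=False)
            rows[cat] = composition_fractions(attr)
        donut[t] = rows
    logger.info("attribution (%.1fs)", tic() - t0)

    # ---- stage: TSS metaprofiles and AUC -------------------------------
    status["stage"] = "profiles"
    t0 = tic()
    gene_sets = {"down": down_genes, "unchanged": unchanged_ref, "up": up_genes}
    auc_records = {}
    profile_rows = []
    for label, ids in gene_sets.items():
        if not ids:
            auc_records[label] = []
            continue
        profiles = {}
        for t in timepoints:
            sig = chip_norm.xs(f"{t}h", axis=1, level="timepoint").mean(axis=1)
            ps = _signal_peakset(ds.template, sig)
            profiles[f"{t}h"] = tss_metaprofile(
                ps, genes, ids, label=label,
                window=cfg.profile_window, binsize=cfg.profile_binsize,
                timepoint=f"{t}h")
        auc_records[label] = auc_reduction(profiles, baseline_key="0h")
        for tp, prof in profiles.items():
            for c, v in zip(prof.bin_centers, prof.values):
                profile_rows.append((label, tp, float(c), float(v)))
    pd.DataFrame(profile_rows,
                 columns=["gene_set", "timepoint", "bin_center", "signal"]
                 ).to_csv(outdir / "tss_profiles.tsv", sep="\t", index=False)
    logger.info("profiles (%.1fs)", tic() - t0)

    # ---- stage: linkage and classification (24 h) -----------------------
    status["stage"] = "linkage"
    t0 = tic()
    t_final = treated[-1]
    hypo_ids_final = chip_res[t_final].index[
        chip_res[t_final].category == "hypo"].tolist()
    hypo_final_ps = baseline_peaks.subset(
        [i for i in hypo_ids_final if i in set(baseline_peaks.ids)])
    frac_se_hypo, hypo_ses = se_hypo_fraction(rep_ses, hypo_final_ps, genes,
                                              tss_window=cfg.tss_window)
    hypo_se_genes = sorted({g for c in hypo_ses for g in c.associated_genes})
    attr_final = attribution.get((t_final, "hypo"))
    link_rates = downreg_link_rate(attr_final, down_genes, hypo_ses) \
        if attr_final is not None else {}
    link_rates_expressed = downreg_link_rate(
        attr_final, down_genes, hypo_ses, expressed_genes=expressed) \
        if attr_final is not None else {}
    explain_df, explain_props = explain_downregulation(
        down_genes, attr_final if attr_final is not None else
        pd.DataFrame(columns=["category", "gene_id"]), hypo_se_genes)
    explain_df.to_csv(outdir / "epigenetic_explanation.tsv", sep="\t",
                      index=False)

    # strongest-peak origin at the earliest treated timepoint
    t_early = treated[0]
    hypo_early = chip_res[t_early].index[
        chip_res[t_early].category == "hypo"].tolist()
    n_top = max(1, int(round(cfg.top_n_fraction * len(baseline_peaks))))
    n_small = max(1, int(round(cfg.top_small_fraction * len(baseline_peaks))))
    origin = top_peak_origin(baseline_peaks, hypo_early, n_top)
    origin_small = top_peak_origin(baseline_peaks, hypo_early, n_small)
    logger.info("linkage (%.1fs)", tic() - t0)

    # ---- stage: catalog summaries (coverage / shared peaks / folds) ----
    status["stage"] = "catalog"
    t0 = tic()
    catalog = {}
    for (mark, donor, t), ps in sorted(ds.catalogs.items()):
        catalog.setdefault(mark, {}).setdefault(donor, {})[f"{t}h"] = {
            "n_peaks": len(ps),
            "coverage_bp_per_mb": round(coverage_per_mb(ps), 3),
        }
    folds = {}
    shared = {}
    for mark in sorted({m for m, _, _ in ds.catalogs}):
        folds[mark] = {}
        shared[mark] = {}
        for donor in sorted({d for m, d, _ in ds.catalogs if m == mark}):
            base = ds.catalogs[(mark, donor, timepoints[0])]
            last = ds.catalogs[(mark, donor, timepoints[-1])]
            folds[mark][donor] = round(len(last) / len(base), 4)
        d_list = sorted({d for m, d, _ in ds.catalogs if m == mark})
        if len(d_list) >= 2:
            for t in timepoints:
                a = ds.catalogs[(mark, d_list[0], t)]
                b = ds.catalogs[(mark, d_list[1], t)]
                shared[mark][f"{t}h"] = {
                    f"{d_list[0]}_vs_{d_list[1]}": len(
                        shared_peaks(a, b, cfg.min_shared_overlap)),
                    f"{d_list[1]}_vs_{d_list[0]}": len(
                        shared_peaks(b, a, cfg.min_shared_overlap)),
                }
    logger.info("catalog summaries (%.1fs)", tic() - t0)

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "software_version": __version__,
        "seed": cfg.seed if cfg.seed is not None else cfg.sim.get("seed"),
        "config": _jsonable(asdict(cfg)),
        "counts": {
            "n_genes": len(genes),
            "n_peaks_template": len(ds.template),
            "n_down_genes": len(down_genes),
            "n_up_genes": len(up_genes),
            "n_expressed_genes": len(expressed),
            "n_reproducible_ses": len(rep_ses),
            "n_unique_se_genes": len(rep_se_genes),
            "n_hypo_ses": len(hypo_ses),
            "n_hypo_se_genes": len(hypo_se_genes),
            "per_timepoint": {
                f"{t}h": {
                    "hypo": int((chip_res[t].category == "hypo").sum()),
                    "hyper": int((chip_res[t].category == "hyper").sum()),
                    "new": len(new_peaks[t]),
                    "unchanged": int((chip_res[t].category == "unchanged").sum()),
                } for t in treated
            },
        },
        "donut_fractions": _jsonable(donut),
        "se_hypo_fraction": frac_se_hypo,
        "link_rates_pct": _jsonable(link_rates),
        "link_rates_expressed_pct": _jsonable(link_rates_expressed),
        "explanation_proportions": _jsonable(explain_props),
        "top_peak_origin": _jsonable(origin),
        "top_peak_origin_small": _jsonable(origin_small),
        "auc_reduction_pct": {
            label: {r.timepoint: (None if r.reduction_vs_baseline is None
                                  else round(r.reduction_vs_baseline, 4))
                    for r in records}
            for label, records in auc_records.items()
        },
        "catalog": catalog,
        "catalog_fold_last_vs_first": folds,
        "shared_peak_counts": shared,
    }
    return _jsonable(report)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
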