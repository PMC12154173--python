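"""Seeded simulator of butyrate-style histone-acetylation dynamics.

The generator lays out a toy genome of well-separated genes, gives each gene
a promoter (TSS) H3K27Ac peak and a handful of distal typical-enhancer (TE)
peaks, gives a subset of genes a stitchable super-enhancer (SE) cluster of
high-signal constituents, and then draws negative-binomial RNA and ChIP
count matrices for two donors across the 0/3/12/24 h treatment timepoints.

The planted effect structure mirrors what an HDAC inhibitor does in primary
mast cells:

* downregulated genes are drawn from the highly expressed pool and lose TSS
  acetylation immediately (from 3 h);
* most other genes lose TSS acetylation later and more weakly (from 12 h);
* a burst of distal hyperacetylation appears transiently at 3 h,
  preferentially at enhancer constituents;
* SE-owning genes - enriched among the downregulated - acquire
  hypoacetylated SE constituents at 24 h;
* strongly induced genes start from low baseline acetylation and gain TSS
  signal, moderately induced genes gain enhancer signal instead;
* new distal peaks are born after treatment, growing the H3K27Ac catalog
  ~2.6-fold by 24 h while the H3K4Me2 control catalog grows only ~1.3-fold.

Every planted flag is recorded in a :class:`TruthTable` so each downstream
stage has a recovery test. All randomness flows from ``SimConfig.seed``
through ``numpy.random.default_rng``; identical configs give identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    read_genes,
    read_peaks,
    write_genes,
    write_peaks,
)

TIMEPOINTS = (0, 3, 12, 24)

__all__ = [
    "SimConfig",
    "TruthTable",
    "SimulatedDataset",
    "generate_genome",
    "simulate_counts",
    "build_catalogs",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment (defaults emulate the study).

    Effect sizes are log2 fold changes of the underlying negative-binomial
    means; fractions are of the gene catalog unless noted.
    """

    seed: int
    n_genes: int = 800
    chrom_length: int = 0  # 0 -> n_genes * gene_spacing
    gene_spacing: int = 150_000
    n_chroms: int = 2
    n_donors: int = 2
    timepoints: tuple = TIMEPOINTS
    frac_se_genes: float = 0.10
    se_down_enrichment: float = 3.0  # SE ownership odds multiplier for down genes
    frac_down: float = 0.08
    frac_up: float = 0.06
    frac_up_strong: float = 0.33  # share of up genes that are low-baseline/strongly induced
    nb_dispersion: float = 0.05
    effect_log2fc: dict = field(
        default_factory=lambda: {
            "down": 2.0,          # expression loss of down genes
            "up_strong": 4.0,     # induction of low-baseline up genes
            "up_moderate": 1.5,   # induction of moderate up genes
            "tss_hypo": 2.0,      # TSS acetylation loss at down genes (from 3 h)
            "tss_hypo_other": 1.5,  # later, weaker TSS loss at other genes (from 12 h)
            "se_hypo": 2.0,       # SE-constituent loss at 24 h
            "distal_hyper": 1.8,  # transient distal gain at 3 h
            "tss_gain": 2.0,      # sustained TSS gain at strongly induced genes
            "te_gain": 1.5,       # sustained enhancer gain at moderate up genes
        }
    )
    frac_tss_hypo_down: float = 0.75   # down genes with planted TSS hypoacetylation
    frac_tss_hypo_other: float = 0.87  # other genes with weak/late TSS hypoacetylation
    se_hypo_coupling_down: float = 0.90  # SE-owning down genes with SE hypoacetylation
    se_hypo_coupling_other: float = 0.83
    se_hypo_constituent_frac: float = 0.30  # constituents hypoacetylated per affected SE
    te_hypo_rate: float = 0.035          # early distal hypo picks, as a fraction of TE count
    te_hypo_down_coupling: float = 3.0   # weight multiplier if nearest gene is down
    distal_hypo_top_frac: float = 0.10   # SE-constituent stream drawn from this top quantile
    distal_hypo_se_share: float = 0.5    # share of early distal hypo on SE constituents
    distal_hyper_rate: float = 0.15      # TE peaks with transient 3 h hyperacetylation
    se_hyper_rate: float = 0.10          # SE constituents with transient 3 h hyperacetylation
    peak_birth_rate: float = 1.6     # new distal peaks per existing H3K27Ac peak at 24 h
    me2_birth_rate: float = 0.3      # same for the H3K4Me2 control mark
    birth_presence: dict = field(
        default_factory=lambda: {0: 0.0, 3: 0.7, 12: 0.9, 24: 1.0}
    )
    chip_depth: float = 12.0   # expected counts per unit of peak signal
    rna_depth: float = 1.0     # scales expression means into counts
    donor_dropout: float = 0.03  # per-donor catalog jitter for Fig-2-style summaries

    def validate(self) -> None:
        errs = []
        if self.seed is None:
            errs.append("seed is required")
        for name in ("n_genes", "gene_spacing", "n_chroms", "n_donors"):
            if getattr(self, name) <= 0:
                errs.append(f"{name} must be positive")
        for name in ("frac_se_genes", "frac_down", "frac_up", "frac_up_strong",
                     "frac_tss_hypo_down", "frac_tss_hypo_other",
                     "se_hypo_coupling_down", "se_hypo_coupling_other",
                     "se_hypo_constituent_frac", "te_hypo_rate",
                     "distal_hypo_top_frac", "distal_hypo_se_share",
                     "distal_hyper_rate", "se_hyper_rate", "donor_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errs.append(f"{name} must be in [0, 1], got {v}")
        if self.frac_down + self.frac_up > 1.0:
            errs.append("frac_down + frac_up must be <= 1")
        if self.nb_dispersion <= 0:
            errs.append("nb_dispersion must be > 0")
        if self.peak_birth_rate < 0 or self.me2_birth_rate < 0:
            errs.append("birth rates must be >= 0")
        if errs:
            raise ValueError("invalid SimConfig: " + "; ".join(errs))

    @property
    def effective_chrom_length(self) -> int:
        if self.chrom_length:
            return self.chrom_length
        genes_per_chrom = -(-self.n_genes // self.n_chroms)
        return (genes_per_chrom + 1) * self.gene_spacing

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown SimConfig keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.timepoints, list):
            cfg.timepoints = tuple(cfg.timepoints)
        cfg.validate()
        return cfg


@dataclass
class TruthTable:
    """Ground truth of the planted effects.

    ``genes``: gene_id, expr_class {down, up_strong, up_moderate, unchanged},
    se_owner, tss_hypo, se_hypo.
    ``peaks``: peak_id, role {TSS, TE, SE, born}, gene_id (owner),
    nearest_gene, trajectory label, and the per-timepoint mean multiplier.
    """

    genes: pd.DataFrame
    peaks: pd.DataFrame

    @property
    def planted_explanation_proportions(self) -> dict:
        """Fig-5H-style class proportions implied by the planted flags."""
        down = self.genes[self.genes.expr_class == "down"]
        if len(down) == 0:
            return {}
        t, s = down.tss_hypo.to_numpy(bool), down.se_hypo.to_numpy(bool)
        n = len(down)
        return {
            "TSS_only": float((t & ~s).sum() / n),
            "TSS_and_SE": float((t & s).sum() / n),
            "SE_only": float((~t & s).sum() / n),
            "unexplained": float((~t & ~s).sum() / n),
        }


@dataclass
class SimulatedDataset:
    config: SimConfig
    genes: list
    template: PeakSet          # canonical (reproducible) H3K27Ac peak catalog incl. born peaks
    rna_counts: pd.DataFrame   # genes x (donor, condition)
    chip_counts: pd.DataFrame  # peaks x (donor, timepoint)
    truth: TruthTable
    catalogs: dict             # (mark, donor, timepoint) -> PeakSet
    gene_lengths: pd.Series = None


# ---------------------------------------------------------------------------
# Genome layout


def generate_genome(cfg: SimConfig):
    """Lay out gene models and the role-annotated template peak catalog.

    Deterministic given ``cfg.seed``. Raises if the genome cannot hold the
    requested features at the configured spacing.
    """
    cfg.validate()
    if cfg.gene_spacing < 30_000:
        raise ValueError(
            "genome too small: gene_spacing must be >= 30 kb to place TSS, "
            "enhancer, and SE features without collision; increase "
            "gene_spacing or chrom_length"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 101]))
    genes_per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    clen = cfg.effective_chrom_length
    spacing = clen // (genes_per_chrom + 1)

    genes: list[GeneModel] = []
    rows = []
    expr = rng.lognormal(mean=np.log(300.0), sigma=1.0, size=cfg.n_genes)
    for i in range(cfg.n_genes):
        chrom = f"chr{i % cfg.n_chroms + 1}"
        slot = i // cfg.n_chroms
        tss = (slot + 1) * spacing + int(rng.integers(-2000, 2000))
        strand = "+" if rng.random() < 0.5 else "-"
        body_len = int(rng.integers(5_000, 20_000))
        if strand == "+":
            body = GenomicInterval(chrom, tss, tss + body_len)
        else:
            body = GenomicInterval(chrom, tss - body_len, tss)
        gid = f"G{i:05d}"
        genes.append(GeneModel(gid, chrom, strand, tss, body, float(expr[i])))

    # expression classes: down genes drawn from the highly expressed top
    # (canonical effector genes of the cell type sit high in the RPKM ranking)
    order = np.argsort(-expr)
    n_down = int(round(cfg.frac_down * cfg.n_genes))
    n_up = int(round(cfg.frac_up * cfg.n_genes))
    n_up_strong = int(round(cfg.frac_up_strong * n_up))
    top_pool = order[: max(n_down, int(0.20 * cfg.n_genes))]
    down_idx = rng.choice(top_pool, size=n_down, replace=False)
    remaining = np.setdiff1d(np.arange(cfg.n_genes), down_idx)
    up_idx = rng.choice(remaining, size=n_up, replace=False)
    up_strong_idx = set(up_idx[:n_up_strong].tolist())
    expr_class = np.full(cfg.n_genes, "unchanged", dtype=object)
    expr_class[down_idx] = "down"
    for j in up_idx:
        expr_class[j] = "up_strong" if j in up_strong_idx else "up_moderate"
    # strongly induced genes start from low baseline expression
    for j in up_idx:
        if expr_class[j] == "up_strong":
            genes[j].baseline_expression = float(rng.uniform(0.5, 3.0))

    # SE ownership, enriched among down genes
    p_down = min(1.0, cfg.frac_se_genes * cfg.se_down_enrichment)
    denom = max(1e-9, 1.0 - cfg.frac_down)
    p_other = max(0.0, (cfg.frac_se_genes - cfg.frac_down * p_down) / denom)
    se_owner = np.array([
        rng.random() < (p_down if expr_class[i] == "down" else p_other)
        for i in range(cfg.n_genes)
    ])

    peaks: list[Peak] = []
    peak_rows = []
    pid = 0

    def add_peak(chrom, start, end, signal, role, gene_id):
        nonlocal pid
        start = max(0, int(start))
        end = min(clen, int(end))
        if end - start < 100:
            return None
        p = Peak(GenomicInterval(chrom, start, end), f"P{pid:06d}", float(signal))
        pid += 1
        peaks.append(p)
        peak_rows.append({"peak_id": p.id, "role": role, "gene_id": gene_id})
        return p

    for i, g in enumerate(genes):
        # promoter peak within +/-2 kb of the TSS; signal scales with
        # expression so the strongest promoters belong to the most highly
        # expressed genes
        width = int(rng.integers(1_000, 1_600))
        center = g.tss + int(rng.integers(-500, 500))
        if expr_class[i] == "up_strong":
            sig = rng.uniform(1.0, 3.0)  # poorly acetylated before induction
        else:
            sig = 2.0 + g.baseline_expression / 12.0 + rng.uniform(0, 3)
        add_peak(g.chrom, center - width // 2, center + width // 2, sig, "TSS", g.gene_id)

        # typical-enhancer peaks, 5-500 kb from the TSS; a minority are
        # strongly acetylated
        for _ in range(int(rng.integers(1, 5))):
            dist = int(rng.uniform(5_000, 500_000)) * (1 if rng.random() < 0.5 else -1)
            w = int(rng.integers(500, 1_200))
            c = g.tss + dist
            if not (0 < c - w // 2 and c + w // 2 < clen):
                continue
            te_sig = rng.uniform(9.0, 25.0) if rng.random() < 0.12 \
                else rng.uniform(2.0, 9.0)
            add_peak(g.chrom, c - w // 2, c + w // 2, te_sig, "TE", g.gene_id)

        if se_owner[i]:
            # SE cluster: 8-25 high-signal constituents with stitchable gaps,
            # starting 20-45 kb from the TSS so it stays clear of promoter
            # windows and remains nearest to its own gene
            k = int(rng.integers(8, 26))
            side = 1 if rng.random() < 0.5 else -1
            pos = g.tss + side * int(rng.uniform(20_000, 45_000))
            for _ in range(k):
                w = int(rng.integers(600, 1_200))
                lo, hi = (pos, pos + w) if side > 0 else (pos - w, pos)
                add_peak(g.chrom, lo, hi, rng.uniform(20.0, 60.0), "SE", g.gene_id)
                gap = int(rng.integers(300, 2_000))
                pos = pos + side * (w + gap)

    truth_genes = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "expr_class": expr_class,
        "se_owner": se_owner,
        "tss_hypo": False,
        "se_hypo": False,
    })
    template = PeakSet(peaks, mark="H3K27Ac", genome_size=clen * cfg.n_chroms)
    truth_peaks = pd.DataFrame(peak_rows)
    return genes, template, truth_genes, truth_peaks


# ---------------------------------------------------------------------------
# Counts


def _nb_draw(rng, mean, dispersion):
    """Negative binomial with var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros_like(mean)
    pos = mean > 0
    if pos.any():
        shape = 1.0 / dispersion
        lam = rng.gamma(shape, mean[pos] * dispersion)
        out[pos] = rng.poisson(lam)
    return out.astype(int)


def simulate_counts(cfg: SimConfig, genes, template: PeakSet,
                    truth_genes: pd.DataFrame, truth_peaks: pd.DataFrame):
    """Draw RNA and ChIP count matrices realizing the planted effect classes.

    Returns ``(rna_counts, chip_counts, truth)`` where the count frames are
    indexed by feature id with MultiIndex columns (donor, condition) and
    (donor, timepoint) respectively, and ``truth`` carries the realized
    planted flags plus per-timepoint mean multipliers for every peak.
    """
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 202]))
    truth_genes = truth_genes.copy().set_index("gene_id", drop=False)
    truth_peaks = truth_peaks.copy()
    eff = cfg.effect_log2fc
    tps = list(cfg.timepoints)

    # ---- plant per-gene flags
    down_ids = truth_genes.index[truth_genes.expr_class == "down"]
    tss_hypo = set(
        rng.choice(down_ids, size=int(round(cfg.frac_tss_hypo_down * len(down_ids))),
                   replace=False)
    ) if len(down_ids) else set()
    other_ids = truth_genes.index[truth_genes.expr_class != "down"]
    tss_hypo_other = set(
        rng.choice(other_ids,
                   size=int(round(cfg.frac_tss_hypo_other * len(other_ids))),
                   replace=False)
    ) if len(other_ids) else set()
    se_hypo = set()
    for gid, row in truth_genes.iterrows():
        if not row.se_owner:
            continue
        p = (cfg.se_hypo_coupling_down if row.expr_class == "down"
             else cfg.se_hypo_coupling_other)
        if rng.random() < p:
            se_hypo.add(gid)
    truth_genes["tss_hypo"] = truth_genes.index.isin(tss_hypo)
    truth_genes["se_hypo"] = truth_genes.index.isin(se_hypo)

    # ---- nearest gene per peak (for distal-hypo coupling to down genes)
    from .core import nearest_tss_table
    nt = nearest_tss_table(template, genes).set_index("peak_id")
    truth_peaks = truth_peaks.set_index("peak_id", drop=False)
    truth_peaks["nearest_gene"] = nt["gene_id"]

    expr_class = truth_genes["expr_class"]
    sig = {p.id: p.signal for p in template}

    # ---- per-peak trajectory multipliers
    mult = {t: np.ones(len(truth_peaks)) for t in tps}
    traj = np.full(len(truth_peaks), "flat", dtype=object)
    roles = truth_peaks["role"].to_numpy()
    owner = truth_peaks["gene_id"].to_numpy()
    nearest = truth_peaks["nearest_gene"].to_numpy(dtype=object)
    ids = truth_peaks["peak_id"].to_numpy()

    def set_traj(i, label, factors):
        traj[i] = label
        for t, f in factors.items():
            mult[t][i] = f

    se_constituent_hypo = np.zeros(len(truth_peaks), dtype=bool)
    for i in range(len(truth_peaks)):
        role, gid = roles[i], owner[i]
        if role == "TSS":
            cls = expr_class.get(gid, "unchanged")
            if gid in tss_hypo:
                f = 2.0 ** -eff["tss_hypo"]
                set_traj(i, "tss_hypo", {t: f for t in tps if t >= 3})
            elif gid in tss_hypo_other:
                f = 2.0 ** -eff["tss_hypo_other"]
                set_traj(i, "tss_hypo_late", {t: f for t in tps if t >= 12})
            if cls == "up_strong":
                f = 2.0 ** eff["tss_gain"]
                set_traj(i, "tss_gain", {t: f for t in tps if t >= 3})
        elif role == "SE":
            if gid in se_hypo and rng.random() < cfg.se_hypo_constituent_frac:
                se_constituent_hypo[i] = True
                set_traj(i, "se_hypo", {24: 2.0 ** -eff["se_hypo"]})

    # transient distal hyperacetylation at 3 h
    te_idx = np.flatnonzero(roles == "TE")
    se_idx = np.flatnonzero(roles == "SE")
    for pool, rate in ((te_idx, cfg.distal_hyper_rate), (se_idx, cfg.se_hyper_rate)):
        n_pick = int(round(rate * len(pool)))
        if n_pick:
            for i in rng.choice(pool, size=n_pick, replace=False):
                if traj[i] == "flat":
                    set_traj(i, "distal_hyper", {3: 2.0 ** eff["distal_hyper"]})

    # moderate up genes gain enhancer acetylation (sustained)
    up_mod = sorted(truth_genes.index[truth_genes.expr_class == "up_moderate"])
    for gid in up_mod:
        cand = np.flatnonzero((roles == "TE") & (owner == gid))
        if len(cand):
            i = int(rng.choice(cand))
            f = 2.0 ** eff["te_gain"]
            set_traj(i, "te_gain", {t: f for t in tps if t >= 3})

    # early sustained distal hypoacetylation targets extensively acetylated
    # distal sites (strongest-peak origin): one stream over the strongest SE
    # constituents, one over the strong tail of TEs with a preference for
    # peaks whose nearest gene is downregulated
    down_set = set(down_ids)
    f_hypo = 2.0 ** -eff["tss_hypo"]
    n_total_pick = int(round(cfg.te_hypo_rate * len(te_idx)))
    n_se_pick = int(round(cfg.distal_hypo_se_share * n_total_pick))
    se_flat = np.flatnonzero((roles == "SE") & (traj == "flat"))
    if len(se_flat) and n_se_pick:
        s = np.array([sig[ids[i]] for i in se_flat])
        n_pool = max(1, int(round(cfg.distal_hypo_top_frac * len(se_flat))))
        pool = se_flat[np.argsort(-s)[:n_pool]]
        w = np.array([sig[ids[i]] ** 2 for i in pool])
        for i in rng.choice(pool, size=min(len(pool), n_se_pick),
                            replace=False, p=w / w.sum()):
            set_traj(i, "distal_hypo", {t: f_hypo for t in tps if t >= 3})
            # an SE constituent planted hypo makes its owner's SE
            # hypoacetylated in truth as well
            se_constituent_hypo[i] = True
            truth_genes.loc[owner[i], "se_hypo"] = True
    te_flat = np.flatnonzero((roles == "TE") & (traj == "flat"))
    n_te_pick = n_total_pick - n_se_pick
    if len(te_flat) and n_te_pick:
        s = np.array([sig[ids[i]] for i in te_flat])
        n_pool = max(1, int(round(0.15 * len(te_flat))))  # the strong TE tail
        pool = te_flat[np.argsort(-s)[:n_pool]]
        w = np.array([
            sig[ids[i]] ** 2
            * (cfg.te_hypo_down_coupling if nearest[i] in down_set else 1.0)
            for i in pool
        ])
        for i in rng.choice(pool, size=min(len(pool), n_te_pick),
                            replace=False, p=w / w.sum()):
            set_traj(i, "distal_hypo", {t: f_hypo for t in tps if t >= 3})

    # ---- born peaks: new distal peaks appearing only after treatment
    clen = cfg.effective_chrom_length
    n_base = len(truth_peaks)
    n_born = int(round(cfg.peak_birth_rate * n_base))
    tss_pos = {(g.chrom, g.tss) for g in genes}
    born_peaks = []
    born_rows = []
    pid = n_base
    chroms = sorted({g.chrom for g in genes})
    presence_draw = rng.random(n_born)
    attempts = 0
    while len(born_peaks) < n_born and attempts < 20 * n_born:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        c = int(rng.uniform(5_000, clen - 5_000))
        if any(abs(c - t) < 5_000 for ch, t in tss_pos if ch == chrom):
            continue
        w = int(rng.integers(400, 900))
        born_peaks.append(Peak(GenomicInterval(chrom, c - w // 2, c + w // 2),
                               f"P{pid:06d}", float(rng.uniform(1.5, 6.0))))
        born_rows.append({"peak_id": f"P{pid:06d}", "role": "born",
                          "gene_id": "", "nearest_gene": ""})
        pid += 1
    n_born = len(born_peaks)

    template_all = PeakSet(list(template) + born_peaks, mark=template.mark,
                           genome_size=template.genome_size)
    truth_peaks_all = pd.concat(
        [truth_peaks.reset_index(drop=True), pd.DataFrame(born_rows)],
        ignore_index=True,
    )
    for t in tps:
        mult[t] = np.concatenate([mult[t], np.zeros(n_born)])
    traj = np.concatenate([traj, np.full(n_born, "born", dtype=object)])

    # born peaks ramp in: a fixed subset is present at each timepoint
    pres_frac = dict(cfg.birth_presence)
    for ti, t in enumerate(tps):
        frac = pres_frac.get(t, 1.0 if t > 0 else 0.0)
        present = presence_draw[:n_born] < frac
        mult[t][n_base:][present] = 1.0

    # ---- draw ChIP counts (rows follow truth-table order, not the
    # coordinate-sorted PeakSet order)
    id_order = truth_peaks_all["peak_id"].tolist()
    sig_all = {p.id: p.signal for p in template_all}
    base_mean = np.array([cfg.chip_depth * sig_all[i] for i in id_order])
    donors = [f"D{d+1}" for d in range(cfg.n_donors)]
    chip_cols = {}
    for d in donors:
        for t in tps:
            mu = base_mean * mult[t]
            chip_cols[(d, f"{t}h")] = _nb_draw(rng, mu, cfg.nb_dispersion)
    chip_counts = pd.DataFrame(chip_cols, index=id_order)
    chip_counts.columns = pd.MultiIndex.from_tuples(chip_counts.columns,
                                                    names=["donor", "timepoint"])

    # ---- draw RNA counts (vehicle vs 24 h butyrate)
    gene_ids = [g.gene_id for g in genes]
    base_expr = np.array([g.baseline_expression for g in genes])
    lfc = np.zeros(len(genes))
    for j, gid in enumerate(gene_ids):
        cls = expr_class.get(gid, "unchanged")
        if cls == "down":
            lfc[j] = -eff["down"]
        elif cls == "up_strong":
            lfc[j] = eff["up_strong"]
        elif cls == "up_moderate":
            lfc[j] = eff["up_moderate"]
    mu_veh = cfg.rna_depth * base_expr
    mu_but = mu_veh * 2.0 ** lfc
    rna_cols = {}
    for d in donors:
        rna_cols[(d, "vehicle")] = _nb_draw(rng, mu_veh, cfg.nb_dispersion)
        rna_cols[(d, "butyrate")] = _nb_draw(rng, mu_but, cfg.nb_dispersion)
    rna_counts = pd.DataFrame(rna_cols, index=gene_ids)
    rna_counts.columns = pd.MultiIndex.from_tuples(rna_counts.columns,
                                                   names=["donor", "condition"])

    truth_peaks_all["trajectory"] = traj
    for t in tps:
        truth_peaks_all[f"mult_{t}h"] = mult[t]
    truth = TruthTable(genes=truth_genes.reset_index(drop=True),
                       peaks=truth_peaks_all)
    return rna_counts, chip_counts, truth, template_all


# ---------------------------------------------------------------------------
# Per-donor catalogs (Fig-2-style coverage / shared-peak summaries)


def build_catalogs(cfg: SimConfig, template_all: PeakSet, truth: TruthTable,
                   genes) -> dict:
    """Per-(mark, donor, timepoint) called-peak catalogs.

    H3K27Ac catalogs at each timepoint contain the baseline peaks plus the
    born peaks present by then; each donor's catalog drops a small random
    fraction and jitters boundaries slightly, emulating independent peak
    calling. The H3K4Me2 control catalogs are built from a separate static
    template with a much lower birth rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 303]))
    tps = list(cfg.timepoints)
    donors = [f"D{d+1}" for d in range(cfg.n_donors)]
    mult_by_id = truth.peaks.set_index("peak_id")
    peaks = list(template_all)
    tp_mult = {
        t: mult_by_id[f"mult_{t}h"].reindex([p.id for p in peaks]).to_numpy()
        for t in tps
    }
    catalogs = {}
    for d in donors:
        keep_noise = rng.random(len(peaks))
        jitter = rng.integers(-30, 31, size=(len(peaks), 2))
        for t in tps:
            kept = []
            for i, p in enumerate(peaks):
                if tp_mult[t][i] <= 0:  # born peak not yet present
                    continue
                if keep_noise[i] < cfg.donor_dropout:
                    continue
                s = max(0, p.interval.start + int(jitter[i, 0]))
                e = p.interval.end + int(jitter[i, 1])
                if e - s < 50:
                    continue
                kept.append(Peak(GenomicInterval(p.interval.chrom, s, e),
                                 p.id, p.signal, sample=f"{d}_{t}h"))
            catalogs[("H3K27Ac", d, t)] = PeakSet(
                kept, mark="H3K27Ac", genome_size=template_all.genome_size)

    # H3K4Me2 control: one promoter-region peak per gene plus some distal,
    # nearly static over time
    me2 = []
    pid = 0
    for g in genes:
        w = int(rng.integers(1_500, 3_000))
        me2.append(Peak(GenomicInterval(g.chrom, max(0, g.tss - w // 2), g.tss + w // 2),
                        f"M{pid:06d}", float(rng.uniform(3, 12))))
        pid += 1
        for _ in range(int(rng.integers(1, 3))):
            c = g.tss + int(rng.uniform(8_000, 120_000)) * (1 if rng.random() < 0.5 else -1)
            w = int(rng.integers(600, 1_500))
            if c - w // 2 <= 0:
                continue
            me2.append(Peak(GenomicInterval(g.chrom, c - w // 2, c + w // 2),
                            f"M{pid:06d}", float(rng.uniform(2, 8))))
            pid += 1
    n_me2_born = int(round(cfg.me2_birth_rate * len(me2)))
    clen = cfg.effective_chrom_length
    chroms = sorted({g.chrom for g in genes})
    me2_born = []
    for _ in range(n_me2_born):
        chrom = chroms[int(rng.integers(len(chroms)))]
        c = int(rng.uniform(5_000, clen - 5_000))
        w = int(rng.integers(400, 1_000))
        me2_born.append(Peak(GenomicInterval(chrom, c - w // 2, c + w // 2),
                             f"M{pid:06d}", float(rng.uniform(1, 5))))
        pid += 1
    me2_presence = rng.random(n_me2_born)
    pres_frac = dict(cfg.birth_presence)
    for d in donors:
        keep_noise = rng.random(len(me2) + n_me2_born)
        for t in tps:
            frac = pres_frac.get(t, 1.0 if t > 0 else 0.0)
            kept = [p for i, p in enumerate(me2) if keep_noise[i] >= cfg.donor_dropout]
            kept += [p for i, p in enumerate(me2_born)
                     if me2_presence[i] < frac
                     and keep_noise[len(me2) + i] >= cfg.donor_dropout]
            catalogs[("H3K4Me2", d, t)] = PeakSet(
                [Peak(p.interval, p.id, p.signal, sample=f"{d}_{t}h") for p in kept],
                mark="H3K4Me2", genome_size=template_all.genome_size)
    return catalogs


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Run the full generator: genome, counts, truth, and per-donor catalogs."""
    genes, template, truth_genes, truth_peaks = generate_genome(cfg)
    rna, chip, truth, template_all = simulate_counts(
        cfg, genes, template, truth_genes, truth_peaks)
    catalogs = build_catalogs(cfg, template_all, truth, genes)
    gene_lengths = pd.Series(
        {g.gene_id: g.body.length for g in genes}, name="length")
    return SimulatedDataset(cfg, genes, template_all, rna, chip, truth,
                            catalogs, gene_lengths)


# ---------------------------------------------------------------------------
# Dataset I/O


def _flatten_cols(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out.columns = [f"{a}:{b}" for a, b in df.columns]
    return out


def _unflatten_cols(df: pd.DataFrame, names) -> pd.DataFrame:
    df = df.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns], names=names)
    return df


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    """Write the dataset in the exact text dialects the core readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genes(ds.genes, outdir / "genes.tsv")
    write_peaks(ds.template, outdir / "peaks_template.bed")
    for (mark, donor, t), ps in ds.catalogs.items():
        write_peaks(ps, outdir / f"peaks_{mark}_{donor}_{t}h.bed")
    _flatten_cols(ds.rna_counts).rename_axis("gene_id").to_csv(
        outdir / "rna_counts.tsv", sep="\t")
    _flatten_cols(ds.chip_counts).rename_axis("peak_id").to_csv(
        outdir / "chip_counts.tsv", sep="\t")
    ds.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    ds.truth.peaks.to_csv(outdir / "truth_peaks.tsv", sep="\t", index=False)
    ds.gene_lengths.rename_axis("gene_id").to_csv(
        outdir / "gene_lengths.tsv", sep="\t")
    with (outdir / "sim_config.yaml").open("w") as fh:
        yaml.safe_dump(asdict(ds.config), fh)


def read_dataset(indir) -> SimulatedDataset:
    """Read back a dataset written by :func:`write_dataset`."""
    indir = Path(indir)
    with (indir / "sim_config.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    if isinstance(raw.get("timepoints"), list):
        raw["timepoints"] = tuple(raw["timepoints"])
    cfg = SimConfig(**raw)
    genes = read_genes(indir / "genes.tsv")
    clen = cfg.effective_chrom_length
    template = read_peaks(indir / "peaks_template.bed",
                          genome_size=clen * cfg.n_chroms)
    rna = _unflatten_cols(
        pd.read_csv(indir / "rna_counts.tsv", sep="\t", index_col=0),
        ["donor", "condition"]).rename_axis(None)
    chip = _unflatten_cols(
        pd.read_csv(indir / "chip_counts.tsv", sep="\t", index_col=0),
        ["donor", "timepoint"]).rename_axis(None)
    truth = TruthTable(
        genes=pd.read_csv(indir / "truth_genes.tsv", sep="\t"),
        peaks=pd.read_csv(indir / "truth_peaks.tsv", sep="\t",
                          keep_default_na=False),
    )
    catalogs = {}
    for f in sorted(indir.glob("peaks_H3K*_D*_*h.bed")):
        mark, donor, tp = f.stem.split("_")[1:4]
        catalogs[(mark, donor, int(tp[:-1]))] = read_peaks(
            f, mark=mark, genome_size=clen * cfg.n_chroms)
    gene_lengths = pd.read_csv(indir / "gene_lengths.tsv", sep="\t",
                               index_col=0)["length"]
    return SimulatedDataset(cfg, genes, template, rna, chip, truth,
                            catalogs, gene_lengths)
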