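"""Negative-binomial differential testing for RNA and ChIP count matrices.

The model is the standard count-based differential framework: per-sample
size factors by median-of-ratios, per-feature NB dispersion by
method-of-moments shrunk toward the ensemble mean, and a Wald test
on the difference of log normalized group means. The categorical thresholds
downstream of the test are the study's: genes are called up/down at
padj < 0.05, |log2FC| >= 0.8 and a per-condition mean RPKM above 1 in at
least one condition; peaks are called hyper/hypoacetylated at padj < 0.05
and fold change > 2 (|log2FC| > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "size_factors",
    "nb_test",
    "bh_adjust",
    "rpkm",
    "classify_genes",
    "classify_peaks",
    "select_unchanged_reference",
]

PADJ_THRESHOLD = 0.05
GENE_LFC_THRESHOLD = 0.8
PEAK_LFC_THRESHOLD = 1.0  # fold change > 2
RPKM_THRESHOLD = 1.0
#: prior weight (pseudo-degrees of freedom) pulling per-feature dispersion
#: estimates toward the trimmed ensemble mean; at two samples per group the
#: per-feature estimate has ~2 df, so the ensemble dominates
DISPERSION_PRIOR_DF = 20.0


@dataclass
class CountMatrix:
    """Features x samples integer counts with sample metadata.

    ``counts``: DataFrame indexed by feature id, one column per sample.
    ``metadata``: DataFrame indexed by sample (column) name with at least a
    ``condition`` column (and typically ``donor``).
    ``lengths``: feature lengths in bp, required for RPKM.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [c for c in self.counts.columns if c not in self.metadata.index]
        if missing:
            raise ValueError(f"metadata missing for samples: {missing}")
        if self.lengths is not None:
            absent = self.counts.index.difference(self.lengths.index)
            if len(absent):
                raise ValueError(f"lengths missing for {len(absent)} features")

    @classmethod
    def from_multiindex(cls, df: pd.DataFrame, lengths: pd.Series | None = None,
                        condition_level: str | None = None) -> "CountMatrix":
        """Build from a frame with (donor, condition/timepoint) column tuples."""
        flat = df.copy()
        names = list(df.columns.names)
        cond_level = condition_level or names[-1]
        meta = pd.DataFrame(
            [dict(zip(names, c)) for c in df.columns],
            index=[f"{a}_{b}" for a, b in df.columns],
        ).rename(columns={cond_level: "condition"})
        flat.columns = meta.index
        return cls(flat, meta, lengths)


def size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios per-sample normalization factors.

    For each feature with all-positive counts, compute count / geometric row
    mean; the factor is the per-sample median of those ratios. With a single
    sample the factor is 1. If no feature has all-positive counts, either
    raise (default) or, with ``pseudo_reference=True``, fall back to the same
    procedure on counts + 1.
    """
    if counts.shape[1] == 1:
        return pd.Series(1.0, index=counts.columns)
    mat = counts.to_numpy(dtype=float)
    if pseudo_reference:
        mat = mat + 1.0
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no feature with all-positive counts; rerun with "
            "pseudo_reference=True to normalize against counts + 1"
        )
    sub = mat[allpos]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    sf = np.exp(np.median(ratios, axis=0))
    return pd.Series(sf, index=counts.columns)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min over j >= i of min(1, m * p_(j) / j) on the sorted
    p-values; monotone nondecreasing in p-rank, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def nb_test(cm: CountMatrix, condition_a: str, condition_b: str,
            prior_df: float = DISPERSION_PRIOR_DF) -> pd.DataFrame:
    """Per-feature NB Wald test of condition_b vs condition_a (reference).

    Counts are normalized by median-of-ratios size factors; the per-feature
    dispersion is method-of-moments on the pooled within-group variance,
    shrunk toward the winsorized ensemble mean (computed over well-measured
    features) with ``prior_df`` pseudo observations. The Wald statistic is
    the difference of log group means over its delta-method standard error,
    referred to the standard normal.

    The reported ``log2fc`` carries a 0.5-count pseudo stabilizer for
    display; the statistic itself uses the raw normalized means. Features
    with all-zero counts are flagged untestable (p = 1, log2fc = 0), as are
    features observed in only one condition (the log-ratio is unbounded and
    the Wald approximation meaningless; such "born" peaks are handled by
    catalog analyses, not by testing).
    """
    meta = cm.metadata
    cols_a = [c for c in cm.counts.columns if meta.loc[c, "condition"] == condition_a]
    cols_b = [c for c in cm.counts.columns if meta.loc[c, "condition"] == condition_b]
    if not cols_a or not cols_b:
        raise ValueError(
            f"need >= 1 sample per condition ({condition_a!r}: {len(cols_a)}, "
            f"{condition_b!r}: {len(cols_b)})"
        )
    sub = cm.counts[cols_a + cols_b]
    sf = size_factors(sub, pseudo_reference=not (sub.to_numpy() > 0).all(axis=1).any())
    norm = sub.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    na, nb = len(cols_a), len(cols_b)
    A, B = norm[:, :na], norm[:, na:]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    base_mean = norm.mean(axis=1)

    # method-of-moments dispersion from pooled within-group variance
    df_within = max(na + nb - 2, 1)
    ss = ((A - mu_a[:, None]) ** 2).sum(axis=1) + ((B - mu_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_within
    mu_pool = base_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu_pool > 0, (s2 - mu_pool) / mu_pool**2, 0.0)
    alpha_raw = np.clip(alpha_raw, 0.0, 10.0)
    # ensemble dispersion from well-measured features, winsorized at the
    # 99th percentile so a handful of outliers cannot drag the mean
    informative = mu_pool > 50.0
    if informative.sum() < 10:
        informative = mu_pool > 1.0
    if informative.any():
        vals = alpha_raw[informative]
        alpha_ens = float(np.clip(vals, 0.0, np.quantile(vals, 0.99)).mean())
    else:
        alpha_ens = 0.0
    w = df_within / (df_within + prior_df)
    alpha = np.maximum(w * alpha_raw + (1 - w) * alpha_ens, 1e-8)

    testable = (mu_a > 0) & (mu_b > 0)
    all_zero = (mu_a == 0) & (mu_b == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.log(mu_b) - np.log(mu_a)
        se2 = (1.0 / mu_a + alpha) / na + (1.0 / mu_b + alpha) / nb
        z = np.where(testable, delta / np.sqrt(se2), 0.0)
    p = np.where(testable, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    log2fc = np.log2((mu_b + 0.5) / (mu_a + 0.5))
    log2fc = np.where(all_zero, 0.0, log2fc)

    res = pd.DataFrame(
        {
            "feature_id": cm.counts.index,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "mean_a": mu_a,
            "mean_b": mu_b,
            "p_value": p,
            "untestable": ~testable,
        }
    ).set_index("feature_id", drop=False)
    res["padj"] = bh_adjust(res["p_value"].to_numpy())
    return res


def rpkm(cm: CountMatrix) -> pd.DataFrame:
    """Reads per kilobase of feature per million mapped reads, per sample."""
    if cm.lengths is None:
        raise ValueError("RPKM requires feature lengths")
    counts = cm.counts.to_numpy(dtype=float)
    lengths = cm.lengths.reindex(cm.counts.index).to_numpy(dtype=float)
    per_million = counts.sum(axis=0) / 1e6
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = counts / (lengths[:, None] / 1e3) / per_million[None, :]
    return pd.DataFrame(vals, index=cm.counts.index, columns=cm.counts.columns)


def mean_rpkm_per_condition(cm: CountMatrix) -> pd.DataFrame:
    r = rpkm(cm)
    cond = cm.metadata.loc[r.columns, "condition"]
    return r.T.groupby(cond.values).mean().T


def classify_genes(res: pd.DataFrame, rpkm_by_condition: pd.DataFrame,
                   padj_threshold: float = PADJ_THRESHOLD,
                   lfc_threshold: float = GENE_LFC_THRESHOLD,
                   rpkm_threshold: float = RPKM_THRESHOLD) -> pd.DataFrame:
    """Categorize genes as up / down / unchanged.

    down: padj < 0.05 and log2fc <= -0.8 and max-condition mean RPKM > 1;
    up symmetric with log2fc >= 0.8; everything else unchanged. A pure
    threshold function of its inputs.
    """
    out = res.copy()
    max_rpkm = rpkm_by_condition.reindex(out.index).max(axis=1)
    out["max_rpkm"] = max_rpkm
    sig = (out["padj"] < padj_threshold) & (max_rpkm > rpkm_threshold)
    out["category"] = "unchanged"
    out.loc[sig & (out["log2fc"] <= -lfc_threshold), "category"] = "down"
    out.loc[sig & (out["log2fc"] >= lfc_threshold), "category"] = "up"
    return out


def classify_peaks(res: pd.DataFrame,
                   padj_threshold: float = PADJ_THRESHOLD,
                   lfc_threshold: float = PEAK_LFC_THRESHOLD) -> pd.DataFrame:
    """Categorize peaks as hyper / hypo / unchanged (FC > 2, padj < 0.05)."""
    out = res.copy()
    sig = out["padj"] < padj_threshold
    out["category"] = "unchanged"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "category"] = "hyper"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "category"] = "hypo"
    return out


def select_unchanged_reference(res: pd.DataFrame, rpkm_by_condition: pd.DataFrame,
                               k: int = 600,
                               rpkm_threshold: float = RPKM_THRESHOLD) -> list[str]:
    """The k expressed genes with the smallest |log2fc| (ties by feature id).

    This is the study's "unchanged" reference gene set for TSS metaprofiles.
    """
    max_rpkm = rpkm_by_condition.reindex(res.index).max(axis=1)
    pool = res[max_rpkm > rpkm_threshold].copy()
    if k > len(pool):
        raise ValueError(f"k={k} exceeds expressed-gene pool of {len(pool)}")
    pool = pool.reset_index(drop=True)
    pool["abs_lfc"] = pool["log2fc"].abs()
    pool = pool.sort_values(["abs_lfc", "feature_id"], kind="mergesort")
    return pool["feature_id"].head(k).tolist()
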