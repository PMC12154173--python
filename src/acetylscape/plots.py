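"""Optional figures rendered from a finished run directory.

Hockey-stick enhancer rankings, donut compositions of differential regions,
and TSS metaprofiles - each read back from the pipeline's intermediate TSV
files so plotting never re-runs analysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def hockey_stick(stitched_tsv, out_png) -> None:
    df = pd.read_csv(stitched_tsv, sep="\t").sort_values("total_signal")
    fig, ax = plt.subplots(figsize=(4, 3))
    colors = df["label"].map({"SE": "crimson", "TE": "grey"})
    ax.scatter(range(len(df)), df["total_signal"], s=4, c=colors)
    ax.axhline(df["cutoff_signal"].iloc[0], ls="--", lw=0.8, c="k")
    ax.set_xlabel("enhancer rank (ascending signal)")
    ax.set_ylabel("stitched H3K27Ac signal")
    n_se = int((df["label"] == "SE").sum())
    ax.set_title(f"{n_se} super-enhancers")
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def donuts(report_json, out_png) -> None:
    with open(report_json) as fh:
        donut = json.load(fh)["donut_fractions"]
    tps = sorted(donut, key=lambda t: int(t))
    fig, axes = plt.subplots(2, len(tps), figsize=(3 * len(tps), 6))
    palette = {"TSS": "#7b3294", "SE": "#fdb863", "TE": "#008837", "other": "#cccccc"}
    for j, t in enumerate(tps):
        for i, cls in enumerate(("hypo", "hyper")):
            ax = axes[i][j] if len(tps) > 1 else axes[i]
            fr = donut[t].get(cls, {})
            if fr:
                labels = [k for k in ("TSS", "SE", "TE", "other") if fr.get(k)]
                ax.pie([fr[k] for k in labels], labels=labels,
                       colors=[palette[k] for k in labels],
                       wedgeprops=dict(width=0.45), autopct="%.0f%%")
            ax.set_title(f"{cls} {t}h", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def metaprofiles(profiles_tsv, out_png) -> None:
    df = pd.read_csv(profiles_tsv, sep="\t")
    sets_ = df["gene_set"].unique()
    fig, axes = plt.subplots(1, len(sets_), figsize=(3.2 * len(sets_), 3),
                             sharey=True)
    if len(sets_) == 1:
        axes = [axes]
    for ax, gs in zip(axes, sets_):
        sub = df[df.gene_set == gs]
        for tp, grp in sub.groupby("timepoint"):
            ax.plot(grp["bin_center"], grp["signal"], label=tp, lw=1)
        ax.set_title(gs)
        ax.set_xlabel("distance to TSS (bp)")
    axes[0].set_ylabel("mean H3K27Ac density")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)


def render_all(run_dir: Path) -> list[Path]:
    run_dir = Path(run_dir)
    out = []
    for tsv in sorted(run_dir.glob("stitched_D*.tsv")):
        png = run_dir / f"hockey_{tsv.stem.split('_')[1]}.png"
        hockey_stick(tsv, png)
        out.append(png)
    if (run_dir / "report.json").exists():
        donuts(run_dir / "report.json", run_dir / "donuts.png")
        out.append(run_dir / "donuts.png")
    if (run_dir / "tss_profiles.tsv").exists():
        metaprofiles(run_dir / "tss_profiles.tsv", run_dir / "metaprofiles.png")
        out.append(run_dir / "metaprofiles.png")
    return out
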