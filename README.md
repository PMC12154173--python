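# acetylscape

Integrative analysis of histone-acetylation dynamics under HDAC inhibition.

Short-chain fatty acids such as butyrate inhibit histone deacetylases
(HDACs) and, paradoxically, silence the core activation program of primary
human mast cells while globally *increasing* H3K27 acetylation. Making
sense of that requires connecting several layers of evidence: which peaks
gain or lose acetylation over a treatment time course, where those regions
sit relative to transcription start sites (TSS), typical enhancers (TE)
and super-enhancers (SE), and which changes actually track with
transcriptional downregulation. `acetylscape` implements that analysis
chain as a tested, reusable Python package for epigenomics analysts:

* interval/peak data model with BED/TSV I/O, overlap, coverage-per-Mb and
  strand-aware nearest-TSS machinery (0-based half-open throughout);
* negative-binomial differential testing for RNA and ChIP count matrices —
  median-of-ratios size factors, moment-based dispersion shrunk toward a
  winsorized ensemble mean, Wald test, Benjamini–Hochberg FDR — with the
  study thresholds (genes: padj < 0.05, |log2FC| ≥ 0.8, RPKM > 1; peaks:
  padj < 0.05, fold change > 2);
* ROSE-style super-enhancer calling: stitch peaks within 12.5 kb after
  excluding TSS ± 2.5 kb windows, rank stitched regions by signal, and cut
  SE from TE at the tangent-slope-1 elbow of the unit-rescaled
  rank/signal curve;
* integrative analytics: exclusive TSS/SE/TE/other attribution of
  differential regions, TSS metaprofiles with area-under-curve reduction,
  per-gene enhancer landscapes, SE-hypoacetylation rates, per-compartment
  linkage to downregulated genes, a four-way epigenetic explanation of
  each downregulated gene, and the strongest-peak origin of
  hypoacetylation;
* a seeded synthetic-data generator that plants the expected effect
  structure (two donors × 0/3/12/24 h, H3K27Ac plus an H3K4Me2 control
  mark, TSS hypoacetylation at highly expressed downregulated genes,
  transient distal hyperacetylation, SE hypoacetylation coupled to
  downregulation, treatment-born peaks) together with a ground-truth table
  so every stage has a recovery test.

The model at the center of the differential stage is the standard NB count
model: counts K_ij ~ NB(mean = s_j · q_i · 2^(x_j·β_i), dispersion α), with
s_j the median-of-ratios size factor and a Wald z on β̂_i (the log fold
change). The SE definition is the ROSE one: after stitching and promoter
exclusion, a region is a super-enhancer iff its aggregate signal exceeds
the signal at the point where a slope-1 line is tangent to the rescaled
ranked-signal curve.

See `docs/methods.md` for the full model description, parameter defaults,
and what the simulation does and does not emulate.

## Worked example

Run the full pipeline on the default synthetic experiment:

```bash
acetylscape run --seed 1 --out demo_run
acetylscape report demo_run/report.json
```

which prints:

```
acetylscape report (schema v1, software 0.1.0, seed 1)
  genes: 800 (down 67, up 49)
  reproducible SEs: 95 (95 unique genes)
  SE hypoacetylation fraction: 0.9052631578947369
  link rates (% to down genes): {'SE': 36.04651162790697, 'TE': 13.793103448275861, 'TSS': 9.45945945945946}
  explanation classes: {'SE_only': 0.1044776119402985, 'TSS_and_SE': 0.3582089552238806, 'TSS_only': 0.373134328358209, 'unexplained': 0.16417910447761194}
  catalog fold (last vs first): {'H3K27Ac': {'D1': 2.593, 'D2': 2.595}, 'H3K4Me2': {'D1': 1.2992, 'D2': 1.3035}}
```

Reading those numbers: of 800 simulated genes, 67 are called
transcriptionally downregulated and 49 upregulated after 24 h of
treatment. Ninety-five super-enhancers reproduce across both donors, and
90.5% of them contain at least one significantly hypoacetylated distal
region at 24 h. A hypoacetylated super-enhancer is the strongest predictor
of downregulation (36% of them link to a down gene, vs ~14% for typical
enhancers and ~9% for TSS regions), and most downregulated genes are
epigenetically explained: 37% by promoter (TSS) hypoacetylation alone,
36% by TSS plus SE, 10% by SE alone, 16% unexplained. The H3K27Ac peak
catalog grows ~2.6-fold over the time course while the H3K4Me2 control
mark grows only ~1.3-fold — the HDAC-specific signature. The run directory
holds every intermediate (differential tables, stitched-region/SE tables,
attributions, TSS profiles) and a deterministic `report.json`; add
`--plots` to render the hockey-stick, donut and metaprofile figures.

`acetylscape simulate --seed 1 --out ds/` writes the synthetic dataset
itself (BED peak catalogs per mark/donor/timepoint, RNA and ChIP count
TSVs, gene models, truth tables), and `acetylscape run` in `files` mode
re-analyzes such a directory, reproducing the simulate-mode results
exactly.

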