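"""Region attribution, TSS metaprofiles/AUC, landscapes, linkage, explanation."""

import numpy as np
import pandas as pd
import pytest

from acetylscape.core import GeneModel, GenomicInterval, Peak, PeakSet
from acetylscape.integration import (
    attribute_regions,
    auc_reduction,
    composition_fractions,
    downreg_link_rate,
    enhancer_landscape,
    explain_downregulation,
    se_hypo_fraction,
    top_peak_origin,
    tss_metaprofile,
)
from acetylscape.superenhancers import StitchedRegion, SuperEnhancerCall


def mkpeak(start, end, pid, signal=1.0, chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), pid, signal)


def mkgene(gid, tss, chrom="chr1", strand="+"):
    body = GenomicInterval(chrom, tss, tss + 1_000) if strand == "+" \
        else GenomicInterval(chrom, tss - 1_000, tss)
    return GeneModel(gid, chrom, strand, tss, body, 10.0)


def mkcall(start, end, label="SE", genes=()):
    c = SuperEnhancerCall(
        StitchedRegion(GenomicInterval("chr1", start, end), [], 10.0),
        label, 1.0)
    c.associated_genes = list(genes)
    return c


GENES = [mkgene("g1", 100_000), mkgene("g2", 500_000)]


class TestAttribution:
    def test_tss_takes_precedence_over_se(self):
        # peak midpoint within 5 kb of g1's TSS AND inside an SE span
        peaks = PeakSet([mkpeak(102_000, 103_000, "p")])
        se = [StitchedRegion(GenomicInterval("chr1", 95_000, 110_000), [], 5.0)]
        out = attribute_regions(peaks, se, [], GENES)
        assert out.category.tolist() == ["TSS"]

    def test_te_only_peak(self):
        peaks = PeakSet([mkpeak(130_000, 131_000, "p")])
        te = [StitchedRegion(GenomicInterval("chr1", 129_000, 132_000), [], 5.0)]
        out = attribute_regions(peaks, [], te, GENES)
        assert out.category.tolist() == ["TE"]

    def test_other_when_nothing_matches(self):
        peaks = PeakSet([mkpeak(300_000, 301_000, "p")])
        out = attribute_regions(peaks, [], [], GENES)
        assert out.category.tolist() == ["other"]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(21)
        peaks = PeakSet([
            mkpeak(int(s), int(s) + 500, f"p{i}")
            for i, s in enumerate(rng.integers(0, 600_000, size=80))
        ])
        se = [StitchedRegion(GenomicInterval("chr1", 200_000, 240_000), [], 5.0)]
        te = [StitchedRegion(GenomicInterval("chr1", 300_000, 340_000), [], 5.0)]
        frac = composition_fractions(attribute_regions(peaks, se, te, GENES))
        assert abs(sum(frac.values()) - 1.0) < 1e-12

    def test_empty_set_flagged(self):
        assert composition_fractions(pd.DataFrame(columns=["category"])) == {}


class TestMetaprofile:
    def test_constant_density_gives_flat_profile(self):
        # one giant peak of uniform density 0.02 covering the whole window
        peaks = PeakSet([mkpeak(80_000, 120_000, "p", signal=800.0)])
        prof = tss_metaprofile(peaks, GENES, ["g1"], window=5_000, binsize=100)
        assert np.allclose(prof.values, 0.02)
        assert prof.auc() == pytest.approx(0.02 * (len(prof.values) - 1) * 100)

    def test_minus_strand_mirrors_plus_strand(self):
        plus, minus = mkgene("gp", 100_000, strand="+"), mkgene("gm", 100_000, strand="-")
        peaks = PeakSet([mkpeak(96_000, 97_000, "up", signal=10.0)])
        p1 = tss_metaprofile(peaks, [plus], ["gp"], window=5_000, binsize=100)
        p2 = tss_metaprofile(peaks, [minus], ["gm"], window=5_000, binsize=100)
        assert np.allclose(p1.values, p2.values[::-1])

    def test_window_binsize_mismatch_rejected(self):
        with pytest.raises(ValueError, match="multiple"):
            tss_metaprofile(PeakSet([]), GENES, ["g1"], window=5_000, binsize=300)

    def test_genes_without_signal_contribute_zeros(self):
        peaks = PeakSet([mkpeak(96_000, 97_000, "p", signal=10.0)])
        one = tss_metaprofile(peaks, GENES, ["g1"], window=5_000, binsize=100)
        both = tss_metaprofile(peaks, GENES, ["g1", "g2"], window=5_000, binsize=100)
        assert np.allclose(both.values, one.values / 2)


class TestAuc:
    def mkprof(self, values, tp):
        from acetylscape.integration import TssProfile
        v = np.asarray(values, dtype=float)
        centers = np.arange(-5_000 + 50, 5_000, 100)[: len(v)]
        return TssProfile("set", tp, centers, v, 10)

    def test_identical_profile_zero_reduction(self):
        profs = {"0h": self.mkprof([1, 2, 3, 2, 1], "0h"),
                 "3h": self.mkprof([1, 2, 3, 2, 1], "3h")}
        recs = {r.timepoint: r for r in auc_reduction(profs)}
        assert recs["3h"].reduction_vs_baseline == pytest.approx(0.0)

    def test_halved_profile_fifty_percent(self):
        profs = {"0h": self.mkprof([2, 4, 6, 4], "0h"),
                 "24h": self.mkprof([1, 2, 3, 2], "24h")}
        recs = {r.timepoint: r for r in auc_reduction(profs)}
        assert recs["24h"].reduction_vs_baseline == pytest.approx(50.0)

    def test_gain_reported_signed(self):
        profs = {"0h": self.mkprof([1, 1], "0h"), "3h": self.mkprof([2, 2], "3h")}
        recs = {r.timepoint: r for r in auc_reduction(profs)}
        assert recs["3h"].reduction_vs_baseline == pytest.approx(-100.0)

    def test_zero_baseline_flagged(self):
        profs = {"0h": self.mkprof([0, 0], "0h"), "3h": self.mkprof([1, 1], "3h")}
        recs = {r.timepoint: r for r in auc_reduction(profs)}
        assert recs["3h"].reduction_vs_baseline is None

    def test_trapezoid_matches_independent_sum(self):
        rng = np.random.default_rng(31)
        v = rng.uniform(0, 5, size=100)
        prof = self.mkprof(v, "0h")
        manual = float(sum((v[i] + v[i + 1]) / 2 * 100 for i in range(len(v) - 1)))
        assert prof.auc() == pytest.approx(manual, rel=1e-12)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            auc_reduction({"3h": self.mkprof([1], "3h")})


class TestLandscape:
    def test_tss_only_gene_has_empty_landscape(self):
        peaks = PeakSet([mkpeak(99_500, 100_500, "tss_peak")])
        out = enhancer_landscape("g1", peaks, GENES)
        assert len(out) == 0

    def test_distal_peak_included(self):
        peaks = PeakSet([mkpeak(129_500, 130_500, "te")])  # 30 kb from g1
        out = enhancer_landscape("g1", peaks, GENES)
        assert out.ids == ["te"]

    def test_unknown_gene_rejected(self):
        with pytest.raises(KeyError):
            enhancer_landscape("nope", PeakSet([]), GENES)

    def test_matches_filter_after_nearest_oracle(self):
        rng = np.random.default_rng(8)
        genes = [mkgene(f"g{i}", int(t))
                 for i, t in enumerate(rng.integers(10_000, 990_000, size=10))]
        peaks = PeakSet([
            mkpeak(int(s), int(s) + 400, f"p{i}")
            for i, s in enumerate(rng.integers(0, 995_000, size=150))
        ])
        for g in genes[:3]:
            got = set(enhancer_landscape(g.gene_id, peaks, genes).ids)
            expected = set()
            for p in peaks:
                mid = p.interval.midpoint
                nearest = min(genes, key=lambda x: (abs(mid - x.tss), x.tss,
                                                    x.gene_id))
                if nearest.gene_id != g.gene_id:
                    continue
                if min(abs(mid - x.tss) for x in genes) <= 5_000:
                    continue
                expected.add(p.id)
            assert got == expected


class TestSeHypoFraction:
    def test_no_hypo_peaks_zero(self):
        ses = [mkcall(200_000, 240_000)]
        frac, hypo = se_hypo_fraction(ses, PeakSet([]), GENES)
        assert frac == 0.0 and hypo == []

    def test_every_se_hit_gives_one(self):
        ses = [mkcall(200_000, 240_000), mkcall(300_000, 320_000)]
        hypo = PeakSet([mkpeak(210_000, 211_000, "h1"),
                        mkpeak(310_000, 311_000, "h2")])
        frac, _ = se_hypo_fraction(ses, hypo, GENES)
        assert frac == 1.0

    def test_tss_proximal_hypo_ignored(self):
        ses = [mkcall(96_000, 140_000)]
        hypo = PeakSet([mkpeak(99_000, 100_500, "h")])  # midpoint ~ TSS of g1
        frac, _ = se_hypo_fraction(ses, hypo, GENES)
        assert frac == 0.0

    def test_zero_ses_flagged(self):
        frac, _ = se_hypo_fraction([], PeakSet([]), GENES)
        assert frac is None


class TestLinkAndExplain:
    def attr(self, rows):
        return pd.DataFrame(rows, columns=["peak_id", "gene_id", "category"])

    def test_all_linked_hundred_percent(self):
        ses = [mkcall(0, 1_000, genes=["g1"]), mkcall(5_000, 6_000, genes=["g2"])]
        rates = downreg_link_rate(self.attr([]), {"g1", "g2"}, ses)
        assert rates["SE"] == 100.0

    def test_no_down_genes_zero(self):
        attr = self.attr([("p1", "g1", "TSS"), ("p2", "g2", "TE")])
        rates = downreg_link_rate(attr, set(), [mkcall(0, 1_000, genes=["g1"])])
        assert rates == {"TSS": 0.0, "TE": 0.0, "SE": 0.0}

    def test_empty_category_flagged(self):
        rates = downreg_link_rate(self.attr([("p1", "g1", "TSS")]), {"g1"}, [])
        assert rates["TE"] is None and rates["SE"] is None
        assert rates["TSS"] == 100.0

    def test_expressed_filter_restricts_denominator(self):
        attr = self.attr([("p1", "g1", "TSS"), ("p2", "gX", "TSS")])
        rates = downreg_link_rate(attr, {"g1"}, [], expressed_genes={"g1"})
        assert rates["TSS"] == 100.0

    def test_explanation_classes(self):
        attr = self.attr([("p1", "gA", "TSS"), ("p2", "gB", "TSS")])
        df, props = explain_downregulation(
            ["gA", "gB", "gC", "gD"], attr, hypo_se_genes={"gB", "gC"})
        by = df.set_index("gene_id")["class"]
        assert by["gA"] == "TSS_only" and by["gB"] == "TSS_and_SE"
        assert by["gC"] == "SE_only" and by["gD"] == "unexplained"
        assert props == {"TSS_only": 0.25, "TSS_and_SE": 0.25,
                         "SE_only": 0.25, "unexplained": 0.25}

    def test_classes_partition_down_genes(self):
        rng = np.random.default_rng(17)
        down = [f"g{i}" for i in range(40)]
        attr = self.attr([(f"p{i}", rng.choice(down), "TSS") for i in range(30)])
        df, props = explain_downregulation(
            down, attr, hypo_se_genes=set(rng.choice(down, size=10)))
        assert sorted(df.gene_id) == sorted(down)
        assert sum(props.values()) == pytest.approx(1.0)


class TestTopOrigin:
    def catalog(self, signals):
        return PeakSet([
            mkpeak(i * 1_000, i * 1_000 + 100, f"p{i}", signal=float(s))
            for i, s in enumerate(signals)
        ])

    def test_all_hypo_in_top(self):
        ps = self.catalog([100, 90, 80, 1, 1, 1])
        out = top_peak_origin(ps, ["p0", "p1"], n_top=3)
        assert out["fraction_hypo_from_top"] == 1.0

    def test_no_hypo_in_top(self):
        ps = self.catalog([100, 90, 80, 1, 1, 1])
        out = top_peak_origin(ps, ["p4", "p5"], n_top=3)
        assert out["fraction_hypo_from_top"] == 0.0

    def test_new_peaks_excluded_and_counted(self):
        ps = self.catalog([100, 1])
        out = top_peak_origin(ps, ["p0", "ghost"], n_top=1)
        assert out["n_excluded_new"] == 1 and out["fraction_hypo_from_top"] == 1.0

    def test_n_top_beyond_catalog_rejected(self):
        with pytest.raises(ValueError):
            top_peak_origin(self.catalog([1, 2]), ["p0"], n_top=3)
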