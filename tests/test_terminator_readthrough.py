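"""Readthrough ratio arithmetic, classification, and exclusion rules."""

import math

import numpy as np
import pytest

from senterm import terminator_readthrough as tr
from senterm.genome_io import Feature, FeatureSet, Interval

from conftest import make_probe_map, make_track


def snr_gene(start=100, length=200, strand="+", chrom="chrT", gene_id="snrA"):
    iv = Interval(chrom, start, start + length, strand)
    mature = iv.end if strand == "+" else iv.start
    return Feature(gene_id, "snr", iv, mature_end=mature)


def level_track(pm, linear_by_region, default=0.0):
    """Build an RNA-level track whose linear value is piecewise constant.

    linear_by_region: list of (start, end, linear_value).
    """
    values = np.zeros(len(pm))
    for start, end, lin in [(None, None, default)] + list(linear_by_region):
        for i, c in enumerate(pm.centers):
            if start is None or start <= c < end:
                values[i] = math.log2(lin) if lin > 1 else 0.0
    return make_track(values, pm, kind="rna_level")


class TestRatio:
    def test_zero_downstream_is_zero_percent(self):
        pm = make_probe_map(n=200, spacing=5, start=2)
        gene = snr_gene(100, 200)
        track = level_track(pm, [(100, 300, 64.0)])
        ratio, body, down = tr.readthrough_ratio(gene, track)
        assert ratio == 0.0 and body == 64.0

    def test_equal_downstream_is_hundred_percent(self):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        track = level_track(pm, [(100, 700, 64.0)])
        ratio, _, _ = tr.readthrough_ratio(gene, track)
        assert ratio == pytest.approx(100.0)

    def test_zero_body_is_undefined(self):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        track = level_track(pm, [(310, 610, 64.0)])
        ratio, body, _ = tr.readthrough_ratio(gene, track)
        assert math.isnan(ratio) and body == 0.0

    def test_max50_picks_best_subwindow(self):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        # downstream scan region is [310, 610); plant a hot 50-bp island
        track = level_track(pm, [(100, 300, 64.0), (400, 450, 32.0)])
        r_max, _, down_max = tr.readthrough_ratio(gene, track, window_rule="max50")
        r_mean, _, down_mean = tr.readthrough_ratio(gene, track, window_rule="mean_region")
        assert down_max == pytest.approx(32.0)
        assert r_max == pytest.approx(50.0)
        assert r_mean < r_max

    def test_scale_invariance(self):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        t1 = level_track(pm, [(100, 300, 64.0), (310, 610, 16.0)])
        t8 = level_track(pm, [(100, 300, 8 * 64.0), (310, 610, 8 * 16.0)])
        r1, _, _ = tr.readthrough_ratio(gene, t1)
        r8, _, _ = tr.readthrough_ratio(gene, t8)
        assert r1 == pytest.approx(r8)

    def test_minus_strand_mirror_gives_same_ratio(self):
        pm = make_probe_map(n=300, spacing=5)
        plus = snr_gene(700, 200, "+")
        minus = snr_gene(500, 200, "-")
        t_plus = level_track(pm, [(700, 900, 64.0), (910, 1210, 16.0)])
        t_minus = level_track(pm, [(500, 700, 64.0), (190, 490, 16.0)])
        rp, _, _ = tr.readthrough_ratio(plus, t_plus)
        rm, _, _ = tr.readthrough_ratio(minus, t_minus)
        assert rp == pytest.approx(rm)

    def test_oracle_direct_windowed_means(self):
        # ratios recomputed by direct averaging over the track's probes
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        rng = np.random.default_rng(9)
        values = np.where(rng.uniform(size=len(pm)) < 0.8,
                          rng.uniform(1, 8, len(pm)), 0.0)
        track = make_track(values, pm, kind="rna_level")
        ratio, body, down = tr.readthrough_ratio(gene, track, window_rule="mean_region")
        lin = np.where(values > 0, 2.0 ** values, 0.0)
        sel_body = (pm.centers >= 100) & (pm.centers < 300)
        sel_down = (pm.centers >= 310) & (pm.centers < 610)
        assert body == pytest.approx(lin[sel_body].mean(), abs=1e-9)
        assert down == pytest.approx(lin[sel_down].mean(), abs=1e-9)
        assert ratio == pytest.approx(100 * down / body, abs=1e-9)


class TestClassification:
    def test_identical_tracks_classify_none(self):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        track = level_track(pm, [(100, 300, 64.0), (310, 610, 16.0)])
        rec = tr.differential_readthrough(gene, track, track)
        assert rec.differential == 0.0 and rec.classification == "none"

    @pytest.mark.parametrize(
        "mutant_linear,expected",
        [(4.0, "none"), (16.0, "readthrough"), (80.0, "confounded")],
    )
    def test_threshold_rules(self, mutant_linear, expected):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        wt = level_track(pm, [(100, 300, 64.0)])
        mut = level_track(pm, [(100, 300, 64.0), (310, 610, mutant_linear)])
        rec = tr.differential_readthrough(gene, mut, wt)
        assert rec.classification == expected

    def test_body_decrease_note(self):
        # defect driven by diminished mature RNA rather than extra downstream
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        wt = level_track(pm, [(100, 300, 64.0), (310, 610, 2.0)])
        mut = level_track(pm, [(100, 300, 16.0), (310, 610, 3.0)])
        rec = tr.differential_readthrough(gene, mut, wt)
        assert rec.classification == "readthrough"
        assert "body-decrease" in rec.notes

    def test_undefined_propagates(self):
        pm = make_probe_map(n=200, spacing=5)
        gene = snr_gene(100, 200)
        wt = level_track(pm, [])  # zero body
        mut = level_track(pm, [(100, 300, 64.0)])
        rec = tr.differential_readthrough(gene, mut, wt)
        assert rec.classification == "undefined"


class TestExclusion:
    def test_isolated_gene_not_excluded(self):
        gene = snr_gene(1000, 200)
        flags = tr.flag_confounded_genes(FeatureSet([gene]), FeatureSet([gene]))
        assert flags[gene.id] is False

    def test_cut_fifty_bp_downstream_excludes(self):
        gene = snr_gene(1000, 200)
        cut = Feature("cutZ", "cut", Interval("chrT", 1250, 1500, "+"))
        flags = tr.flag_confounded_genes(
            FeatureSet([gene]), FeatureSet([gene, cut])
        )
        assert flags[gene.id] is True

    def test_mask_and_polya_do_not_exclude(self):
        gene = snr_gene(1000, 200)
        others = FeatureSet(
            [
                gene,
                Feature("m", "mask", Interval("chrT", 1200, 1600)),
                Feature("pa", "polyA_cluster", Interval("chrT", 1210, 1260, "+")),
            ]
        )
        assert tr.flag_confounded_genes(FeatureSet([gene]), others)[gene.id] is False

    def test_overrides(self):
        gene = snr_gene(1000, 200)
        cut = Feature("cutZ", "cut", Interval("chrT", 1250, 1500, "+"))
        both = FeatureSet([gene, cut])
        flags = tr.flag_confounded_genes(FeatureSet([gene]), both, include={gene.id})
        assert flags[gene.id] is False
        flags = tr.flag_confounded_genes(FeatureSet([gene]), FeatureSet([gene]),
                                         exclude={gene.id})
        assert flags[gene.id] is True


class TestTable:
    def test_counts_and_shape(self):
        pm = make_probe_map(n=400, spacing=5)
        g1 = snr_gene(100, 200, gene_id="s1")
        g2 = snr_gene(1000, 200, gene_id="s2")
        genes = FeatureSet([g1, g2])
        wt = level_track(pm, [(100, 300, 64.0), (1000, 1200, 64.0)])
        mut = level_track(pm, [(100, 300, 64.0), (310, 610, 32.0), (1000, 1200, 64.0)])
        table = tr.readthrough_table(genes, {"WT": wt, "mut": mut}, "WT")
        assert len(table) == 2  # 2 genes x 1 mutant
        counts = tr.count_defective(table)
        assert counts["mut"] == 1
        wide = tr.to_wide(table)
        assert wide.shape == (2, 1)
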