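"""Coordinate conventions, format round trips, and masking."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from senterm import genome_io as gio
from senterm.genome_io import Feature, FeatureSet, Interval, ParseError

from conftest import make_probe_map, make_track, make_intensities


class TestInterval:
    def test_reversed_bounds_are_normalized(self):
        iv = Interval("chrXV", 771_766, 722_818)
        assert (iv.start, iv.end) == (722_818, 771_766)

    def test_rejects_negative_start_and_empty_chrom(self):
        with pytest.raises(ValueError):
            Interval("chr1", -5, 10)
        with pytest.raises(ValueError):
            Interval("", 0, 10)


class TestFeatureIO:
    def test_gff3_one_based_inclusive_to_internal(self, tmp_path):
        path = tmp_path / "f.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=geneA\n"
        )
        feats = gio.read_features(path, format="gff3")
        iv = feats["geneA"].interval
        assert (iv.start, iv.end, iv.strand) == (100, 200, "+")

    def test_bed_zero_based_passthrough(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chr1\t99\t200\tgeneX\t0\t-\n")
        iv = gio.read_features(path, format="bed")["geneX"].interval
        assert (iv.start, iv.end, iv.strand) == (99, 200, "-")

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("chr1\tsrc\tgene\t10\t20\t.\t+\t.\tID=a\nchr1\tbroken\n")
        with pytest.raises(ParseError, match=":2"):
            gio.read_features(path, format="gff3")

    @pytest.mark.parametrize("fmt", ["gff3", "bed"])
    def test_round_trip_preserves_intervals(self, tmp_path, fmt):
        feats = FeatureSet(
            [
                Feature("a", "orf", Interval("chr1", 0, 500, "+")),
                Feature("b", "snr", Interval("chr1", 600, 900, "-"), mature_end=650),
                Feature("c", "mask", Interval("chr2", 10, 20, ".")),
            ]
        )
        path = tmp_path / f"f.{fmt}"
        gio.write_features(feats, path, format=fmt)
        back = gio.read_features(path, format=fmt)
        for f in feats:
            assert back[f.id].interval == f.interval
            if fmt == "gff3":
                assert back[f.id].kind == f.kind
                assert back[f.id].mature_end == f.mature_end

    @settings(max_examples=30, deadline=None)
    @given(
        start=st.integers(min_value=0, max_value=10_000),
        length=st.integers(min_value=1, max_value=5_000),
        strand=st.sampled_from(["+", "-"]),
    )
    def test_gff3_round_trip_property(self, tmp_path_factory, start, length, strand):
        tmp = tmp_path_factory.mktemp("rt")
        feats = FeatureSet(
            [Feature("g", "orf", Interval("chr1", start, start + length, strand))]
        )
        path = tmp / "f.gff3"
        gio.write_features(feats, path)
        assert gio.read_features(path)["g"].interval == feats["g"].interval

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "f.gff3.gz"
        with gzip.open(path, "wt") as fh:
            fh.write("chr1\tsrc\tgene\t1\t50\t.\t+\t.\tID=z\n")
        assert gio.read_features(path)["z"].interval.start == 0


class TestIntensityIO:
    def test_shuffled_file_order_matches_sorted(self, tmp_path):
        pm = make_probe_map(n=3)
        rows = [f"{pid}\t{10 + i}\t{5 + i}" for i, pid in enumerate(pm.probe_ids)]
        header = "probe_id\tPM_a_rep1\tMM_a_rep1"
        sorted_path = tmp_path / "sorted.tsv"
        sorted_path.write_text("\n".join([header] + rows) + "\n")
        shuffled_path = tmp_path / "shuffled.tsv"
        shuffled_path.write_text("\n".join([header] + rows[::-1]) + "\n")
        a = gio.read_intensities(sorted_path, pm)
        b = gio.read_intensities(shuffled_path, pm)
        assert np.array_equal(a.pm, b.pm) and np.array_equal(a.mm, b.mm)
        assert a.pm.shape == (1, 3)

    def test_missing_probe_error_names_it(self, tmp_path):
        pm = make_probe_map(n=3)
        path = tmp_path / "short.tsv"
        path.write_text(
            "probe_id\tPM_a\tMM_a\n"
            + f"{pm.probe_ids[0]}\t10\t5\n"
            + f"{pm.probe_ids[1]}\t10\t5\n"
        )
        with pytest.raises(ParseError, match=str(pm.probe_ids[2])):
            gio.read_intensities(path, pm)

    def test_negative_intensity_rejected(self, tmp_path):
        pm = make_probe_map(n=1)
        path = tmp_path / "neg.tsv"
        path.write_text(f"probe_id\tPM_a\tMM_a\n{pm.probe_ids[0]}\t-1\t5\n")
        with pytest.raises(ParseError, match="negative"):
            gio.read_intensities(path, pm)

    def test_write_read_identity(self, tmp_path):
        pm = make_probe_map(n=5)
        rng = np.random.default_rng(0)
        iset = make_intensities(
            rng.uniform(10, 100, (2, 5)).round(4), rng.uniform(1, 50, (2, 5)).round(4), pm
        )
        path = tmp_path / "i.tsv"
        gio.write_intensities(iset, path)
        back = gio.read_intensities(path, pm)
        np.testing.assert_allclose(back.pm, iset.pm, atol=1e-6)
        np.testing.assert_allclose(back.mm, iset.mm, atol=1e-6)
        assert [a.label for a in back.arrays] == [a.label for a in iset.arrays]


class TestTrackIO:
    def test_constant_track_collapses_in_bedgraph(self, tmp_path):
        pm = make_probe_map(n=3)
        track = make_track([1.5, 1.5, 1.5], pm)
        path = tmp_path / "t.bedgraph"
        gio.write_track(track, path, format="bedgraph")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("track")]
        assert len(lines) <= 3
        assert all(l.split("\t")[3] == "1.500000" for l in lines)

    def test_tsv_round_trip_six_decimals(self, tmp_path):
        pm = make_probe_map(n=4)
        track = make_track([0.1234567, -2.5, np.nan, 7.0], pm)
        path = tmp_path / "t.tsv"
        gio.write_track(track, path, format="tsv")
        back = gio.read_track(path, pm, "rna_level", 101, "mut")
        np.testing.assert_allclose(back.values[[0, 1, 3]], [0.123457, -2.5, 7.0], atol=1e-6)
        assert np.isnan(back.values[2])

    def test_missing_values_omitted_from_bedgraph(self, tmp_path):
        pm = make_probe_map(n=3)
        track = make_track([1.0, np.nan, 2.0], pm)
        path = tmp_path / "t.bedgraph"
        gio.write_track(track, path, format="bedgraph")
        lines = [l for l in path.read_text().splitlines() if not l.startswith("track")]
        starts = {int(l.split("\t")[1]) for l in lines}
        assert int(pm.centers[1]) not in starts


class TestMaskTrack:
    def test_plasmid_masks_remove_exactly_inside_probes(self):
        # the published mask spans, one of them printed high->low
        records = []
        for c in [722_000, 722_820, 750_000, 771_760, 771_900]:
            records.append((f"chrXV:p{c}", "chrXV", c))
        for c in [91_000, 91_200, 92_700, 92_800]:
            records.append((f"chrIII:p{c}", "chrIII", c))
        pm = gio.ProbeMap.from_records(records)
        track = make_track(np.arange(len(pm), dtype=float), pm)
        masks = FeatureSet(
            [
                Feature("his3", "mask", Interval("chrXV", 771_766, 722_818)),
                Feature("leu2", "mask", Interval("chrIII", 91_185, 92_702)),
            ]
        )
        out = gio.mask_track(track, masks)
        by_pos = dict(zip(pm.centers, out.values))
        assert np.isnan(by_pos[722_820]) and np.isnan(by_pos[750_000])
        assert np.isnan(by_pos[771_760])
        assert not np.isnan(by_pos[722_000]) and not np.isnan(by_pos[771_900])
        assert np.isnan(by_pos[91_200]) and np.isnan(by_pos[92_700])
        assert not np.isnan(by_pos[91_000]) and not np.isnan(by_pos[92_800])

    def test_empty_mask_is_identity_and_masking_is_idempotent(self):
        pm = make_probe_map(n=10)
        track = make_track(np.arange(10, dtype=float), pm)
        assert np.array_equal(gio.mask_track(track, FeatureSet()).values, track.values)
        masks = FeatureSet([Feature("m", "mask", Interval("chrT", 10, 30))])
        once = gio.mask_track(track, masks)
        twice = gio.mask_track(once, masks)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_whole_genome_mask_blanks_everything(self):
        pm = make_probe_map(n=10)
        track = make_track(np.ones(10), pm)
        masks = FeatureSet([Feature("m", "mask", Interval("chrT", 0, 10_000))])
        assert np.isnan(gio.mask_track(track, masks).values).all()

    def test_non_mask_kind_rejected(self):
        pm = make_probe_map(n=2)
        track = make_track([1.0, 2.0], pm)
        bad = FeatureSet([Feature("g", "orf", Interval("chrT", 0, 10, "+"))])
        with pytest.raises(ValueError):
            gio.mask_track(track, bad)
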