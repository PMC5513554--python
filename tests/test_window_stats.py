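"""Rank statistics against exhaustive/brute-force oracles and scipy."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from senterm import window_stats as ws
from senterm.window_stats import WindowSpec, WindowValues

from conftest import make_intensities, make_probe_map


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def enumerate_signed_rank_p(d):
    """Exact one-sided p by enumerating all 2^n sign assignments of the
    nonzero values (zeros ranked but excluded, midranks for ties)."""
    d = np.asarray(d, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    nz = d != 0
    r = ranks[nz]
    w_obs = r[d[nz] > 0].sum()
    n = len(r)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(ri for ri, s in zip(r, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n if n else 1.0


def brute_pseudomedian(d):
    walsh = [(a + b) / 2 for a, b in itertools.combinations_with_replacement(d, 2)]
    return float(np.median(walsh))


def brute_shift(a, b):
    return float(np.median([x - y for x in a for y in b]))


# ---------------------------------------------------------------------------
# Hodges-Lehmann estimators
# ---------------------------------------------------------------------------


class TestHodgesLehmann:
    def test_walsh_average_example(self):
        # {1,2,3}: Walsh averages 1, 1.5, 2, 2, 2.5, 3 -> median 2
        assert ws.pseudomedian(np.array([1.0, 2.0, 3.0])) == 2.0

    def test_shift_example(self):
        # all 9 pairwise differences of {1,2,3} vs {0,1,2}: median 1
        assert ws.hl_shift(np.array([1.0, 2.0, 3.0]), np.array([0.0, 1.0, 2.0])) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.integers(-20, 20), min_size=1, max_size=12))
    def test_pseudomedian_matches_brute_force(self, vals):
        d = np.array(vals, dtype=float)
        assert abs(ws.pseudomedian(d) - brute_pseudomedian(d)) < 1e-9

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.integers(-20, 20), min_size=1, max_size=8),
        st.lists(st.integers(-20, 20), min_size=1, max_size=8),
    )
    def test_shift_matches_brute_force(self, a, b):
        assert abs(ws.hl_shift(np.array(a, float), np.array(b, float)) - brute_shift(a, b)) < 1e-9

    def test_shift_equivariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=15), rng.normal(size=12)
        base = ws.hl_shift(a, b)
        assert abs(ws.hl_shift(a + 2.5, b) - (base + 2.5)) < 1e-12


# ---------------------------------------------------------------------------
# signed-rank test
# ---------------------------------------------------------------------------


class TestSignedRank:
    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(-6, 6), min_size=1, max_size=11))
    def test_exact_p_matches_sign_enumeration(self, vals):
        # integer-valued inputs force ties and zeros, the hard cases
        d = np.array(vals, dtype=float)
        p = ws.signed_rank_p(d)
        assert abs(p - enumerate_signed_rank_p(d)) < 1e-12

    def test_matches_scipy_normal_approximation(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.2, 1.0, size=40)  # continuous: no ties/zeros
        ours = ws.signed_rank_p(d)
        ref = stats.wilcoxon(d, alternative="greater", correction=True, method="approx").pvalue
        assert abs(ours - ref) < 1e-12

    def test_all_zero_window_gives_p_one(self):
        assert ws.signed_rank_p(np.zeros(10)) == 1.0

    def test_signal_example(self):
        score, s, level = ws.signed_rank_signal(
            WindowValues(d=np.array([1.0, 2.0, 3.0]), x=np.log2([1.0, 2.0, 3.0]))
        )
        assert s == 2.0
        assert level == 1.0

    def test_floor_rule_zero_level_for_weak_signal(self):
        d = np.array([0.5, 0.8, 1.0, 0.2])
        _, s, level = ws.signed_rank_signal(WindowValues(d=d, x=np.zeros(4)))
        assert s <= 1.0 and level == 0.0

    def test_detection_score_definition(self):
        assert ws.detection_score(1.0) == 0.0
        assert abs(ws.detection_score(0.1) - 10.0) < 1e-12


class TestRankSum:
    @settings(max_examples=40, deadline=None)
    @given(
        st.lists(st.integers(-5, 5), min_size=2, max_size=12),
        st.lists(st.integers(-5, 5), min_size=2, max_size=12),
    )
    def test_matches_scipy_mannwhitney_with_ties(self, a, b):
        a, b = np.array(a, float), np.array(b, float)
        ours = ws.rank_sum_p(a, b)
        ref = stats.mannwhitneyu(a, b, method="asymptotic").pvalue
        assert abs(ours - ref) < 1e-9

    def test_identical_groups_shift_zero(self):
        v = WindowValues(d=np.array([1.0, 2.0]), x=np.array([0.0, 1.0]))
        score, shift = ws.rank_sum_differential(v, v)
        assert shift == 0.0
        assert score == 0.0


# ---------------------------------------------------------------------------
# window collection and tracks
# ---------------------------------------------------------------------------


class TestCollectWindow:
    def test_width_one_takes_only_center(self):
        pm = make_probe_map(n=10, spacing=5)
        data = make_intensities(
            np.arange(10, dtype=float)[None, :] + 10.0, np.zeros((1, 10)), pm
        )
        v = ws.collect_window(pm, data, int(pm.centers[4]), WindowSpec(1), data.labels)
        assert len(v.d) == 1
        assert v.d[0] == data.pm[0, 4]

    def test_interior_101bp_window_holds_21_probes(self):
        # positions every 5 bp within +-50 bp of the center: 21 by enumeration
        pm = make_probe_map(n=60, spacing=5)
        data = make_intensities(np.ones((1, 60)), np.zeros((1, 60)), pm)
        v = ws.collect_window(pm, data, int(pm.centers[30]), WindowSpec(101), data.labels)
        assert len(v.d) == 21

    def test_chromosome_edge_truncates(self):
        pm = make_probe_map(n=60, spacing=5)
        data = make_intensities(np.ones((1, 60)), np.zeros((1, 60)), pm)
        v = ws.collect_window(pm, data, int(pm.centers[0]), WindowSpec(101), data.labels)
        assert len(v.d) == 11  # center plus ten probes to the right

    def test_even_width_rounded_up(self):
        assert WindowSpec(100).width_bp == 101


class TestTracks:
    def test_constant_signal_gives_constant_interior_track(self):
        pm = make_probe_map(n=60, spacing=5)
        data = make_intensities(
            np.full((2, 60), 120.0), np.full((2, 60), 20.0), pm, strains=["s", "s"]
        )
        track, _ = ws.signal_track(pm, data, "s")
        interior = track.values[10:-10]
        np.testing.assert_allclose(interior, math.log2(100.0), atol=1e-9)

    def test_wider_window_reduces_null_variance(self):
        rng = np.random.default_rng(4)
        pm = make_probe_map(n=400, spacing=5)
        mm = np.full((4, 400), 20.0)
        pm_mat = mm + rng.gamma(2.0, 30.0, size=(4, 400))
        data = make_intensities(pm_mat, mm, pm, strains=["t", "t", "c", "c"])
        narrow, _ = ws.differential_track(pm, data, "t", "c", WindowSpec(101))
        wide, _ = ws.differential_track(pm, data, "t", "c", WindowSpec(501))
        assert np.var(wide.values[60:-60]) < np.var(narrow.values[60:-60])

    def test_log2fc_requires_baseline(self):
        pm = make_probe_map(n=4)
        data = make_intensities(np.ones((1, 4)), np.zeros((1, 4)), pm)
        with pytest.raises(ValueError):
            ws.make_track(pm, data, mode="log2fc", strain="s0")
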