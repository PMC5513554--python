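"""Sliding-window rank statistics with Hodges-Lehmann estimates.

This is the computational core of the pipeline, a reimplementation of the
per-position analysis performed by Affymetrix Tiling Analysis Software on
PM/MM tiling arrays:

* RNA level per strain: a one-sample Wilcoxon signed-rank test of the
  PM - MM differences in a bp-defined window against zero (one-sided,
  positive), with the Hodges-Lehmann pseudomedian ``s`` of the differences as
  the signal estimate.  ``s > 1`` is reported as ``log2(s)``; otherwise the
  RNA level is 0.
* Differential RNA level (mutant vs matched wild-type): a two-sample
  Wilcoxon rank-sum test on the ``log2(max(PM - MM, 1))`` values of the two
  groups, with the two-sample Hodges-Lehmann shift (median of all pairwise
  differences) reported directly as the log2 fold change.
* Detection scores are ``-10 log10(p)``.

Zeros in the signed-rank test are handled by Pratt's method (zeros are
ranked, then dropped from the statistic; the null is conditional on the
observed zeros); ties receive midranks.  The null distribution is exact
(convolution over doubled midranks) for up to ``exact_n_max`` nonzero values
and a continuity-corrected normal approximation beyond.  The rank-sum test
uses the tie-corrected normal approximation with continuity correction.

Windows are defined in base pairs, centered on each probe, both ends
inclusive, and truncated at chromosome ends.  Replicate arrays of a group are
pooled into one window sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .genome_io import IntensitySet, ProbeMap, SignalTrack

DEFAULT_WINDOW_BP = 101
EXACT_N_MAX = 25

__all__ = [
    "WindowSpec",
    "WindowValues",
    "collect_window",
    "signed_rank_signal",
    "rank_sum_differential",
    "make_track",
    "signal_track",
    "differential_track",
    "pseudomedian",
    "hl_shift",
    "signed_rank_p",
    "rank_sum_p",
]


@dataclass(frozen=True)
class WindowSpec:
    """A bp-defined smoothing window centered on a probe position.

    Even widths are rounded up to the next odd number so the window is
    symmetric around the center probe.
    """

    width_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        if self.width_bp < 1:
            raise ValueError("window width must be >= 1")
        if self.width_bp % 2 == 0:
            object.__setattr__(self, "width_bp", self.width_bp + 1)

    @property
    def half(self) -> int:
        return (self.width_bp - 1) // 2


@dataclass
class WindowValues:
    """Probe-level values collected in one window across a group's arrays.

    ``d`` holds the linear PM - MM differences; ``x`` holds the
    ``log2(max(d, 1))`` transforms used by the differential statistics.
    """

    d: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        if len(self.d) != len(self.x):
            raise ValueError("d and x must have equal length")


def _window_bounds(pm: ProbeMap, spec: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-probe [lo, hi) index bounds of the bp window, per chromosome."""
    n = len(pm)
    lo = np.empty(n, dtype=np.int64)
    hi = np.empty(n, dtype=np.int64)
    for chrom in np.unique(pm.chroms):
        sl = pm.chrom_slice(str(chrom))
        centers = pm.centers[sl]
        lo[sl] = sl.start + np.searchsorted(centers, centers - spec.half, side="left")
        hi[sl] = sl.start + np.searchsorted(centers, centers + spec.half, side="right")
    return lo, hi


def collect_window(
    probe_map: ProbeMap,
    intensities: IntensitySet,
    center: int,
    spec: WindowSpec,
    arrays: list[str],
    chrom: str | None = None,
) -> WindowValues:
    """Collect PM - MM differences for all probes within ``spec.half`` bp of
    ``center`` (same chromosome, both ends inclusive) across ``arrays``."""
    if chrom is None:
        hits = np.flatnonzero(probe_map.centers == center)
        if len(hits) == 0:
            raise ValueError(f"center {center} is not a probe position")
        chrom = str(probe_map.chroms[hits[0]])
    sl = probe_map.chrom_slice(chrom)
    centers = probe_map.centers[sl]
    lo = sl.start + int(np.searchsorted(centers, center - spec.half, side="left"))
    hi = sl.start + int(np.searchsorted(centers, center + spec.half, side="right"))
    idx = intensities.array_indices(arrays)
    d = (intensities.pm[idx, lo:hi] - intensities.mm[idx, lo:hi]).ravel()
    return WindowValues(d=d, x=np.log2(np.maximum(d, 1.0)))


# ---------------------------------------------------------------------------
# rank statistics (authored here; scipy provides only the distributions)
# ---------------------------------------------------------------------------


def pseudomedian(d: np.ndarray) -> float:
    """One-sample Hodges-Lehmann estimate: median of Walsh averages
    (d_i + d_j)/2 over all i <= j."""
    d = np.asarray(d, dtype=float)
    n = len(d)
    if n == 0:
        return math.nan
    iu = np.triu_indices(n)
    return float(np.median((d[iu[0]] + d[iu[1]]) / 2.0))


def hl_shift(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample Hodges-Lehmann shift: median of all pairwise a_i - b_j."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        return math.nan
    return float(np.median(a[:, None] - b[None, :]))


def _exact_signed_rank_sf(ranks2: np.ndarray, w2: float) -> float:
    """P(W+ >= w2/2) under random signs, ranks given as doubled midranks.

    Convolution DP over the doubled (hence integral) midranks of the nonzero
    differences; exact under ties because the null is conditional on the
    observed rank multiset.
    """
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2i = int(math.ceil(w2 - 1e-9))
    if w2i <= 0:
        return 1.0
    return float(counts[w2i:].sum())


def signed_rank_p(d: np.ndarray, exact_n_max: int = EXACT_N_MAX) -> float:
    """One-sided (positive) signed-rank p-value of ``d`` against location 0.

    Pratt zero handling: zeros are included when ranking |d| and then
    excluded from the statistic and the null.  Midranks for ties.
    """
    d = np.asarray(d, dtype=float)
    if len(d) == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))  # midranks, zeros included
    nonzero = d != 0
    if not nonzero.any():
        return 1.0
    r = ranks[nonzero]
    w_plus = float(r[d[nonzero] > 0].sum())
    if nonzero.sum() <= exact_n_max:
        return _exact_signed_rank_sf(np.round(2 * r).astype(int), 2 * w_plus)
    mu = r.sum() / 2.0
    sigma = math.sqrt(float(np.square(r).sum()) / 4.0)
    if sigma == 0:
        return 1.0
    z = (w_plus - mu - 0.5) / sigma  # continuity correction toward the null
    return float(stats.norm.sf(z))


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p-value with midranks, tie-corrected variance, and
    continuity correction (normal approximation)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 1.0
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    ra = float(ranks[:n].sum())
    u = ra - n * (n + 1) / 2.0
    mu = n * m / 2.0
    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        return 1.0
    diff = u - mu
    z = (abs(diff) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def detection_score(p: float) -> float:
    """-10 log10(p), the TAS-style detection score (0 when p = 1)."""
    p = min(max(p, 1e-300), 1.0)
    return -10.0 * math.log10(p)


def signed_rank_signal(
    values: WindowValues,
    detect_on: str = "linear",
    exact_n_max: int = EXACT_N_MAX,
) -> tuple[float, float, float]:
    """Detection score, HL signal estimate s, and RNA level for one window.

    ``detect_on="linear"`` applies the signed-rank test to the paired
    d = PM - MM differences (the reading under which the ``s > 1 ->
    log2(s)`` floor rule is coherent); ``detect_on="log2"`` applies it to
    the nonnegative log2(max(d,1)) values instead.  The signal estimate s is
    the pseudomedian of d on the linear scale in both modes.
    """
    data = values.d if detect_on == "linear" else values.x
    p = signed_rank_p(data, exact_n_max=exact_n_max)
    s = pseudomedian(values.d)
    rna_level = math.log2(s) if s > 1 else 0.0
    return detection_score(p), s, rna_level


def rank_sum_differential(
    treat: WindowValues, ctrl: WindowValues
) -> tuple[float, float]:
    """Detection score and log2 fold change (HL shift of the log2 values)."""
    p = rank_sum_p(treat.x, ctrl.x)
    return detection_score(p), hl_shift(treat.x, ctrl.x)


# ---------------------------------------------------------------------------
# whole-genome track construction
# ---------------------------------------------------------------------------


def _fast_pseudomedian(d: np.ndarray) -> float:
    n = len(d)
    iu = np.triu_indices(n)
    return float(np.median((d[iu[0]] + d[iu[1]]) * 0.5))


def signal_track(
    probe_map: ProbeMap,
    intensities: IntensitySet,
    strain: str,
    spec: WindowSpec | None = None,
    detect_on: str = "linear",
    exact_n_max: int = EXACT_N_MAX,
) -> tuple[SignalTrack, SignalTrack]:
    """Per-probe RNA-level and signed-rank detection-score tracks for one
    strain (replicate arrays pooled per window)."""
    spec = spec or WindowSpec()
    labels = intensities.strain_labels(strain)
    idx = intensities.array_indices(labels)
    diffs = intensities.pm[idx] - intensities.mm[idx]  # arrays x probes
    lo, hi = _window_bounds(probe_map, spec)

    n = len(probe_map)
    levels = np.zeros(n)
    scores = np.zeros(n)
    log = np.log2
    for i in range(n):
        d = diffs[:, lo[i] : hi[i]].ravel()
        if not d.any():
            continue  # all-zero window: p = 1, s = 0, RNA level 0
        data = d if detect_on == "linear" else log(np.maximum(d, 1.0))
        p = signed_rank_p(data, exact_n_max=exact_n_max)
        s = _fast_pseudomedian(d)
        scores[i] = detection_score(p)
        if s > 1:
            levels[i] = log(s)
    level_track = SignalTrack(
        probe_map=probe_map,
        values=levels,
        kind="rna_level",
        window_bp=spec.width_bp,
        strain=strain,
    )
    score_track = SignalTrack(
        probe_map=probe_map,
        values=scores,
        kind="detection_score",
        window_bp=spec.width_bp,
        strain=strain,
    )
    return level_track, score_track


def differential_track(
    probe_map: ProbeMap,
    intensities: IntensitySet,
    strain: str,
    baseline: str,
    spec: WindowSpec | None = None,
) -> tuple[SignalTrack, SignalTrack]:
    """Per-probe log2-fold-change and rank-sum detection-score tracks for a
    mutant strain against its matched wild-type baseline."""
    spec = spec or WindowSpec()
    t_idx = intensities.array_indices(intensities.strain_labels(strain))
    c_idx = intensities.array_indices(intensities.strain_labels(baseline))
    xt = np.log2(np.maximum(intensities.pm[t_idx] - intensities.mm[t_idx], 1.0))
    xc = np.log2(np.maximum(intensities.pm[c_idx] - intensities.mm[c_idx], 1.0))
    lo, hi = _window_bounds(probe_map, spec)

    n = len(probe_map)
    fc = np.zeros(n)
    scores = np.zeros(n)
    for i in range(n):
        a = xt[:, lo[i] : hi[i]].ravel()
        b = xc[:, lo[i] : hi[i]].ravel()
        if not a.any() and not b.any():
            continue  # both groups all at the log floor: shift 0, p = 1
        scores[i] = detection_score(rank_sum_p(a, b))
        fc[i] = float(np.median(a[:, None] - b[None, :]))
    fc_track = SignalTrack(
        probe_map=probe_map,
        values=fc,
        kind="log2fc",
        window_bp=spec.width_bp,
        strain=strain,
        baseline=baseline,
    )
    score_track = SignalTrack(
        probe_map=probe_map,
        values=scores,
        kind="detection_score",
        window_bp=spec.width_bp,
        strain=strain,
        baseline=baseline,
    )
    return fc_track, score_track


def make_track(
    probe_map: ProbeMap,
    intensities: IntensitySet,
    spec: WindowSpec | None = None,
    mode: str = "rna_level",
    strain: str = "",
    baseline: str | None = None,
    detect_on: str = "linear",
) -> SignalTrack:
    """Build one whole-genome track (inputs are assumed normalized/scaled)."""
    if mode == "rna_level":
        track, _ = signal_track(probe_map, intensities, strain, spec, detect_on)
        return track
    if mode == "log2fc":
        if baseline is None:
            raise ValueError("log2fc mode requires a baseline strain")
        track, _ = differential_track(probe_map, intensities, strain, baseline, spec)
        return track
    raise ValueError(f"unknown mode {mode!r}")
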