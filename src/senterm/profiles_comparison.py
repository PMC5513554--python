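"""Metagene profiles, pairwise track correlation, and loop detection.

* Metagene: each gene is rescaled to percent distance along its ORF (100
  bins) plus ten 10-bp bins over the first 100 bp after the stop codon (a
  surrogate for the 3'-UTR).  Genes are averaged with equal weight (per-gene
  bin means first, then an unweighted mean across genes) so long genes do
  not dominate.
* Correlation: Pearson correlation of two tracks over every probe position
  where both are finite; with six mutants this yields the 15 unique pairs.
* Loop detection: a robust-z outlier scan over a pair of long-window
  (500-bp) differential tracks — probes where either axis exceeds the z
  threshold are merged into segments, reproducing the discrete "loops" that
  strongly affected transcription units trace in a pairwise scatter plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import FeatureSet, Interval, SignalTrack

N_ORF_BINS = 100
N_UTR_BINS = 10
UTR_BIN_BP = 10

__all__ = [
    "MetageneProfile",
    "LoopSegment",
    "metagene",
    "correlation_matrix",
    "correlation_groups",
    "detect_loops",
    "gene_level_change",
]


@dataclass
class MetageneProfile:
    """Mean signal per percent-distance ORF bin and per 10-bp 3'-UTR bin."""

    orf_bins: np.ndarray  # length 100
    utr_bins: np.ndarray  # length 10
    n_genes: int


@dataclass
class LoopSegment:
    interval: Interval
    mean_a: float
    mean_b: float
    peak_z: float
    feature_ids: list[str] = field(default_factory=list)


def _gene_bin_means(
    track: SignalTrack, chrom: str, start: int, end: int, strand: str
) -> tuple[np.ndarray, np.ndarray]:
    """(orf bin means, utr bin means) for one gene; NaN where no probe."""
    pm = track.probe_map
    sl = pm.chrom_slice(chrom)
    centers = pm.centers[sl]
    values = track.values[sl]
    length = end - start

    lo = int(np.searchsorted(centers, start, side="left"))
    hi = int(np.searchsorted(centers, end, side="left"))
    c = centers[lo:hi]
    v = values[lo:hi]
    if strand == "-":
        frac = (end - c - 0.5) / length
    else:
        frac = (c - start + 0.5) / length
    bins = np.clip((frac * N_ORF_BINS).astype(int), 0, N_ORF_BINS - 1)
    orf = np.full(N_ORF_BINS, np.nan)
    for b in range(N_ORF_BINS):
        sel = bins == b
        if sel.any() and np.isfinite(v[sel]).any():
            orf[b] = np.nanmean(v[sel])

    if strand == "-":
        u0, u1 = start - N_UTR_BINS * UTR_BIN_BP, start
    else:
        u0, u1 = end, end + N_UTR_BINS * UTR_BIN_BP
    lo = int(np.searchsorted(centers, u0, side="left"))
    hi = int(np.searchsorted(centers, u1, side="left"))
    c = centers[lo:hi]
    v = values[lo:hi]
    ub = ((c - u0) // UTR_BIN_BP if strand != "-" else (u1 - 1 - c) // UTR_BIN_BP)
    ub = np.clip(ub.astype(int), 0, N_UTR_BINS - 1)
    utr = np.full(N_UTR_BINS, np.nan)
    for b in range(N_UTR_BINS):
        sel = ub == b
        if sel.any() and np.isfinite(v[sel]).any():
            utr[b] = np.nanmean(v[sel])
    return orf, utr


def metagene(genes: FeatureSet, track: SignalTrack) -> MetageneProfile:
    """Equal-weight metagene profile of a track over a set of ORFs."""
    orf_rows, utr_rows = [], []
    n_genes = 0
    for gene in genes:
        iv = gene.interval
        if iv.strand not in ("+", "-"):
            raise ValueError(f"metagene requires stranded genes ({gene.id})")
        orf, utr = _gene_bin_means(track, iv.chrom, iv.start, iv.end, iv.strand)
        if np.isfinite(orf).any() or np.isfinite(utr).any():
            orf_rows.append(orf)
            utr_rows.append(utr)
            n_genes += 1
    if n_genes == 0:
        raise ValueError("no gene contributed any probe to the metagene")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins stay NaN
        orf_bins = np.nanmean(np.vstack(orf_rows), axis=0)
        utr_bins = np.nanmean(np.vstack(utr_rows), axis=0)
    return MetageneProfile(orf_bins=orf_bins, utr_bins=utr_bins, n_genes=n_genes)


def correlation_matrix(tracks: list[SignalTrack]) -> pd.DataFrame:
    """All-pairs Pearson correlation of tracks sharing one probe map.

    Masked or missing positions are dropped pairwise; an entry is NaN when
    fewer than two shared finite positions remain.
    """
    n = len(tracks)
    base = tracks[0].probe_map
    for t in tracks[1:]:
        if t.probe_map is not base and len(t.probe_map) != len(base):
            raise ValueError("tracks must share a probe map")
    labels = [t.strain for t in tracks]
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = tracks[i].values, tracks[j].values
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 2 or np.std(a[ok]) == 0 or np.std(b[ok]) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(a[ok], b[ok])[0, 1])
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=labels, columns=labels)


def correlation_groups(
    matrix: pd.DataFrame, edges: tuple[float, ...] = (0.55, 0.45, 0.30, 0.20, 0.10)
) -> pd.DataFrame:
    """Rank the unique pairs by coefficient and band them into groups
    (group 1 = highest band), mirroring a grouped pairwise-similarity report."""
    rows = []
    labels = list(matrix.index)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            r = matrix.iloc[i, j]
            group = 1 + int(np.searchsorted(-np.asarray(edges), -r, side="right"))
            rows.append({"a": labels[i], "b": labels[j], "r": r, "group": group})
    return (
        pd.DataFrame(rows)
        .sort_values("r", ascending=False, kind="stable")
        .reset_index(drop=True)
    )


def _robust_z(values: np.ndarray, min_scale: float = 0.0) -> np.ndarray:
    finite = values[np.isfinite(values)]
    med = np.median(finite)
    mad = np.median(np.abs(finite - med))
    if mad == 0:
        warnings.warn("MAD is zero; falling back to standard deviation")
        scale = float(np.std(finite))
        if scale == 0:
            return np.zeros_like(values)
    else:
        scale = 1.4826 * mad
    return (values - med) / max(scale, min_scale)


def detect_loops(
    track_a: SignalTrack,
    track_b: SignalTrack,
    z_threshold: float = 4.0,
    merge_gap: int = 250,
    min_span: int = 300,
    features: FeatureSet | None = None,
    min_scale: float = 0.05,
) -> list[LoopSegment]:
    """Robust-z outlier segments over a pair of long-window log2fc tracks.

    A probe is flagged when max(|zA|, |zB|) >= z_threshold; flagged probes on
    one chromosome are merged when separated by <= merge_gap bp, and merged
    runs spanning >= min_span bp are reported (disjoint, sorted), annotated
    with overlapping features.  ``min_scale`` floors the robust scale (in
    log2 units) so that near-noiseless tracks, whose MAD reflects only
    numerical jitter, do not flag biologically negligible excursions.
    """
    pm = track_a.probe_map
    za = _robust_z(track_a.values, min_scale)
    zb = _robust_z(track_b.values, min_scale)
    with np.errstate(invalid="ignore"):
        peak = np.fmax(np.abs(za), np.abs(zb))
        flagged = peak >= z_threshold
    flagged &= np.isfinite(peak)

    segments: list[LoopSegment] = []
    idx = np.flatnonzero(flagged)
    if len(idx) == 0:
        return segments
    runs: list[list[int]] = [[idx[0]]]
    for i in idx[1:]:
        prev = runs[-1][-1]
        if pm.chroms[i] == pm.chroms[prev] and pm.centers[i] - pm.centers[prev] <= merge_gap:
            runs[-1].append(i)
        else:
            runs.append([i])
    for run in runs:
        start = int(pm.centers[run[0]])
        end = int(pm.centers[run[-1]]) + 1
        if end - start < min_span:
            continue
        chrom = str(pm.chroms[run[0]])
        iv = Interval(chrom, start, end, ".")
        ids = (
            [f.id for f in features.overlapping(chrom, start, end)] if features else []
        )
        segments.append(
            LoopSegment(
                interval=iv,
                mean_a=float(np.nanmean(track_a.values[run])),
                mean_b=float(np.nanmean(track_b.values[run])),
                peak_z=float(np.nanmax(peak[run])),
                feature_ids=ids,
            )
        )
    return segments


def gene_level_change(genes: FeatureSet, track: SignalTrack) -> pd.DataFrame:
    """Per-gene mean log2 fold change over the ORF and the untransformed fold.

    Genes without any probe (or with only masked probes) get NaN.
    """
    pm = track.probe_map
    rows = []
    for gene in genes.of_kind("orf"):
        iv = gene.interval
        sl = pm.chrom_slice(iv.chrom)
        centers = pm.centers[sl]
        lo = int(np.searchsorted(centers, iv.start, side="left"))
        hi = int(np.searchsorted(centers, iv.end, side="left"))
        v = track.values[sl][lo:hi]
        v = v[np.isfinite(v)]
        mean = float(np.mean(v)) if len(v) else np.nan
        rows.append(
            {
                "gene_id": gene.id,
                "strain": track.strain,
                "mean_log2fc": mean,
                "fold": 2.0 ** mean if np.isfinite(mean) else np.nan,
                "n_probes": len(v),
            }
        )
    return pd.DataFrame(rows)
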