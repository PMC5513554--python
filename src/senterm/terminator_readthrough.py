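"""Differential terminator-readthrough ratios for sn/snoRNA genes.

For each sn/snoRNA gene the readthrough ratio is the average linear
transcript level in a 50-bp window placed 10 to 310 bp downstream of the
mature coding region, divided by the average level over the mature coding
region itself, times 100%.  The differential readthrough ratio subtracts the
matched wild-type value; differentials below 10% are treated as
insignificant (not detectable by orthogonal blotting), values above 100% are
flagged as likely confounded by unannotated overlapping transcripts, and
genes with annotated transcription units close downstream of their 3' ends
are excluded outright.

Signals come from RNA-level tracks and are converted back to the linear
scale (2**level where the level is positive, else 0), since the ratio is a
statement about transcript abundance, not its logarithm.  All window
arithmetic is strand-aware: "downstream" means 3' of the mature end on the
annotated strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Feature, FeatureSet, SignalTrack

DOWNSTREAM_OFFSET = 10  # bp past the mature 3' end where the scan region starts
DOWNSTREAM_SPAN = 300  # scan region length: +10 .. +310
SUBWINDOW = 50  # width of the downstream averaging window
INSIGNIFICANT_BELOW = 10.0  # percent
CONFOUNDED_ABOVE = 100.0  # percent
DEFAULT_WINDOW_RULE = "mean_region"

__all__ = [
    "ReadthroughRecord",
    "readthrough_ratio",
    "differential_readthrough",
    "flag_confounded_genes",
    "readthrough_table",
    "count_defective",
]


@dataclass
class ReadthroughRecord:
    """Per-gene, per-strain readthrough quantification and classification."""

    gene_id: str
    strain: str
    body_mean: float
    downstream_mean: float
    ratio: float  # percent, this strain
    wt_ratio: float  # percent, matched wild-type
    differential: float  # percent, ratio - wt_ratio
    classification: str  # none | readthrough | confounded | excluded | undefined
    notes: list[str] = field(default_factory=list)


def _linear(values: np.ndarray) -> np.ndarray:
    """RNA-level track values back to linear abundance (floor rule inverse)."""
    out = np.where(values > 0, 2.0 ** values, 0.0)
    out[~np.isfinite(values)] = np.nan
    return out


def _gene_regions(gene: Feature) -> tuple[tuple[int, int], tuple[int, int]]:
    """(body, downstream-scan) half-open genomic intervals, strand-aware."""
    if gene.mature_end is None:
        raise ValueError(f"gene {gene.id} has no mature_end")
    iv = gene.interval
    me = gene.mature_end
    if iv.strand == "+":
        body = (iv.start, me)
        down = (me + DOWNSTREAM_OFFSET, me + DOWNSTREAM_OFFSET + DOWNSTREAM_SPAN)
    elif iv.strand == "-":
        body = (me, iv.end)
        down = (me - DOWNSTREAM_OFFSET - DOWNSTREAM_SPAN, me - DOWNSTREAM_OFFSET)
    else:
        raise ValueError(f"gene {gene.id} requires explicit strand")
    return body, down


def _region_values(
    track: SignalTrack, chrom: str, start: int, end: int
) -> tuple[np.ndarray, np.ndarray]:
    pm = track.probe_map
    sl = pm.chrom_slice(chrom)
    centers = pm.centers[sl]
    lo = int(np.searchsorted(centers, start, side="left"))
    hi = int(np.searchsorted(centers, end, side="left"))
    return centers[lo:hi], _linear(track.values[sl][lo:hi])


def readthrough_ratio(
    gene: Feature,
    track: SignalTrack,
    window_rule: str = DEFAULT_WINDOW_RULE,
) -> tuple[float, float, float]:
    """Readthrough ratio (percent) of one gene on one strain's RNA-level track.

    Returns (ratio, body_mean, downstream_mean); the ratio is NaN when the
    body mean is zero (recorded downstream as 'undefined', never raised).

    ``window_rule="max50"`` takes the maximum mean over all 50-bp sub-windows
    fully inside the +10..+310 scan region, stepped at probe spacing;
    ``"mean_region"`` (default) averages the whole scan region.
    """
    if gene.kind != "snr":
        raise ValueError(f"readthrough_ratio expects an snr gene, got {gene.kind!r}")
    if track.kind != "rna_level":
        raise ValueError("readthrough_ratio expects an RNA-level track")
    chrom = gene.interval.chrom
    (b0, b1), (d0, d1) = _gene_regions(gene)
    _, body_vals = _region_values(track, chrom, b0, b1)
    centers, down_vals = _region_values(track, chrom, d0, d1)
    body_mean = float(np.nanmean(body_vals)) if len(body_vals) else math.nan

    if len(down_vals) == 0:
        downstream_mean = math.nan
    elif window_rule == "mean_region":
        downstream_mean = float(np.nanmean(down_vals))
    elif window_rule == "max50":
        step = track.probe_map.spacing_hint
        best = -math.inf
        for s in range(d0, d1 - SUBWINDOW + 1, step):
            sel = (centers >= s) & (centers < s + SUBWINDOW)
            if sel.any():
                best = max(best, float(np.nanmean(down_vals[sel])))
        downstream_mean = best if best > -math.inf else math.nan
    else:
        raise ValueError(f"unknown window_rule {window_rule!r}")

    if not (body_mean > 0) or not np.isfinite(downstream_mean):
        return math.nan, body_mean, downstream_mean
    return 100.0 * downstream_mean / body_mean, body_mean, downstream_mean


def differential_readthrough(
    gene: Feature,
    mutant_track: SignalTrack,
    wt_track: SignalTrack,
    window_rule: str = DEFAULT_WINDOW_RULE,
) -> ReadthroughRecord:
    """Differential readthrough ratio and classification for one gene.

    Classification: 'none' below 10 points, 'readthrough' from 10 to 100,
    'confounded' above 100 (likely overlapping unannotated transcripts),
    'undefined' when either strain's ratio is undefined.  A 'body-decrease'
    note marks defects driven by diminished mature RNA rather than elevated
    downstream signal (mutant body mean below half of wild-type).
    """
    ratio_m, body_m, down_m = readthrough_ratio(gene, mutant_track, window_rule)
    ratio_w, body_w, _ = readthrough_ratio(gene, wt_track, window_rule)
    notes: list[str] = []
    if not np.isfinite(ratio_m) or not np.isfinite(ratio_w):
        diff = math.nan
        cls = "undefined"
    else:
        diff = ratio_m - ratio_w
        if diff > CONFOUNDED_ABOVE:
            cls = "confounded"
        elif diff >= INSIGNIFICANT_BELOW:
            cls = "readthrough"
        else:
            cls = "none"
        if np.isfinite(body_m) and np.isfinite(body_w) and body_m < 0.5 * body_w:
            notes.append("body-decrease")
    return ReadthroughRecord(
        gene_id=gene.id,
        strain=mutant_track.strain,
        body_mean=body_m,
        downstream_mean=down_m,
        ratio=ratio_m,
        wt_ratio=ratio_w,
        differential=diff,
        classification=cls,
        notes=notes,
    )


def flag_confounded_genes(
    genes: FeatureSet,
    all_features: FeatureSet,
    slack: int = DOWNSTREAM_OFFSET + DOWNSTREAM_SPAN,
    include: set[str] | None = None,
    exclude: set[str] | None = None,
) -> dict[str, bool]:
    """Per-gene exclusion flags for sn/snoRNA genes with adjacent or
    overlapping transcription units at their 3' ends.

    A gene is excluded when any transcription-unit feature (any kind except
    mask and polyA_cluster, on either strand, other than the gene itself)
    overlaps the ``[mature_end, mature_end + slack)`` downstream region.
    ``include``/``exclude`` id sets override the automatic call.
    """
    flags: dict[str, bool] = {}
    for gene in genes.of_kind("snr"):
        if gene.mature_end is None:
            flags[gene.id] = True
            continue
        me = gene.mature_end
        if gene.strand == "+":
            lo, hi = me, me + slack
        else:
            lo, hi = me - slack, me
        hits = [
            f
            for f in all_features.overlapping(gene.interval.chrom, lo, hi)
            if f.id != gene.id and f.kind not in ("mask", "polyA_cluster")
        ]
        flags[gene.id] = bool(hits)
    for gid in include or ():
        flags[gid] = False
    for gid in exclude or ():
        flags[gid] = True
    return flags


def readthrough_table(
    genes: FeatureSet,
    tracks: dict[str, SignalTrack],
    wt_label: str,
    window_rule: str = DEFAULT_WINDOW_RULE,
    all_features: FeatureSet | None = None,
) -> pd.DataFrame:
    """Long-format table of one ReadthroughRecord per (retained gene, mutant).

    ``tracks`` maps strain label -> RNA-level track (the wild-type label
    must be present).  Genes flagged as confounded by adjacent transcription
    units are reported with classification 'excluded' and no ratios.
    Use :func:`to_wide` for the genes-by-strains supplementary-table layout.
    """
    if wt_label not in tracks:
        raise ValueError(f"wild-type track {wt_label!r} missing")
    snr_genes = genes.of_kind("snr")
    excluded = flag_confounded_genes(snr_genes, all_features or genes)
    wt_track = tracks[wt_label]
    rows = []
    for gene in snr_genes:
        for strain, track in tracks.items():
            if strain == wt_label:
                continue
            if excluded.get(gene.id, False):
                rows.append(
                    {
                        "gene_id": gene.id,
                        "strain": strain,
                        "body_mean": math.nan,
                        "downstream_mean": math.nan,
                        "ratio": math.nan,
                        "wt_ratio": math.nan,
                        "differential": math.nan,
                        "classification": "excluded",
                        "notes": "",
                    }
                )
                continue
            rec = differential_readthrough(gene, track, wt_track, window_rule)
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "strain": rec.strain,
                    "body_mean": rec.body_mean,
                    "downstream_mean": rec.downstream_mean,
                    "ratio": rec.ratio,
                    "wt_ratio": rec.wt_ratio,
                    "differential": rec.differential,
                    "classification": rec.classification,
                    "notes": ";".join(rec.notes),
                }
            )
    columns = [
        "gene_id", "strain", "body_mean", "downstream_mean", "ratio",
        "wt_ratio", "differential", "classification", "notes",
    ]
    return pd.DataFrame(rows, columns=columns)


def to_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Genes-by-strains matrix of differential readthrough ratios (percent)."""
    return table.pivot(index="gene_id", columns="strain", values="differential")


def count_defective(table: pd.DataFrame, threshold: float = INSIGNIFICANT_BELOW) -> pd.Series:
    """Per-strain count of genes whose differential ratio exceeds the
    significance threshold (the supplementary-table bold-count rule)."""
    ok = table[table["classification"] != "excluded"]
    return (
        ok.assign(defective=ok["differential"] > threshold)
        .groupby("strain")["defective"]
        .sum()
        .astype(int)
    )
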