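"""Rule-based screens for attenuated genes and upstream-biased derepression.

The attenuation screen encodes, as a transparent conjunction of named
boolean features, the sequence and expression properties shared by genes
regulated through upstream Sen1-dependent termination:

* transcript level up at least ``min_fold`` in at least one mutant strain;
* no ATG trinucleotide on the nontemplate strand between the transcription
  start site (or a fixed scan distance upstream of the start codon) and the
  start codon — the hallmark of a long scanned 5'-UTR;
* terminator specificity elements in the 5'-UTR: Nab3 (UCUU) and/or Nrd1
  (GUAA/G) consensus sites, scanned on the transcript strand in IUPAC code;
* a cluster of poly(A) 3'-ends at the upstream end of the ORF, the footprint
  of termination-coupled polyadenylation of the attenuated transcript;
* a TATA box 200-400 bp upstream of the start codon.

The mode hint distinguishes single-TATA/single-start (ST-SS) genes from
dual-TATA/dual-start (DT-DS) genes driven by an independent annotated
upstream transcript, with single-TATA/dual-start (ST-DS) as the remainder.

The upstream-bias screen splits each ORF at its midpoint in transcription
direction and flags genes whose differential signal is concentrated in the
upstream half — the signature of a derepressed upstream (e.g. meiotic)
transcription start site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .genome_io import Feature, FeatureSet, SignalTrack
from .profiles_comparison import gene_level_change

__all__ = [
    "ScreenParams",
    "AttenuatorReport",
    "BiasRecord",
    "screen_attenuators",
    "upstream_bias",
    "threshold_gene_list",
    "iupac_to_regex",
    "revcomp",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[GC]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC DNA/RNA consensus (U treated as T) to a regex."""
    try:
        return re.compile("".join(_IUPAC[c] for c in motif.upper()))
    except KeyError as exc:
        raise ValueError(f"invalid IUPAC code in motif {motif!r}: {exc}") from exc


@dataclass(frozen=True)
class ScreenParams:
    """Tunable criteria of the attenuation screen (all in bp or fold units)."""

    min_fold: float = 2.0  # required in at least one strain
    utr_scan_bp: int = 350  # scan length upstream of the start codon (no TSS given)
    nab3_motif: str = "UCUU"
    nrd1_motif: str = "GUAR"  # GUA[AG]
    tata_motif: str = "TATAWAWR"  # TATA[AT]A[AT][AG]
    tata_window: tuple[int, int] = (200, 400)  # bp upstream of the start codon


@dataclass
class AttenuatorReport:
    gene_id: str
    fold_by_strain: Mapping[str, float]
    utr_interval: tuple[str, int, int]
    atg_free: bool
    tata_hits: list[int]
    nab3_sites: list[int]
    nrd1_sites: list[int]
    polyA_cluster_present: bool
    mode_hint: str  # ST-SS | ST-DS | DT-DS | none
    passed: bool


@dataclass
class BiasRecord:
    gene_id: str
    up_mean: float
    down_mean: float
    bias: float
    flagged: bool


def _transcript_strand_seq(sequence: Mapping[str, str], chrom: str, start: int, end: int, strand: str) -> str:
    """Nontemplate-strand (mRNA-sense) sequence of [start, end), 5'->3'."""
    if chrom not in sequence:
        raise KeyError(f"no sequence for chromosome {chrom!r}")
    seq = sequence[chrom][max(0, start):end].upper()
    return revcomp(seq) if strand == "-" else seq


def _utr_region(gene: Feature, params: ScreenParams) -> tuple[int, int]:
    """Genomic [start, end) of the 5'-UTR scan region, strand-aware.

    An annotated TSS (``tss`` attribute, genomic coordinate) anchors the
    region; otherwise a fixed ``utr_scan_bp`` distance upstream of the start
    codon is used.
    """
    iv = gene.interval
    tss = gene.attributes.get("tss")
    if iv.strand == "-":
        hi = iv.end + params.utr_scan_bp if tss is None else int(tss) + 1
        return iv.end, hi
    lo = iv.start - params.utr_scan_bp if tss is None else int(tss)
    return max(0, lo), iv.start


def screen_attenuators(
    genes: FeatureSet,
    tracks: Mapping[str, SignalTrack],
    sequence: Mapping[str, str],
    polyA: FeatureSet,
    params: ScreenParams | None = None,
) -> list[AttenuatorReport]:
    """Screen ORFs for the attenuated-gene signature.

    ``tracks`` maps mutant strain -> log2fc track.  A gene passes when it
    clears the fold filter AND its scan region is ATG-free AND it carries
    either a specificity motif or an upstream poly(A) cluster.  The report
    exposes every individual criterion so users can re-weight them.
    """
    params = params or ScreenParams()
    nab3_re = iupac_to_regex(params.nab3_motif)
    nrd1_re = iupac_to_regex(params.nrd1_motif)
    tata_re = iupac_to_regex(params.tata_motif)

    folds: dict[str, pd.Series] = {}
    for strain, track in tracks.items():
        tbl = gene_level_change(genes, track)
        folds[strain] = tbl.set_index("gene_id")["fold"]

    reports: list[AttenuatorReport] = []
    for gene in genes.of_kind("orf"):
        iv = gene.interval
        fold_by_strain = {s: float(folds[s].get(gene.id, np.nan)) for s in tracks}
        fold_ok = any(f >= params.min_fold for f in fold_by_strain.values() if np.isfinite(f))

        u0, u1 = _utr_region(gene, params)
        utr_seq = _transcript_strand_seq(sequence, iv.chrom, u0, u1, iv.strand)
        atg_free = "ATG" not in utr_seq
        nab3_sites = [m.start() for m in nab3_re.finditer(utr_seq)]
        nrd1_sites = [m.start() for m in nrd1_re.finditer(utr_seq)]

        # TATA scan window, measured upstream from the start codon
        w0, w1 = params.tata_window
        if iv.strand == "-":
            t_lo, t_hi = iv.end + w0, iv.end + w1
        else:
            t_lo, t_hi = max(0, iv.start - w1), max(0, iv.start - w0)
        tata_seq = _transcript_strand_seq(sequence, iv.chrom, t_lo, t_hi, iv.strand)
        tata_hits = [m.start() for m in tata_re.finditer(tata_seq)]

        # poly(A) cluster at the upstream end of the ORF or in the UTR region
        orf_head = (
            (iv.start, min(iv.start + 100, iv.end))
            if iv.strand != "-"
            else (max(iv.start, iv.end - 100), iv.end)
        )
        polyA_present = bool(
            polyA.of_kind("polyA_cluster").overlapping(iv.chrom, u0, u1)
            or polyA.of_kind("polyA_cluster").overlapping(iv.chrom, *orf_head)
        )

        # independent upstream transcription unit (annotated CUT) in the UTR
        upstream_tu = [
            f
            for f in genes.overlapping(iv.chrom, u0, u1)
            if f.kind == "cut" and f.id != gene.id
        ]

        passed = bool(fold_ok and atg_free and (nab3_sites or nrd1_sites or polyA_present))
        if not passed:
            mode = "none"
        elif upstream_tu:
            mode = "DT-DS"
        elif len(tata_hits) == 1 and polyA_present:
            mode = "ST-SS"
        else:
            mode = "ST-DS"
        reports.append(
            AttenuatorReport(
                gene_id=gene.id,
                fold_by_strain=fold_by_strain,
                utr_interval=(iv.chrom, u0, u1),
                atg_free=atg_free,
                tata_hits=tata_hits,
                nab3_sites=nab3_sites,
                nrd1_sites=nrd1_sites,
                polyA_cluster_present=polyA_present,
                mode_hint=mode,
                passed=passed,
            )
        )
    return reports


def reports_to_frame(reports: list[AttenuatorReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        row = {
            "gene_id": r.gene_id,
            "atg_free": r.atg_free,
            "n_tata": len(r.tata_hits),
            "n_nab3": len(r.nab3_sites),
            "n_nrd1": len(r.nrd1_sites),
            "polyA_cluster": r.polyA_cluster_present,
            "mode_hint": r.mode_hint,
            "passed": r.passed,
        }
        for strain, f in r.fold_by_strain.items():
            row[f"fold_{strain}"] = f
        rows.append(row)
    return pd.DataFrame(rows)


def upstream_bias(
    genes: FeatureSet,
    track: SignalTrack,
    min_up: float = 1.0,
    min_bias: float = 0.5,
) -> list[BiasRecord]:
    """Mean log2fc over the upstream vs downstream half of each ORF.

    Flagged when the upstream-half mean reaches ``min_up`` and exceeds the
    downstream-half mean by at least ``min_bias`` — upstream-biased
    derepression in transcription direction.
    """
    pm = track.probe_map
    records = []
    for gene in genes.of_kind("orf"):
        iv = gene.interval
        mid = (iv.start + iv.end) // 2
        sl = pm.chrom_slice(iv.chrom)
        centers = pm.centers[sl]
        lo = int(np.searchsorted(centers, iv.start, side="left"))
        m = int(np.searchsorted(centers, mid, side="left"))
        hi = int(np.searchsorted(centers, iv.end, side="left"))
        left = track.values[sl][lo:m]
        right = track.values[sl][m:hi]
        if iv.strand == "-":
            left, right = right, left
        up = float(np.nanmean(left)) if np.isfinite(left).any() else np.nan
        down = float(np.nanmean(right)) if np.isfinite(right).any() else np.nan
        bias = up - down
        flagged = bool(np.isfinite(bias) and up >= min_up and bias >= min_bias)
        records.append(BiasRecord(gene.id, up, down, bias, flagged))
    return records


def threshold_gene_list(
    gene_changes: pd.DataFrame, strain: str, min_fold: float = 2.0
) -> list[str]:
    """Gene ids with untransformed fold >= min_fold in one strain, sorted by
    fold descending ('at least' is inclusive at the boundary).

    ``gene_changes`` is gene_level_change output, possibly concatenated over
    strains (columns gene_id, strain, fold).
    """
    if strain not in set(gene_changes["strain"]):
        raise KeyError(f"unknown strain {strain!r}")
    sub = gene_changes[gene_changes["strain"] == strain]
    sub = sub[np.isfinite(sub["fold"]) & (sub["fold"] >= min_fold)]
    return list(sub.sort_values("fold", ascending=False, kind="stable")["gene_id"])
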