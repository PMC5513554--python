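"""Data model and I/O for genomes, features, probes, intensities, and tracks.

Internal coordinates are 0-based half-open throughout.  The 1-based inclusive
convention of GFF3/SGD and the 0-based half-open convention of BED/bedGraph
appear only at the I/O boundary.  Probe positions are single genomic
coordinates (probe centers); probe length is not modeled, because every
downstream statistic is computed per interrogated genomic position.

All readers and writers are gzip-transparent (a ``.gz`` suffix switches to
gzip mode).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("orf", "snr", "cut", "polyA_cluster", "mask", "other")

#: GFF3 type column -> internal feature kind.
DEFAULT_KIND_MAP = {
    "gene": "orf",
    "orf": "orf",
    "cds": "orf",
    "mrna": "orf",
    "snorna": "snr",
    "snrna": "snr",
    "snr": "snr",
    "ncrna": "snr",
    "cut": "cut",
    "polya_cluster": "polyA_cluster",
    "polya_site": "polyA_cluster",
    "mask": "mask",
    "region": "mask",
}


class ParseError(ValueError):
    """Raised when an annotation or table file fails to parse; names the line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        start, end = self.start, self.end
        if start > end:
            # The source literature itself prints at least one high->low range
            # (a plasmid-mask span), so reversed bounds are normalized rather
            # than rejected.
            logger.warning(
                "interval bounds reversed (%s:%d-%d); normalizing", self.chrom, start, end
            )
            object.__setattr__(self, "start", end)
            object.__setattr__(self, "end", start)
            start, end = end, start
        if start < 0:
            raise ValueError(f"negative start: {start}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Feature:
    """A typed genomic feature (ORF, sn/snoRNA gene, CUT, poly(A) cluster, mask).

    ``mature_end`` is the genomic coordinate of the mature 3' end of a
    sn/snoRNA (the boundary between the mature-coding region and the
    terminator-readthrough region), strand-aware: for a ``+`` gene the mature
    region is ``[start, mature_end)``; for a ``-`` gene it is
    ``[mature_end, end)``.
    """

    id: str
    kind: str
    interval: Interval
    mature_end: int | None = None
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "snr" and self.interval.strand not in ("+", "-"):
            raise ValueError(f"snr feature {self.id} requires explicit strand")
        if self.mature_end is not None and not (
            self.interval.start <= self.mature_end <= self.interval.end
        ):
            raise ValueError(
                f"mature_end {self.mature_end} outside {self.interval} for {self.id}"
            )

    @property
    def strand(self) -> str:
        return self.interval.strand


class FeatureSet:
    """An ordered collection of features with overlap queries."""

    def __init__(self, features: Iterable[Feature] = ()):
        self.features: list[Feature] = list(features)
        ids = [f.id for f in self.features]
        if len(set(ids)) != len(ids):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise ValueError(f"duplicate feature id: {dup}")
        self._by_id = {f.id: f for f in self.features}
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __getitem__(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def of_kind(self, *kinds: str) -> "FeatureSet":
        return FeatureSet(f for f in self.features if f.kind in kinds)

    def _tree(self, chrom: str) -> IntervalTree:
        if self._trees is None:
            self._trees = {}
            for f in self.features:
                t = self._trees.setdefault(f.interval.chrom, IntervalTree())
                if len(f.interval) > 0:
                    t.addi(f.interval.start, f.interval.end, f)
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, chrom: str, start: int, end: int) -> list[Feature]:
        """Features overlapping [start, end) on either strand, in input order."""
        if end <= start:
            return []
        hits = {iv.data.id for iv in self._tree(chrom).overlap(start, end)}
        return [f for f in self.features if f.id in hits]


@dataclass(frozen=True)
class ProbeMap:
    """Tiled probe layout: one genomic center coordinate per PM/MM probe pair."""

    probe_ids: np.ndarray  # str array
    chroms: np.ndarray  # str array
    centers: np.ndarray  # int array
    spacing_hint: int = 5

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        if not (len(self.chroms) == len(self.centers) == n):
            raise ValueError("probe map columns must have equal length")
        if len(set(self.probe_ids.tolist())) != n:
            raise ValueError("probe ids must be unique")
        order = np.lexsort((self.centers, self.chroms))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("probes must be sorted by (chrom, center)")

    def __len__(self) -> int:
        return len(self.probe_ids)

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str, int]], spacing_hint: int = 5
    ) -> "ProbeMap":
        recs = sorted(records, key=lambda r: (r[1], r[2]))
        return cls(
            probe_ids=np.array([r[0] for r in recs], dtype=object),
            chroms=np.array([r[1] for r in recs], dtype=object),
            centers=np.array([r[2] for r in recs], dtype=np.int64),
            spacing_hint=spacing_hint,
        )

    def chrom_slice(self, chrom: str) -> slice:
        """Index range of this chromosome's probes (probes are chrom-sorted)."""
        lo = int(np.searchsorted(self.chroms, chrom, side="left"))
        hi = int(np.searchsorted(self.chroms, chrom, side="right"))
        return slice(lo, hi)

    def index_of(self, probe_id: str) -> int:
        if not hasattr(self, "_index"):
            object.__setattr__(
                self, "_index", {p: i for i, p in enumerate(self.probe_ids)}
            )
        return self._index[probe_id]


@dataclass(frozen=True)
class ArrayInfo:
    """Label and design metadata for one array (one hybridization)."""

    label: str
    strain: str
    replicate: int


@dataclass
class IntensitySet:
    """PM/MM intensity matrices (arrays x probes) aligned to a probe map."""

    probe_map: ProbeMap
    arrays: list[ArrayInfo]
    pm: np.ndarray
    mm: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.arrays), len(self.probe_map))
        if self.pm.shape != shape or self.mm.shape != shape:
            raise ValueError(
                f"intensity matrices must have shape {shape}, got "
                f"pm {self.pm.shape}, mm {self.mm.shape}"
            )
        if np.any(self.pm < 0) or np.any(self.mm < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def labels(self) -> list[str]:
        return [a.label for a in self.arrays]

    def array_indices(self, labels: Sequence[str]) -> list[int]:
        lookup = {a.label: i for i, a in enumerate(self.arrays)}
        missing = [l for l in labels if l not in lookup]
        if missing:
            raise KeyError(f"unknown array labels: {missing}")
        return [lookup[l] for l in labels]

    def strain_labels(self, strain: str) -> list[str]:
        out = [a.label for a in self.arrays if a.strain == strain]
        if not out:
            raise KeyError(f"no arrays for strain {strain!r}")
        return out

    def copy(self) -> "IntensitySet":
        return IntensitySet(
            self.probe_map, list(self.arrays), self.pm.copy(), self.mm.copy()
        )


TRACK_KINDS = ("rna_level", "log2fc", "detection_score")


@dataclass
class SignalTrack:
    """Per-probe-position genome-indexed values (NaN marks missing)."""

    probe_map: ProbeMap
    values: np.ndarray
    kind: str
    window_bp: int
    strain: str
    baseline: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")
        if len(self.values) != len(self.probe_map):
            raise ValueError("values length must equal probe count")
        if self.window_bp < 1 or self.window_bp % 2 == 0:
            raise ValueError("window_bp must be odd and positive")
        if self.kind == "log2fc" and self.baseline is None:
            raise ValueError("log2fc track requires a baseline strain")
        self.values = np.asarray(self.values, dtype=float)

    def copy(self) -> "SignalTrack":
        return replace(self, values=self.values.copy())


# ---------------------------------------------------------------------------
# gzip-transparent open
# ---------------------------------------------------------------------------


def xopen(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# feature I/O
# ---------------------------------------------------------------------------


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_features(
    path: str | Path,
    format: str = "gff3",
    kind_map: Mapping[str, str] | None = None,
) -> FeatureSet:
    """Read a GFF3 or BED6 annotation file into a FeatureSet.

    GFF3 coordinates (1-based inclusive) and BED coordinates (0-based
    half-open) are both normalized to the internal 0-based half-open
    convention.  The feature kind comes from the GFF3 type column (or the BED
    name prefix ``kind:``) through ``kind_map``; unmapped types become
    ``other``.  A ``mature_end`` GFF3 attribute (1-based, inclusive position
    of the mature 3' nucleotide) is converted to the internal boundary
    coordinate.
    """
    kind_map = dict(DEFAULT_KIND_MAP, **(kind_map or {}))
    feats: list[Feature] = []
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            cols = line.split("\t")
            try:
                if format == "gff3":
                    feats.append(_gff3_feature(cols, kind_map))
                elif format == "bed":
                    feats.append(_bed_feature(cols, kind_map, lineno))
                else:
                    raise ValueError(f"unknown format {format!r}")
            except ParseError:
                raise
            except (ValueError, IndexError, KeyError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return FeatureSet(feats)


def _gff3_feature(cols: Sequence[str], kind_map: Mapping[str, str]) -> Feature:
    if len(cols) < 9:
        raise ValueError(f"expected 9 GFF3 columns, got {len(cols)}")
    chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
    attributes = _parse_gff3_attributes(attrs)
    fid = attributes.pop("ID", None) or attributes.get("Name")
    if fid is None:
        raise ValueError("missing ID attribute")
    kind = attributes.pop("kind", None) or kind_map.get(ftype.lower(), "other")
    start0 = int(start) - 1  # GFF3 is 1-based inclusive
    end0 = int(end)
    mature_raw = attributes.pop("mature_end", None)
    mature_end = None
    if mature_raw is not None:
        # 1-based inclusive mature 3' nucleotide -> half-open boundary:
        # + strand: boundary after the base; - strand: boundary before it.
        pos = int(mature_raw)
        mature_end = pos if strand == "+" else pos - 1
    return Feature(
        id=fid,
        kind=kind,
        interval=Interval(chrom, start0, end0, strand if strand in "+-" else "."),
        mature_end=mature_end,
        attributes=attributes,
    )


def _bed_feature(cols: Sequence[str], kind_map: Mapping[str, str], lineno: int) -> Feature:
    if len(cols) < 4:
        raise ValueError(f"expected >=4 BED columns, got {len(cols)}")
    chrom, start, end = cols[0], int(cols[1]), int(cols[2])
    name = cols[3]
    strand = cols[5] if len(cols) > 5 and cols[5] in "+-" else "."
    kind = "other"
    if ":" in name:
        prefix, rest = name.split(":", 1)
        if prefix.lower() in kind_map or prefix in FEATURE_KINDS:
            kind = kind_map.get(prefix.lower(), prefix)
            name = rest
    return Feature(id=name, kind=kind, interval=Interval(chrom, start, end, strand))


def write_features(features: FeatureSet, path: str | Path, format: str = "gff3") -> None:
    """Write features as GFF3 (1-based inclusive) or BED6 (0-based half-open)."""
    with xopen(path, "wt") as fh:
        if format == "gff3":
            fh.write("##gff-version 3\n")
            for f in features:
                iv = f.interval
                attrs = [f"ID={f.id}", f"kind={f.kind}"]
                if f.mature_end is not None:
                    pos = f.mature_end if iv.strand == "+" else f.mature_end + 1
                    attrs.append(f"mature_end={pos}")
                attrs += [f"{k}={v}" for k, v in f.attributes.items()]
                fh.write(
                    f"{iv.chrom}\tsenterm\t{f.kind}\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\t{';'.join(attrs)}\n"
                )
        elif format == "bed":
            for f in features:
                iv = f.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{f.kind}:{f.id}\t0\t"
                    f"{iv.strand if iv.strand in '+-' else '.'}\n"
                )
        else:
            raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# probe map and intensity I/O
# ---------------------------------------------------------------------------


def read_probe_map(path: str | Path, spacing_hint: int | None = None) -> ProbeMap:
    """Read a probe-map TSV with columns probe_id, chrom, center."""
    records: list[tuple[str, str, int]] = []
    with xopen(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["probe_id", "chrom", "center"]:
            raise ParseError(f"{path}:1: expected header probe_id\tchrom\tcenter")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                records.append((cols[0], cols[1], int(cols[2])))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    if spacing_hint is None:
        ordered = sorted(records, key=lambda r: (r[1], r[2]))
        diffs = [
            b[2] - a[2]
            for a, b in zip(ordered, ordered[1:])
            if a[1] == b[1]
        ]
        spacing_hint = int(np.median(diffs)) if diffs else 5
    return ProbeMap.from_records(records, spacing_hint=spacing_hint)


def write_probe_map(probe_map: ProbeMap, path: str | Path) -> None:
    with xopen(path, "wt") as fh:
        fh.write("probe_id\tchrom\tcenter\n")
        for pid, chrom, center in zip(
            probe_map.probe_ids, probe_map.chroms, probe_map.centers
        ):
            fh.write(f"{pid}\t{chrom}\t{center}\n")


def read_intensities(
    path: str | Path,
    probe_map: ProbeMap,
    array_info: Mapping[str, tuple[str, int]] | None = None,
) -> IntensitySet:
    """Read an intensity TSV (probe_id, then PM_<label>/MM_<label> pairs).

    Rows are aligned to the probe map's (chrom, center) order regardless of
    file order.  ``array_info`` optionally maps each array label to a
    (strain, replicate) pair; otherwise labels of the form
    ``<strain>_rep<k>`` are parsed and anything else becomes
    (label, replicate 1).
    """
    with xopen(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "probe_id":
            raise ParseError(f"{path}:1: first column must be probe_id")
        labels: list[str] = []
        for col in header[1:]:
            if col.startswith("PM_"):
                labels.append(col[3:])
            elif col.startswith("MM_"):
                if col[3:] not in labels:
                    raise ParseError(f"{path}:1: MM column {col} precedes its PM column")
            else:
                raise ParseError(f"{path}:1: unexpected column {col!r}")
        col_index = {c: i for i, c in enumerate(header)}
        for lab in labels:
            if f"MM_{lab}" not in col_index:
                raise ParseError(f"{path}:1: missing MM column for array {lab!r}")

        n = len(probe_map)
        pm = np.full((len(labels), n), np.nan)
        mm = np.full((len(labels), n), np.nan)
        seen = np.zeros(n, dtype=bool)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            pid = cols[0]
            try:
                row = probe_map.index_of(pid)
            except KeyError:
                raise ParseError(f"{path}:{lineno}: unknown probe_id {pid!r}") from None
            seen[row] = True
            for j, lab in enumerate(labels):
                pv = float(cols[col_index[f"PM_{lab}"]])
                mv = float(cols[col_index[f"MM_{lab}"]])
                if pv < 0 or mv < 0:
                    raise ParseError(f"{path}:{lineno}: negative intensity for {pid}")
                pm[j, row] = pv
                mm[j, row] = mv
    if not seen.all():
        missing = probe_map.probe_ids[~seen][0]
        raise ParseError(f"{path}: missing probe {missing!r}")

    arrays = []
    for lab in labels:
        if array_info and lab in array_info:
            strain, rep = array_info[lab]
        elif "_rep" in lab:
            strain, rep_s = lab.rsplit("_rep", 1)
            rep = int(rep_s) if rep_s.isdigit() else 1
        else:
            strain, rep = lab, 1
        arrays.append(ArrayInfo(label=lab, strain=strain, replicate=rep))
    return IntensitySet(probe_map=probe_map, arrays=arrays, pm=pm, mm=mm)


def write_intensities(intensities: IntensitySet, path: str | Path) -> None:
    with xopen(path, "wt") as fh:
        cols = ["probe_id"]
        for a in intensities.arrays:
            cols += [f"PM_{a.label}", f"MM_{a.label}"]
        fh.write("\t".join(cols) + "\n")
        pm, mm = intensities.pm, intensities.mm
        for i, pid in enumerate(intensities.probe_map.probe_ids):
            vals = []
            for j in range(len(intensities.arrays)):
                vals += [f"{pm[j, i]:.6f}", f"{mm[j, i]:.6f}"]
            fh.write(pid + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# track I/O and masking
# ---------------------------------------------------------------------------


def write_track(track: SignalTrack, path: str | Path, format: str = "bedgraph") -> None:
    """Write a track as bedGraph (run-length merged equal values, missing
    probes omitted) or as TSV (probe_id, chrom, center, value; missing = NA)."""
    pm = track.probe_map
    if format == "bedgraph":
        with xopen(path, "wt") as fh:
            fh.write(f'track type=bedGraph name="{track.kind}:{track.strain}"\n')
            run_chrom: str | None = None
            run_start = run_end = 0
            run_val = 0.0
            spacing = pm.spacing_hint

            def flush() -> None:
                if run_chrom is not None:
                    fh.write(f"{run_chrom}\t{run_start}\t{run_end}\t{run_val:.6f}\n")

            for chrom, center, v in zip(pm.chroms, pm.centers, track.values):
                if not np.isfinite(v):
                    flush()
                    run_chrom = None
                    continue
                start, end = int(center), int(center) + 1
                if (
                    run_chrom == chrom
                    and f"{v:.6f}" == f"{run_val:.6f}"
                    and start - run_end <= spacing
                ):
                    run_end = end
                else:
                    flush()
                    run_chrom, run_start, run_end, run_val = chrom, start, end, float(v)
            flush()
    elif format == "tsv":
        with xopen(path, "wt") as fh:
            fh.write("probe_id\tchrom\tcenter\tvalue\n")
            for pid, chrom, center, v in zip(
                pm.probe_ids, pm.chroms, pm.centers, track.values
            ):
                sval = "NA" if not np.isfinite(v) else f"{v:.6f}"
                fh.write(f"{pid}\t{chrom}\t{center}\t{sval}\n")
    else:
        raise ValueError(f"unknown track format {format!r}")


def read_track(
    path: str | Path,
    probe_map: ProbeMap,
    kind: str,
    window_bp: int,
    strain: str,
    baseline: str | None = None,
) -> SignalTrack:
    """Read a track TSV written by :func:`write_track` back onto a probe map."""
    values = np.full(len(probe_map), np.nan)
    with xopen(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["probe_id", "chrom", "center", "value"]:
            raise ParseError(f"{path}:1: not a track TSV")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            try:
                idx = probe_map.index_of(cols[0])
            except KeyError:
                raise ParseError(f"{path}:{lineno}: unknown probe {cols[0]!r}") from None
            values[idx] = np.nan if cols[3] == "NA" else float(cols[3])
    return SignalTrack(
        probe_map=probe_map,
        values=values,
        kind=kind,
        window_bp=window_bp,
        strain=strain,
        baseline=baseline,
    )


def mask_track(track: SignalTrack, mask: FeatureSet) -> SignalTrack:
    """Set values to missing for probes whose center lies in any mask interval.

    Idempotent; an empty mask returns an identical copy.  Reversed interval
    bounds in mask features are already normalized at Interval construction.
    """
    for f in mask:
        if f.kind != "mask":
            raise ValueError(f"mask feature {f.id} has kind {f.kind!r}, expected 'mask'")
    out = track.copy()
    pm = track.probe_map
    for f in mask:
        sl = pm.chrom_slice(f.interval.chrom)
        centers = pm.centers[sl]
        lo = int(np.searchsorted(centers, f.interval.start, side="left"))
        hi = int(np.searchsorted(centers, f.interval.end, side="left"))
        out.values[sl.start + lo : sl.start + hi] = np.nan
    return out
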