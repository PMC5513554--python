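"""End-to-end orchestration: config validation, stage execution, manifest.

The pipeline mirrors the two-pass analysis of the source protocol: replicate
arrays of each strain are quantile-normalized and median-scaled together for
the RNA-level pass, while each mutant's arrays are normalized jointly with
its matched wild-type arrays for the differential pass.  Stages:

    normalize -> tracks (101 bp; 500 bp when loops enabled) -> mask ->
    readthrough table -> metagene -> correlation matrix -> loops ->
    gene-level table -> screens

Every run writes a manifest (JSON) listing input and output checksums; a
rerun with identical config and inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    genome_io,
    normalization,
    profiles_comparison,
    regulatory_screens,
    synthetic_data,
    terminator_readthrough,
    window_stats,
)
from .genome_io import FeatureSet, SignalTrack

logger = logging.getLogger(__name__)

STAGES = (
    "normalize",
    "tracks",
    "readthrough",
    "metagene",
    "correlate",
    "loops",
    "genetable",
    "screens",
)

FLOAT_FORMAT = "%.6g"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, strain design, and stage toggles for one pipeline run."""

    probe_map: str
    intensities: str
    features: str
    outdir: str
    wt: str = synthetic_data.WT
    mutants: list[str] = field(default_factory=list)
    wt_map: dict[str, str] = field(default_factory=dict)  # mutant -> matched wt
    fasta: str | None = None
    masks: str | None = None  # BED of mask intervals; kind=mask features also apply
    window_bp: int = window_stats.DEFAULT_WINDOW_BP
    loop_window_bp: int = 501
    loop_pair: tuple[str, str] | None = None
    window_rule: str = terminator_readthrough.DEFAULT_WINDOW_RULE
    detect_on: str = "linear"
    target_median: float = normalization.DEFAULT_TARGET_MEDIAN
    stages: dict[str, bool] = field(default_factory=dict)
    seed: int = 0

    def matched_wt(self, mutant: str) -> str:
        return self.wt_map.get(mutant, self.wt)

    def stage_enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "loop_pair" in raw and raw["loop_pair"] is not None:
            raw["loop_pair"] = tuple(raw["loop_pair"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = asdict(self)
        if raw["loop_pair"] is not None:
            raw["loop_pair"] = list(raw["loop_pair"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Empty list iff the config is runnable; problems name the field."""
    problems: list[str] = []
    for attr in ("probe_map", "intensities", "features"):
        p = getattr(config, attr)
        if not Path(p).exists():
            problems.append(f"{attr}: path does not exist: {p}")
    for attr in ("fasta", "masks"):
        p = getattr(config, attr)
        if p is not None and not Path(p).exists():
            problems.append(f"{attr}: path does not exist: {p}")
    if not config.mutants:
        problems.append("mutants: at least one mutant strain required")
    for mutant in config.mutants:
        if not config.matched_wt(mutant):
            problems.append(f"wt_map: mutant {mutant!r} has no matched wild-type")
    if config.window_bp < 1:
        problems.append("window_bp: must be >= 1")
    elif config.window_bp % 2 == 0:
        logger.warning("window_bp %d is even; will be rounded up", config.window_bp)
    if config.loop_window_bp % 2 == 0:
        logger.warning("loop_window_bp %d is even; will be rounded up", config.loop_window_bp)
    if config.stage_enabled("loops") and config.loop_pair is None and len(config.mutants) < 2:
        problems.append("loop_pair: loops stage needs two strains")
    for stage in config.stages:
        if stage not in STAGES:
            problems.append(f"stages: unknown stage {stage!r}")
    if config.window_rule not in ("max50", "mean_region"):
        problems.append(f"window_rule: unknown rule {config.window_rule!r}")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    df.to_csv(path, sep="\t", index=kw.pop("index", False), float_format=FLOAT_FORMAT, **kw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns (and writes) the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {"inputs": {}, "stages": {}, "config": asdict(config)}
    if manifest["config"]["loop_pair"] is not None:
        manifest["config"]["loop_pair"] = list(manifest["config"]["loop_pair"])
    for attr in ("probe_map", "intensities", "features", "fasta", "masks"):
        p = getattr(config, attr)
        if p is not None:
            manifest["inputs"][attr] = _sha256(Path(p))

    outputs: dict[str, Path] = {}

    def record(stage: str, name: str, path: Path) -> None:
        outputs[name] = path
        manifest["stages"].setdefault(stage, {})[name] = _sha256(path)

    probe_map = genome_io.read_probe_map(config.probe_map)
    intensities = genome_io.read_intensities(config.intensities, probe_map)
    features = genome_io.read_features(config.features, format="gff3")
    masks = features.of_kind("mask")
    if config.masks:
        extra = genome_io.read_features(config.masks, format="bed")
        masks = FeatureSet(
            list(masks)
            + [
                genome_io.Feature(id=f.id, kind="mask", interval=f.interval)
                for f in extra
            ]
        )

    strains = [config.wt] + list(config.mutants)
    spec = window_stats.WindowSpec(config.window_bp)

    try:
        stage = "normalize"
        rna_norm: dict[str, genome_io.IntensitySet] = {}
        diff_norm: dict[str, genome_io.IntensitySet] = {}
        if config.stage_enabled(stage) or config.stage_enabled("tracks"):
            for strain in strains:
                rna_norm[strain] = normalization.normalize_group(
                    intensities,
                    group=intensities.strain_labels(strain),
                    target=config.target_median,
                )
            for mutant in config.mutants:
                wt = config.matched_wt(mutant)
                diff_norm[mutant] = normalization.normalize_group(
                    intensities,
                    group=intensities.strain_labels(mutant)
                    + intensities.strain_labels(wt),
                    target=config.target_median,
                )

        stage = "tracks"
        rna_tracks: dict[str, SignalTrack] = {}
        fc_tracks: dict[str, SignalTrack] = {}
        if config.stage_enabled(stage):
            for strain in strains:
                track, _score = window_stats.signal_track(
                    probe_map, rna_norm[strain], strain, spec, detect_on=config.detect_on
                )
                track = genome_io.mask_track(track, masks)
                rna_tracks[strain] = track
                path = outdir / f"rna_level_{strain}.tsv"
                genome_io.write_track(track, path, format="tsv")
                record(stage, f"rna_level_{strain}", path)
            for mutant in config.mutants:
                track, _score = window_stats.differential_track(
                    probe_map, diff_norm[mutant], mutant, config.matched_wt(mutant), spec
                )
                track = genome_io.mask_track(track, masks)
                fc_tracks[mutant] = track
                path = outdir / f"log2fc_{mutant}.tsv"
                genome_io.write_track(track, path, format="tsv")
                record(stage, f"log2fc_{mutant}", path)
                bg = outdir / f"log2fc_{mutant}.bedgraph"
                genome_io.write_track(track, bg, format="bedgraph")
                record(stage, f"log2fc_{mutant}_bedgraph", bg)

        stage = "readthrough"
        if config.stage_enabled(stage) and rna_tracks:
            table = terminator_readthrough.readthrough_table(
                features,
                {s: rna_tracks[s] for s in strains},
                wt_label=config.wt,
                window_rule=config.window_rule,
                all_features=features,
            )
            path = outdir / "readthrough_long.tsv"
            _write_csv(table, path)
            record(stage, "readthrough_long", path)
            wide = terminator_readthrough.to_wide(table)
            path = outdir / "readthrough_wide.tsv"
            _write_csv(wide, path, index=True)
            record(stage, "readthrough_wide", path)

        stage = "metagene"
        if config.stage_enabled(stage) and fc_tracks and len(features.of_kind("orf")):
            orfs = features.of_kind("orf")
            rows = []
            for mutant, track in fc_tracks.items():
                prof = profiles_comparison.metagene(orfs, track)
                for i, v in enumerate(prof.orf_bins):
                    rows.append({"strain": mutant, "bin": i, "region": "orf", "value": v})
                for i, v in enumerate(prof.utr_bins):
                    rows.append({"strain": mutant, "bin": i, "region": "utr3", "value": v})
            path = outdir / "metagene.tsv"
            _write_csv(pd.DataFrame(rows), path)
            record(stage, "metagene", path)

        stage = "correlate"
        if config.stage_enabled(stage) and len(fc_tracks) >= 2:
            mat = profiles_comparison.correlation_matrix(list(fc_tracks.values()))
            path = outdir / "correlation_matrix.tsv"
            _write_csv(mat, path, index=True)
            record(stage, "correlation_matrix", path)
            groups = profiles_comparison.correlation_groups(mat)
            path = outdir / "correlation_groups.tsv"
            _write_csv(groups, path)
            record(stage, "correlation_groups", path)

        stage = "loops"
        if config.stage_enabled(stage):
            pair = config.loop_pair or tuple(config.mutants[:2])
            loop_spec = window_stats.WindowSpec(config.loop_window_bp)
            loop_tracks = []
            for strain in pair:
                track, _ = window_stats.differential_track(
                    probe_map, diff_norm[strain], strain, config.matched_wt(strain), loop_spec
                )
                loop_tracks.append(genome_io.mask_track(track, masks))
            segments = profiles_comparison.detect_loops(
                loop_tracks[0], loop_tracks[1], features=features
            )
            rows = [
                {
                    "chrom": s.interval.chrom,
                    "start": s.interval.start,
                    "end": s.interval.end,
                    f"mean_log2fc_{pair[0]}": s.mean_a,
                    f"mean_log2fc_{pair[1]}": s.mean_b,
                    "peak_z": s.peak_z,
                    "features": ",".join(s.feature_ids),
                }
                for s in segments
            ]
            path = outdir / "loops.tsv"
            _write_csv(pd.DataFrame(rows), path)
            record(stage, "loops", path)
            path = outdir / "loops.bed"
            with open(path, "w") as fh:
                for i, s in enumerate(segments):
                    fh.write(
                        f"{s.interval.chrom}\t{s.interval.start}\t{s.interval.end}"
                        f"\tloop{i + 1}\t0\t.\n"
                    )
            record(stage, "loops_bed", path)

        stage = "genetable"
        gene_table = pd.DataFrame()
        if config.stage_enabled(stage) and fc_tracks and len(features.of_kind("orf")):
            orfs = features.of_kind("orf")
            gene_table = pd.concat(
                [profiles_comparison.gene_level_change(orfs, t) for t in fc_tracks.values()],
                ignore_index=True,
            )
            path = outdir / "gene_level_change.tsv"
            _write_csv(gene_table, path)
            record(stage, "gene_level_change", path)

        stage = "screens"
        if config.stage_enabled(stage) and fc_tracks:
            bias_rows = []
            for mutant, track in fc_tracks.items():
                for rec in regulatory_screens.upstream_bias(features, track):
                    bias_rows.append(
                        {
                            "gene_id": rec.gene_id,
                            "strain": mutant,
                            "up_mean": rec.up_mean,
                            "down_mean": rec.down_mean,
                            "bias": rec.bias,
                            "flagged": rec.flagged,
                        }
                    )
            path = outdir / "upstream_bias.tsv"
            _write_csv(pd.DataFrame(bias_rows), path)
            record(stage, "upstream_bias", path)

            if not gene_table.empty:
                fold_lists = {
                    m: regulatory_screens.threshold_gene_list(gene_table, m)
                    for m in fc_tracks
                }
                path = outdir / "twofold_gene_lists.tsv"
                rows = [
                    {"strain": m, "gene_id": g, "rank": i + 1}
                    for m, lst in fold_lists.items()
                    for i, g in enumerate(lst)
                ]
                _write_csv(pd.DataFrame(rows), path)
                record(stage, "twofold_gene_lists", path)

            if config.fasta:
                from Bio import SeqIO

                sequence = {
                    rec.id: str(rec.seq)
                    for rec in SeqIO.parse(genome_io.xopen(config.fasta), "fasta")
                }
                reports = regulatory_screens.screen_attenuators(
                    features, fc_tracks, sequence, features
                )
                path = outdir / "attenuator_screen.tsv"
                _write_csv(regulatory_screens.reports_to_frame(reports), path)
                record(stage, "attenuator_screen", path)
    except Exception as exc:  # noqa: BLE001 - abort names the failing stage
        partial = outdir / "manifest.partial.json"
        with open(partial, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise StageError(stage, exc) from exc

    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# scenario materialization (simulation -> on-disk pipeline inputs)
# ---------------------------------------------------------------------------


def write_scenario(
    config: synthetic_data.SimConfig, outdir: str | Path, with_fasta: bool = True
) -> RunConfig:
    """Simulate a scenario and write every pipeline input to ``outdir``.

    Emits probe map, intensity table, GFF3 annotation, genome FASTA, the
    truth table, and a ready-to-run pipeline config (YAML).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    features, probe_map, intensities, truth = synthetic_data.simulate(config)

    genome_io.write_probe_map(probe_map, outdir / "probe_map.tsv")
    genome_io.write_intensities(intensities, outdir / "intensities.tsv")
    genome_io.write_features(features, outdir / "features.gff3", format="gff3")
    _write_csv(truth, outdir / "truth.tsv")
    fasta_path = None
    if with_fasta:
        fasta_path = outdir / "genome.fa"
        seqs = synthetic_data.genome_sequence(config)
        with open(fasta_path, "w") as fh:
            for chrom in sorted(seqs):
                fh.write(f">{chrom}\n")
                seq = seqs[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    mutants = [s for s in config.strains if s != config.wt]
    run = RunConfig(
        probe_map=str(outdir / "probe_map.tsv"),
        intensities=str(outdir / "intensities.tsv"),
        features=str(outdir / "features.gff3"),
        fasta=str(fasta_path) if fasta_path else None,
        outdir=str(outdir / "results"),
        wt=config.wt,
        mutants=mutants,
        loop_pair=tuple(mutants[:2]) if len(mutants) >= 2 else None,
        stages={} if len(mutants) >= 2 else {"loops": False},
        seed=config.seed,
    )
    run.to_yaml(outdir / "run_config.yaml")
    return run
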