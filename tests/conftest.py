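"""Shared fixtures: the default synthetic scenario and its derived tracks.

The heavy objects (full simulation, per-strain RNA-level tracks, per-mutant
differential tracks) are session-scoped so the recovery and acceptance tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from senterm import normalization, synthetic_data, window_stats
from senterm.genome_io import ArrayInfo, IntensitySet, ProbeMap, SignalTrack

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_sim():
    """(config, features, probe_map, intensities, truth) for the default scenario."""
    config = synthetic_data.default_scenario(DEFAULT_SEED)
    features, probe_map, intensities, truth = synthetic_data.simulate(config)
    return config, features, probe_map, intensities, truth


@pytest.fixture(scope="session")
def rna_tracks(default_sim):
    """Per-strain RNA-level tracks (normalized per strain, 101-bp window)."""
    config, _features, probe_map, intensities, _truth = default_sim
    tracks = {}
    for strain in config.strains:
        norm = normalization.normalize_group(
            intensities, group=intensities.strain_labels(strain)
        )
        tracks[strain], _ = window_stats.signal_track(probe_map, norm, strain)
    return tracks


@pytest.fixture(scope="session")
def fc_tracks(default_sim):
    """Per-mutant log2fc tracks (mutant normalized jointly with wild-type)."""
    config, _features, probe_map, intensities, _truth = default_sim
    tracks = {}
    for mutant in config.strains:
        if mutant == config.wt:
            continue
        norm = normalization.normalize_group(
            intensities,
            group=intensities.strain_labels(mutant)
            + intensities.strain_labels(config.wt),
        )
        tracks[mutant], _ = window_stats.differential_track(
            probe_map, norm, mutant, config.wt
        )
    return tracks


def make_probe_map(
    n: int = 60, spacing: int = 5, chrom: str = "chrT", start: int = 2
) -> ProbeMap:
    """A small uniform probe map for constructed-track tests."""
    return ProbeMap.from_records(
        [(f"{chrom}:p{start + i * spacing:06d}", chrom, start + i * spacing) for i in range(n)],
        spacing_hint=spacing,
    )


def make_track(
    values, probe_map: ProbeMap, kind: str = "rna_level", strain: str = "mut",
    baseline: str | None = None, window_bp: int = 101
) -> SignalTrack:
    if kind == "log2fc" and baseline is None:
        baseline = "WT"
    return SignalTrack(
        probe_map=probe_map,
        values=np.asarray(values, dtype=float),
        kind=kind,
        window_bp=window_bp,
        strain=strain,
        baseline=baseline,
    )


def make_intensities(pm_rows, mm_rows, probe_map: ProbeMap, strains=None) -> IntensitySet:
    pm = np.atleast_2d(np.asarray(pm_rows, dtype=float))
    mm = np.atleast_2d(np.asarray(mm_rows, dtype=float))
    strains = strains or [f"s{i}" for i in range(pm.shape[0])]
    arrays = [ArrayInfo(label=f"{s}_rep1", strain=s, replicate=1) for s in strains]
    return IntensitySet(probe_map=probe_map, arrays=arrays, pm=pm, mm=mm)
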