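"""Synthetic tiling-array generator with known injected effects.

Emulates an Affymetrix-style PM/MM tiling design over a mock genome: probe
pairs tiled at ~5-bp spacing, two biological replicates per strain, a
lognormal mismatch (background) channel, and a perfect-match channel carrying
the transcript signal with multiplicative noise:

    MM_probe        ~ lognormal(background)           (shared across arrays)
    PM_probe,array  = MM_probe + max(0, gain * T(pos, strain) * (1 + eps))
    eps ~ Normal(0, noise_cv), independent per array and probe

T(pos, strain) sums, over every transcript covering pos, the transcript's
abundance multiplied by a 5'->3' elongation gradient (1 - lambda *
dist5'/1000, floored at 0), an attenuator factor (positions past the
attenuator carry the strain's release fraction), and — for terminator
readthrough — the readthrough fraction f for positions between the mature 3'
end and the transcript's downstream stop.  With noise_cv = 0, PM - MM equals
gain * T exactly, which is the generator's own oracle.

Because MM carries no signal and is shared between replicates, replicates
differ only through the noise stream.  One seed governs an explicitly
ordered set of substreams (genome sequence, background, then per-array
noise), so adding strains or features does not reshuffle existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import ArrayInfo, Feature, FeatureSet, IntensitySet, Interval, ProbeMap

WT = "WT"
MUTANTS = ("sen1", "nrd1", "nab3", "ssu72", "rpb11", "hrp1")

__all__ = [
    "WT",
    "MUTANTS",
    "FeatureSpec",
    "SimConfig",
    "simulate",
    "default_scenario",
    "null_scenario",
    "abundance_profile",
    "genome_sequence",
]


@dataclass(frozen=True)
class FeatureSpec:
    """One transcript with its baseline abundance and per-strain effects.

    Effects default to "no effect" for strains absent from the mappings:
    fold change 1, readthrough fraction 0, attenuator release equal to
    ``release_default`` (1 = no attenuation), elongation slope 0.
    ``downstream_stop`` is the genomic coordinate at which readthrough
    transcripts end (strictly 3' of ``mature_end`` on the transcribed
    strand); ``attenuator_offset`` is measured in bp from the transcript 5'
    end (which sits ``tss_offset`` bp upstream of the feature interval).
    """

    feature: Feature
    baseline_abundance: float
    fold_change: Mapping[str, float] = field(default_factory=dict)
    readthrough_fraction: Mapping[str, float] = field(default_factory=dict)
    downstream_stop: int | None = None
    attenuator_offset: int | None = None
    attenuator_release: Mapping[str, float] = field(default_factory=dict)
    release_default: float = 1.0
    elongation_slope: Mapping[str, float] = field(default_factory=dict)
    tss_offset: int = 0

    def __post_init__(self) -> None:
        if self.baseline_abundance < 0:
            raise ValueError("baseline_abundance must be >= 0")
        for f in self.readthrough_fraction.values():
            if not 0 <= f <= 1:
                raise ValueError("readthrough fractions must lie in [0, 1]")
        for r in self.attenuator_release.values():
            if not 0 <= r <= 1:
                raise ValueError("attenuator release must lie in [0, 1]")
        if any(self.readthrough_fraction.values()):
            me = self.feature.mature_end
            if me is None or self.downstream_stop is None:
                raise ValueError(
                    f"{self.feature.id}: readthrough requires mature_end and downstream_stop"
                )
            if self.feature.strand == "+" and self.downstream_stop <= me:
                raise ValueError(f"{self.feature.id}: downstream_stop must be > mature_end")
            if self.feature.strand == "-" and self.downstream_stop >= me:
                raise ValueError(
                    f"{self.feature.id}: downstream_stop must be < mature_end on -"
                )

    def fold(self, strain: str) -> float:
        return float(self.fold_change.get(strain, 1.0))

    def f_readthrough(self, strain: str) -> float:
        return float(self.readthrough_fraction.get(strain, 0.0))

    def release(self, strain: str) -> float:
        return float(self.attenuator_release.get(strain, self.release_default))

    def slope(self, strain: str) -> float:
        return float(self.elongation_slope.get(strain, 0.0))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; a fixed seed yields byte-identical outputs."""

    seed: int
    genome: Sequence[tuple[str, int]]
    strains: Sequence[str]
    wt: str = WT
    probe_spacing: int = 5
    n_replicates: int = 2
    background: tuple[float, float] = (np.log(60.0), 0.35)  # (log-mean, log-sd)
    gain: float = 50.0
    noise_cv: float = 0.25
    features: Sequence[FeatureSpec] = ()
    extra_features: Sequence[Feature] = ()  # masks, poly(A) clusters, annotation-only

    def __post_init__(self) -> None:
        if self.probe_spacing < 1:
            raise ValueError("probe_spacing must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        names = [c for c, _ in self.genome]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in genome")
        if self.wt not in self.strains:
            raise ValueError("wt strain must be listed in strains")


# ---------------------------------------------------------------------------
# abundance model
# ---------------------------------------------------------------------------


def _spec_contribution(
    spec: FeatureSpec, strain: str, centers: np.ndarray
) -> np.ndarray:
    """Abundance contributed by one transcript at the given probe centers
    (all on the transcript's chromosome)."""
    iv = spec.feature.interval
    a = spec.baseline_abundance * spec.fold(strain)
    out = np.zeros(len(centers))
    if a == 0:
        return out
    lam = spec.slope(strain)
    rel = spec.release(strain)
    f = spec.f_readthrough(strain)
    me = spec.feature.mature_end

    plus = iv.strand != "-"
    if plus:
        tss = iv.start - spec.tss_offset
        body_end = me if me is not None else iv.end
        t = centers - tss  # transcript coordinate (bp from 5' end)
        body = (centers >= tss) & (centers < body_end)
    else:
        tss = iv.end + spec.tss_offset  # half-open 5' boundary
        body_start = me if me is not None else iv.start
        t = tss - 1 - centers
        body = (centers >= body_start) & (centers < tss)

    grad = np.maximum(0.0, 1.0 - lam * t / 1000.0)
    atten = np.ones(len(centers))
    if spec.attenuator_offset is not None:
        atten[t >= spec.attenuator_offset] = rel
    out[body] = a * grad[body] * atten[body]

    if f > 0 and me is not None and spec.downstream_stop is not None:
        if plus:
            rt = (centers >= me) & (centers < spec.downstream_stop)
        else:
            rt = (centers >= spec.downstream_stop) & (centers < me)
        out[rt] = a * f * grad[rt] * atten[rt]
    return out


def abundance_profile(config: SimConfig, probe_map: ProbeMap) -> pd.DataFrame:
    """Noise-free abundance T(pos, strain) at every probe center.

    Returns a DataFrame indexed like the probe map with one column per
    strain.  This is the independent oracle for the sampler: with
    noise_cv = 0, PM - MM equals gain times these values exactly.
    """
    data = {s: np.zeros(len(probe_map)) for s in config.strains}
    for spec in config.features:
        chrom = spec.feature.interval.chrom
        sl = probe_map.chrom_slice(chrom)
        centers = probe_map.centers[sl]
        for strain in config.strains:
            data[strain][sl] += _spec_contribution(spec, strain, centers)
    return pd.DataFrame(data)


def _build_probe_map(config: SimConfig) -> ProbeMap:
    records = []
    for chrom, length in sorted(config.genome):
        for center in range(2, length, config.probe_spacing):
            records.append((f"{chrom}:p{center:08d}", chrom, center))
    return ProbeMap.from_records(records, spacing_hint=config.probe_spacing)


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate(
    config: SimConfig,
) -> tuple[FeatureSet, ProbeMap, IntensitySet, pd.DataFrame]:
    """Generate annotations, probe layout, intensities, and the truth table.

    The returned IntensitySet holds all strains' replicate arrays (labels
    ``<strain>_rep<k>``).  The truth table has one row per (feature, strain)
    with the injected effect sizes, plus — for ORF-kind features — the
    effective ORF-mean log2 fold change implied by the abundance model
    (the quantity gene-level recovery is judged against).
    """
    probe_map = _build_probe_map(config)
    profile = abundance_profile(config, probe_map)

    rng_bg = _stream(config.seed, 1)
    log_mean, log_sd = config.background
    mm_row = np.exp(rng_bg.normal(log_mean, log_sd, size=len(probe_map)))

    arrays: list[ArrayInfo] = []
    pm_rows, mm_rows = [], []
    for si, strain in enumerate(config.strains):
        t = profile[strain].to_numpy()
        for rep in range(1, config.n_replicates + 1):
            if config.noise_cv > 0:
                eps = _stream(config.seed, 2, si, rep).normal(
                    0.0, config.noise_cv, size=len(probe_map)
                )
            else:
                eps = 0.0
            signal = np.maximum(0.0, config.gain * t * (1.0 + eps))
            pm_rows.append(mm_row + signal)
            mm_rows.append(mm_row.copy())
            arrays.append(ArrayInfo(label=f"{strain}_rep{rep}", strain=strain, replicate=rep))
    intensities = IntensitySet(
        probe_map=probe_map,
        arrays=arrays,
        pm=np.vstack(pm_rows),
        mm=np.vstack(mm_rows),
    )

    features = FeatureSet(
        [s.feature for s in config.features] + list(config.extra_features)
    )
    truth = _truth_table(config, probe_map, profile)
    return features, probe_map, intensities, truth


def _truth_table(
    config: SimConfig, probe_map: ProbeMap, profile: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    wt_t = profile[config.wt].to_numpy()
    for spec in config.features:
        feat = spec.feature
        iv = feat.interval
        sl = probe_map.chrom_slice(iv.chrom)
        centers = probe_map.centers[sl]
        in_orf = (centers >= iv.start) & (centers < iv.end)
        for strain in config.strains:
            row = {
                "feature_id": feat.id,
                "kind": feat.kind,
                "strain": strain,
                "fold_change": spec.fold(strain),
                "readthrough_fraction": spec.f_readthrough(strain),
                "attenuator_release": spec.release(strain),
                "elongation_slope": spec.slope(strain),
                "orf_log2fc_truth": np.nan,
            }
            if feat.kind == "orf":
                t_s = profile[strain].to_numpy()[sl][in_orf]
                t_w = wt_t[sl][in_orf]
                ok = (t_s > 0) & (t_w > 0)
                if ok.any():
                    row["orf_log2fc_truth"] = float(np.mean(np.log2(t_s[ok] / t_w[ok])))
            rows.append(row)
    truth = pd.DataFrame(rows)
    truth["orf_fold_truth"] = 2.0 ** truth["orf_log2fc_truth"]
    return truth


# ---------------------------------------------------------------------------
# genome sequence with planted promoter/UTR elements
# ---------------------------------------------------------------------------


def genome_sequence(config: SimConfig) -> dict[str, str]:
    """Deterministic random genome with planted regulatory elements.

    Features carrying a ``plant_stss`` attribute get an ATG-free scan region
    (350 bp upstream of the feature start on the nontemplate strand), a TATA
    box 300 bp upstream, and a Nab3 UCUU site (TCTT in DNA) 150 bp upstream —
    the sequence profile of a single-TATA/single-start attenuated gene.
    Plus-strand placement is assumed for planted genes.
    """
    rng = _stream(config.seed, 0)
    bases = np.array(list("ACGT"))
    seqs: dict[str, list[str]] = {}
    for chrom, length in sorted(config.genome):
        seqs[chrom] = list(bases[rng.integers(0, 4, size=length)])
    for spec in config.features:
        feat = spec.feature
        if feat.attributes.get("plant_stss") != "1":
            continue
        seq = seqs[feat.interval.chrom]
        start = feat.interval.start
        lo = max(0, start - 350)
        # scrub ATG trinucleotides from the nontemplate strand of the UTR
        region = seq[lo:start]
        text = "".join(region)
        while "ATG" in text:
            idx = text.index("ATG")
            region[idx + 2] = "C"
            text = "".join(region)
        seq[lo:start] = region
        seq[start - 300 : start - 292] = list("TATAAAAG")
        seq[start - 150 : start - 146] = list("TCTT")
    return {chrom: "".join(s) for chrom, s in seqs.items()}


# ---------------------------------------------------------------------------
# canned scenarios
# ---------------------------------------------------------------------------


def _snr(
    fid: str,
    chrom: str,
    start: int,
    length: int = 400,
    strand: str = "+",
    rt_span: int = 400,
    abundance: float = 4.0,
    f: Mapping[str, float] | None = None,
) -> FeatureSpec:
    if strand == "+":
        iv = Interval(chrom, start, start + length, "+")
        me, stop = iv.end, iv.end + rt_span
    else:
        iv = Interval(chrom, start, start + length, "-")
        me, stop = iv.start, iv.start - rt_span
    return FeatureSpec(
        feature=Feature(id=fid, kind="snr", interval=iv, mature_end=me),
        baseline_abundance=abundance,
        readthrough_fraction=dict(f or {}),
        downstream_stop=stop,
    )


def default_scenario(seed: int) -> SimConfig:
    """The bundled study-like scenario: a 200-kb two-chromosome mock genome,
    wild-type plus six mutants, two replicates each.

    Injected effects: ten sn/snoRNA genes with per-strain terminator
    readthrough fractions spanning 0-0.6 (including a Pol III-like negative
    control with f = 0 everywhere and one gene confounded by an immediately
    downstream CUT); twenty ORFs including a single-TATA/single-start
    attenuated gene (ATG-free 5'-UTR, planted Nab3 site, upstream poly(A)
    cluster), a sawtooth elongation-defect gene (positive 5'->3' slope in
    hrp1 only), a meiotic-like gene whose full-length isoform is derepressed
    in sen1 over a constitutive internal start, a long gene with an exact
    +1.5 log2 fold change in sen1, shared up-regulation between nrd1 and
    nab3, rpb11-specific induction, hrp1-specific reduction; and two
    plasmid-style mask intervals.
    """
    strains = [WT, *MUTANTS]
    chrI, chrII = ("chrI", 120_000), ("chrII", 80_000)

    specs: list[FeatureSpec] = []
    # --- sn/snoRNA genes on chrI -----------------------------------------
    snr_effects: dict[str, dict[str, float]] = {
        "snr01": {"sen1": 0.6, "nrd1": 0.45, "nab3": 0.5, "ssu72": 0.4, "rpb11": 0.3, "hrp1": 0.1},
        "snr02": {"sen1": 0.3, "nrd1": 0.3, "nab3": 0.25, "ssu72": 0.2},
        "snr03": {"sen1": 0.15, "nrd1": 0.12, "nab3": 0.15},
        "snr04": {"sen1": 0.5, "rpb11": 0.5},
        "snr05": {"sen1": 0.3},
        "snr06": {"sen1": 0.6, "nrd1": 0.5, "nab3": 0.55, "ssu72": 0.45},
        "snr07": {"sen1": 0.15, "hrp1": 0.3},
        "snr08": {"sen1": 0.45, "nrd1": 0.2, "nab3": 0.2, "ssu72": 0.3, "hrp1": 0.15},
        "snr_ctrl": {},  # Pol III-like negative control: no readthrough anywhere
        "snr09": {"sen1": 0.4, "nrd1": 0.3},  # confounded by the CUT below
    }
    pos = 5_000
    for i, (fid, eff) in enumerate(snr_effects.items()):
        strand = "-" if fid == "snr07" else "+"
        specs.append(_snr(fid, "chrI", pos, strand=strand, f=eff))
        pos += 2_500

    cut_start = specs[-1].feature.interval.end + 50  # 50 bp downstream of snr09
    extra: list[Feature] = [
        Feature(
            id="cut01",
            kind="cut",
            interval=Interval("chrI", cut_start, cut_start + 300, "+"),
        )
    ]

    # Unaffected expressed mass spanning a broad abundance spectrum.  Real
    # arrays are dominated by transcripts that no mutation touches (rRNA,
    # tRNA, most mRNAs), which is what lets joint quantile normalization of
    # treatment and control arrays leave genuine fold changes intact; the
    # mock genome needs the same dilution or normalization would compress
    # the injected effects.
    for bi, abundance in enumerate(2.0 ** np.linspace(-1.0, 3.2, 26)):
        start = 30_000 + bi * 3_000
        specs.append(
            FeatureSpec(
                feature=Feature(
                    id=f"bg{bi:02d}",
                    kind="other",
                    interval=Interval("chrI", start, start + 2_500, "+"),
                ),
                baseline_abundance=float(abundance),
            )
        )

    # --- protein-coding genes on chrII -----------------------------------
    def orf(fid: str, start: int, length: int, strand: str = "+", **kw) -> FeatureSpec:
        return FeatureSpec(
            feature=Feature(
                id=fid,
                kind="orf",
                interval=Interval("chrII", start, start + length, strand),
                attributes=kw.pop("attributes", {}),
            ),
            **kw,
        )

    cursor = 2_000
    lengths = [1500, 2000, 2000, 3000] + [1500] * 16

    def next_start(length: int) -> int:
        nonlocal cursor
        start = cursor
        cursor = start + length + 900
        return start

    # ST-SS attenuated gene: attenuator in the 350-bp 5'-UTR, released in mutants
    specs.append(
        orf(
            "orf01",
            next_start(lengths[0]),
            lengths[0],
            baseline_abundance=3.0,
            tss_offset=350,
            attenuator_offset=250,
            attenuator_release={WT: 0.25, "sen1": 0.9, "ssu72": 0.6, "nrd1": 0.5},
            release_default=0.25,
            attributes={"plant_stss": "1"},
        )
    )
    # sawtooth elongation-defect gene (hrp1 only)
    specs.append(
        orf(
            "orf02",
            next_start(lengths[1]),
            lengths[1],
            baseline_abundance=4.0,
            elongation_slope={"hrp1": 0.45},
        )
    )
    # meiotic-like gene: constitutive internal start + sen1-derepressed full length
    mei_start = next_start(lengths[2])
    mei_len = lengths[2]
    specs.append(orf("orf03", mei_start, mei_len, baseline_abundance=0.5,
                     fold_change={"sen1": 6.0}))
    specs.append(
        FeatureSpec(
            feature=Feature(
                id="orf03_internal",
                kind="other",
                interval=Interval("chrII", mei_start + mei_len // 2, mei_start + mei_len, "+"),
            ),
            baseline_abundance=3.0,
        )
    )
    # long gene with an exact +1.5 log2 fold change in sen1
    specs.append(
        orf(
            "orf04",
            next_start(lengths[3]),
            lengths[3],
            baseline_abundance=3.0,
            fold_change={"sen1": 2.0 ** 1.5},
        )
    )
    # boundary case: exactly two-fold in sen1
    specs.append(orf("orf05", next_start(lengths[4]), lengths[4],
                     baseline_abundance=2.5, fold_change={"sen1": 2.0}))
    # shared nrd1/nab3 (and sen1) induction — the high-overlap pair
    for i in range(6, 10):
        specs.append(
            orf(
                f"orf{i:02d}",
                next_start(lengths[i - 1]),
                lengths[i - 1],
                baseline_abundance=3.0,
                fold_change={"sen1": 2.2, "nrd1": 2.0, "nab3": 2.1},
            )
        )
    # rpb11-specific induction (FLO1-like) — the low-overlap strain
    for i in range(10, 12):
        specs.append(
            orf(f"orf{i:02d}", next_start(lengths[i - 1]), lengths[i - 1],
                baseline_abundance=3.0, fold_change={"rpb11": 2.5})
        )
    # hrp1-specific reduction
    for i in range(12, 15):
        specs.append(
            orf(f"orf{i:02d}", next_start(lengths[i - 1]), lengths[i - 1],
                baseline_abundance=3.0, fold_change={"hrp1": 0.5})
        )
    # unaffected genes (null background for screens and correlations)
    for i in range(15, 21):
        strand = "-" if i % 2 else "+"
        specs.append(
            orf(f"orf{i:02d}", next_start(lengths[i - 1]), lengths[i - 1],
                strand=strand, baseline_abundance=2.0 + 0.3 * (i - 15))
        )
    # down-regulated genes: repressible-phosphatase-like (down in every
    # mutant) and CWP1-like (down in sen1/ssu72/hrp1).  Besides being real
    # phenotypes of the study system, they keep each mutant's net transcript
    # mass roughly balanced, which the rank-based joint normalization of
    # treatment and control arrays implicitly assumes.
    down_all = {m: 0.3 for m in MUTANTS}
    for i, fid in enumerate(["orf21", "orf22"]):
        specs.append(orf(fid, next_start(2000), 2000, baseline_abundance=7.0,
                         fold_change=dict(down_all)))
    specs.append(orf("orf23", next_start(2000), 2000, baseline_abundance=9.0,
                     fold_change={"sen1": 0.35, "ssu72": 0.5, "hrp1": 0.5}))
    specs.append(orf("orf24", next_start(2500), 2500, baseline_abundance=8.0,
                     fold_change={"sen1": 0.4}))

    # poly(A) cluster at the upstream end of the attenuated ORF
    o1 = next(s.feature.interval for s in specs if s.feature.id == "orf01")
    extra.append(
        Feature(id="polyA_orf01", kind="polyA_cluster",
                interval=Interval("chrII", o1.start, o1.start + 60, "+"))
    )
    # plasmid-style masks over feature-free regions
    extra.append(Feature(id="mask_chrI", kind="mask",
                         interval=Interval("chrI", 110_000, 112_000, ".")))
    extra.append(Feature(id="mask_chrII", kind="mask",
                         interval=Interval("chrII", 76_000, 77_500, ".")))

    return SimConfig(
        seed=seed,
        genome=[chrI, chrII],
        strains=strains,
        features=specs,
        extra_features=extra,
    )


def null_scenario(seed: int, strain: str = "sen1") -> SimConfig:
    """A fully expressed genome with no differential effects, for calibration
    of the rank-sum detection score (every window informative, all folds 1)."""
    length = 60_000
    specs = [
        FeatureSpec(
            feature=Feature(
                id=f"block{i:02d}",
                kind="other",
                interval=Interval("chrN", i * 10_000, (i + 1) * 10_000, "+"),
            ),
            baseline_abundance=3.0,
        )
        for i in range(length // 10_000)
    ]
    return SimConfig(
        seed=seed,
        genome=[("chrN", length)],
        strains=[WT, strain],
        features=specs,
    )
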