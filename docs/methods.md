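# Methods

This note documents the statistical model behind `senterm`, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the design choices made where the design was genuinely open.

## Probe-level model and normalization

The data model is an Affymetrix-style tiling design: paired perfect-match
(PM) and mismatch (MM) probes, one pair per interrogated genomic position
(we index probes by their center coordinate and do not model probe
length).  MM serves as a per-probe background estimate, so the per-probe
signal is d = PM − MM on the linear scale, and x = log₂(max(d, 1)) on the
log scale, with the floor at 1 absorbing negative and sub-unit
differences.

Normalization proceeds in two passes mirroring how treatment/control
tiling analyses are conventionally run:

* RNA-level pass: the replicate arrays of one strain are quantile
  normalized together.
* Differential pass: each mutant's arrays are quantile normalized
  jointly with its matched wild-type arrays.

Each array's PM and MM vectors are concatenated into one vector before
quantile normalization (a `joint_pm_mm` flag normalizes them separately;
the joint default reflects that scaling is effectively to total hybridized
material).  Ties receive the mean of the tied ranks' targets, making the
transform deterministic and idempotent.  The group is then linearly
scaled so the pooled PM∪MM median is 100 (`target_median`).

Because normalization is rank-based across treatment and control arrays
together, it implicitly assumes that differentially expressed probes are
a minority diluted by a broad spectrum of unaffected signal.  When the
treated sample gains (or loses) substantial net transcript mass, the
normalization redistributes part of that excess — net genome-wide changes
are detectable but compressed.  This is an inherent property of the
method, not an artifact of this implementation; the synthetic default
scenario is constructed to sit in the dilution regime (below).

## Windowed rank statistics

All per-position statistics use a bp-defined window (default 101 bp,
odd; even widths are rounded up) centered on each probe, truncated at
chromosome ends, with replicate arrays pooled into one window sample.

**RNA level.**  A one-sample Wilcoxon signed-rank test of the window's d
values against location 0 (one-sided, positive).  Zeros are handled by
Pratt's method — zeros are ranked together with the rest but excluded
from the statistic, and the null is conditional on the observed zeros —
and ties receive midranks.  For ≤ `exact_n_max` (25) nonzero values the
null distribution is computed exactly by a convolution over the doubled
midranks; beyond that a normal approximation with continuity correction
is used.  The detection score is −10·log₁₀(p).  The signal estimate s is
the Hodges-Lehmann pseudomedian of d (median of Walsh averages); the RNA
level is log₂(s) for s > 1 and 0 otherwise.

The signed-rank test is applied to the *linear* d values by default.
Applying a one-sided positive test to the nonnegative log-floored x
values instead is degenerate (no negative values can ever appear), and
the s > 1 → log₂(s) floor rule is only coherent if s lives on the linear
scale; `detect_on="log2"` is provided for the literal log-scale reading.

**Differential RNA level.**  A two-sample Wilcoxon rank-sum test (two
sided, midranks, tie-corrected variance, continuity correction) on the x
values of the mutant vs wild-type window samples, with the two-sample
Hodges-Lehmann shift — the median of all pairwise x_treat − x_ctrl —
reported directly as the log₂ fold change.

Both tests are authored here (scipy supplies only `rankdata` and the
normal distribution); the test suite verifies them against exhaustive
sign-assignment enumeration, brute-force Walsh-average/pairwise-difference
enumeration, and scipy's `wilcoxon`/`mannwhitneyu` where those are
applicable.

## Terminator readthrough

For a sn/snoRNA gene with annotated mature 3' end, signals are converted
back to the linear scale (2^level where the level is positive, else 0) and

    R = 100% × downstream_mean / body_mean

where body_mean averages the mature coding region and downstream_mean
summarizes a 50-bp window inside the region 10–310 bp 3' of the mature
end (strand-aware).  The differential ratio subtracts the matched
wild-type value; < 10 points is classified `none`, 10–100 `readthrough`,
> 100 `confounded`, and genes whose downstream region overlaps another
annotated transcription unit are `excluded` (masks and poly(A) clusters
do not trigger exclusion — they are not transcription units).  A
`body-decrease` note marks defects driven by diminished mature RNA
(mutant body below half of wild-type) rather than elevated downstream
signal.

Two placements of the 50-bp downstream window are provided.  `max50`
takes the maximum 50-bp sub-window mean inside the scan region, stepped
at probe spacing; `mean_region` (the default) averages the whole region.
With 101-bp smoothing, the probes in the first ~40 bp of the scan region
are contaminated by bleed from the gene body, and since (1 + f)/2 > f for
any readthrough fraction f < 1, `max50` systematically selects exactly
that contaminated sub-window and overestimates single-strain ratios.
`mean_region` dilutes the bleed ~10-fold and recovers injected fractions
within a few points (verified against the generator's truth table), which
is why it is the default; `max50` remains available for sensitivity
analysis and for data where intermediate 3'-end processing dominates.

## Analytics

* **Metagene**: each gene contributes per-bin means over 100
  percent-distance bins along the ORF (strand-aware) and ten 10-bp bins
  over the first 100 bp after the stop codon; genes are then averaged
  with equal weight so long genes do not dominate.
* **Correlation**: Pearson over every probe position finite in both
  tracks (masked positions drop pairwise); a banding helper groups the
  pairs by coefficient.
* **Loops**: per track, robust z = (value − median)/(1.4826·MAD); probes
  with max(|z_A|, |z_B|) ≥ 4 are merged across gaps ≤ 250 bp and runs
  spanning ≥ 300 bp are reported with overlapping-feature annotation.
  The robust scale is floored at `min_scale` = 0.05 log₂ units: on
  near-noiseless tracks (e.g. long-window summaries of low-noise data)
  the MAD measures only numerical jitter and would otherwise flag
  negligible excursions.  MAD = 0 falls back to the standard deviation
  with a warning.
* **Screens**: the attenuation screen is a transparent conjunction of
  named boolean criteria — fold ≥ 2 in ≥ 1 strain, ATG-free nontemplate
  strand over the 5'-UTR scan region (annotated TSS if present, else
  350 bp upstream of the start codon), Nab3 `UCUU` / Nrd1 `GUAR` motif
  hits on the transcript strand, TATA consensus `TATAWAWR` 200–400 bp
  upstream, and an upstream poly(A)-cluster overlap.  Every criterion is
  reported so users can re-weight; the consensi are config strings in
  IUPAC code (the canonical literature motifs are defaults).  The
  upstream-bias screen splits each ORF at its midpoint in transcription
  direction and flags up_mean ≥ 1.0 with bias ≥ 0.5 (log₂ units).

## Synthetic data generator

The generator emulates the study design: a mock genome, probe pairs
tiled every 5 bp, wild-type plus six mutant strains, two biological
replicates each.  Abundance at a position is the sum over covering
transcripts of

    abundance × fold_change(strain) × gradient × attenuator × readthrough

with gradient = max(0, 1 − λ·dist₅'/1000) (an elongation-defect slope λ
per kb), an attenuator factor equal to the strain's release fraction for
positions past the attenuator offset, and readthrough transcripts present
at fraction f between the mature 3' end and a per-gene downstream stop.
Intensities are MM ~ lognormal(log-mean ln 60, log-sd 0.35), shared
across arrays, and PM = MM + max(0, gain·T·(1+ε)) with gain 50 and
ε ~ N(0, noise_cv), noise_cv 0.25, drawn independently per array — so
replicates differ only through the noise stream, and with noise_cv = 0
the realized PM − MM equals gain·T exactly (the generator's own oracle).
One seed drives an explicitly ordered set of substreams (sequence,
background, per-array noise), so outputs are byte-reproducible and
adding strains does not reshuffle existing draws.

The default scenario (200 kb, two chromosomes, 40,000 probe pairs)
injects: ten sn/snoRNA genes with per-strain readthrough fractions
spanning 0–0.6, including a Pol III-like negative control (f = 0
everywhere) and one gene confounded by an immediately downstream CUT;
twenty-four ORFs including a single-TATA/single-start attenuated gene
(ATG-free 350-bp 5'-UTR with planted TATA box and Nab3 site, upstream
poly(A) cluster, attenuator released in sen1/ssu72/nrd1), a sawtooth
elongation-defect gene (λ = 0.45/kb in hrp1), a meiotic-like gene whose
full-length isoform is derepressed over a constitutive internal start in
sen1, a gene with an exact +1.5 log₂ fold change in sen1, shared
induction between nrd1 and nab3, rpb11-specific induction, and
down-regulated genes (phosphatase-like repression in all mutants,
CWP1-like loss in sen1/ssu72/hrp1); two plasmid-style mask intervals;
and 26 unaffected transcripts spanning abundances 0.5–9 in geometric
steps.  The unaffected spectrum is not decoration: it reproduces the
dilution regime that joint quantile normalization needs (most array
signal comes from transcripts no mutation touches), and the down
regulated genes keep each mutant's net transcript mass roughly balanced.
Effect-overlap structure across strains (sen1 broad, nrd1/nab3 nearly
identical, rpb11 mostly private) gives the pairwise correlation matrix a
known ordering.

A separate null scenario (60 kb, fully covered by expressed blocks, no
differential effects) calibrates the rank-sum detection score: every
window is informative and the fraction of positions exceeding the
p < 0.05 score is ~4–5% (slightly conservative, as expected for a
continuity-corrected rank test).

What the generator does **not** emulate: probe-sequence-dependent
hybridization and cross-hybridization (MM carries no signal),
array-spatial artifacts, intermediate termination sites between a
terminator and the downstream poly(A) site, and transcript-isoform
complexity beyond the effects listed.  Passing recovery tests therefore
demonstrates correctness of the statistics and plumbing under the
modeled effects, not robustness to every failure mode of real arrays.

## Numerical and scale choices

* Problem sizes: the bundled scenarios (40k probes, 14 arrays; 12k-probe
  null) keep a full end-to-end analysis and its test suite to minutes on
  one CPU while leaving every window with ≥ 40 pooled values in the
  interior — the same per-window sample size a 2.5M-probe genome would
  give.
* Windows all-zero on the linear scale short-circuit to p = 1, s = 0
  (RNA level 0), which also makes background regions cheap.
* Coordinates are 0-based half-open internally; GFF3 I/O is 1-based
  inclusive, BED/bedGraph 0-based half-open.  Reversed interval bounds in
  inputs are normalized with a logged warning (published mask coordinates
  for one plasmid region are printed high→low, so such input exists in
  the wild).
* Track writers emit 6-decimal fixed-format values; manifests record
  SHA-256 checksums of every input and output, and a rerun under a fixed
  config and seed is byte-identical.
* Floating-point NaN marks missing/masked track values everywhere;
  undefined readthrough ratios (zero body signal) are recorded as
  `undefined`, never raised.

## Known limitations

* Gene-level fold changes inherit the compression/offset behaviour of
  rank-based joint normalization when net transcript mass shifts; the
  pipeline detects such shifts qualitatively but cannot quantify them
  without a spike-in standard.
* The readthrough ratio conflates diminished body signal with elevated
  downstream signal by construction; the `body-decrease` note flags the
  cases, but resolving them needs orthogonal data.
* The attenuation screen encodes necessary sequence features, not
  sufficient ones; its output is a candidate list for inspection, not a
  classifier.
* Exact signed-rank p-values are conditional on the observed tie/zero
  pattern; with heavy ties and tiny windows the test is conservative.
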