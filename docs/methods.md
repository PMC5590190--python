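# Methods

This note documents the models behind `panelval`, the defaults that
matter, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want to know about.

## Evidence model

Read-level sequencing data are abstracted to count records. For small
variants the unit of evidence is a stranded tumor/normal pileup at one
site: alt and ref read counts split by strand, plus matched-normal alt
count and depth. The calling rules the package implements operate on
counts, depths and pair geometry, so nothing is lost by skipping
FASTQ/BAM realism — with the one exception of rearrangements, where
per-read records (position, strand, aligned length, soft-clip lengths)
are retained because clip boundaries carry the breakpoint information.
Indels use the same count model as SNVs; local-assembly realism
(how an aligner resolves an indel into counts) is out of scope.

## SNV/indel filter cascade

A candidate site passes iff all of the following hold:

* depth ≥ `min_depth` (30 reads) — a site with 29 reads fails, 30 passes;
* matched-normal alt fraction ≤ `max_normal_maf` (0.03) — the stated
  maximum is itself allowed; the filter is skipped when no normal reads
  are available;
* forward-strand fraction of alt reads within
  [`strand_bias_low`, `strand_bias_high`] = [0.1, 0.9], evaluated only
  when ≥ 2 alt reads exist (a single read is always at 0 or 1, which
  would make the filter fire on every singleton);
* observed MAF strictly greater than `maf_min` (1%), relaxed to
  `maf_min_hotspot` (0.5%) at catalogued hotspot sites — a MAF of
  exactly 1% is filtered;
* indels flagged as lying in repeat tracts additionally need MAF ≥
  `repeat_maf_min` (2%) and ≥ `repeat_min_alt` (8) supporting reads.
  These two numbers quantify an otherwise qualitative "raised
  requirement at repeats" and are deliberately configurable.

Threshold comparisons are done on exact rationals (`Fraction(alt,
depth)` against `Fraction("0.01")`), never on formatted decimals, so
boundary behavior is independent of depth and float representation.
Hotspot matching requires exact (chrom, pos, ref, alt) identity by
default; positional-only matching is available.

The beta-binomial posterior — allele fraction prior Beta(1, 99), or
Beta(5, 95) at hotspots, posterior tail beyond the background error
rate (default 1%) — is advisory: it is reported in the VCF INFO field
but is not a gate, because the reproducible, documented gates are the
threshold rules above. It is monotone in alt count at fixed depth and
the hotspot prior can only raise it.

## Coverage, GC and copy number

Tumor counts per target are Poisson with mean
`depth · (p·CN_t + 2(1−p))/2 · w(gc)` where `p` is tumor purity, `CN_t`
the tumor copy number and `w` a unimodal capture-efficiency weight
(default `1 − 2(gc − 0.5)²`, peaking at GC 0.5); the matched normal uses
CN 2 under the same weight. The log2 ratio per bin is library-size
normalized: `log2((t/T)/(n/N))`. Bins with zero tumor or normal counts
are masked, never imputed.

Because `T` includes reads from amplified targets, the copy-neutral
level of the raw profile is offset below zero whenever amplifications
are present. GC correction therefore starts by estimating the neutral
center as the global median log2 ratio (valid when most of the panel is
copy-neutral — the key assumption of this module), takes bins within
±0.3 of that center as putatively neutral, and subtracts per GC stratum
(20 equal-width strata) the median log2 ratio of its neutral bins;
strata with fewer than 5 neutral bins fall back to the global neutral
median. After correction the neutral level sits at zero and the mixing
identity `E[mean log2] = log2((p·CN_t + 2(1−p))/2)` holds, which the
test suite checks by Monte Carlo.

Segmentation is an agglomerative merge guided by the Bayesian
information criterion under a Gaussian model with **known** noise
variance: `BIC = RSS/σ² + λ·k·log n` for k segments over n bins, with σ
estimated robustly as the median absolute within-chromosome
first difference scaled for normality (true breakpoints are too few to
drag a median). Starting from one segment per bin, the adjacent
within-chromosome pair with the smallest RSS increase (leftmost on
ties) is merged while that increase stays below `λ·σ²·log n`; λ
defaults to 2. The unknown-variance form `n·log(RSS/n)` is degenerate
at the all-singleton start (RSS = 0 drives it to −∞, so no first merge
is ever accepted); fixing the variance from the data removes the
degeneracy while keeping the same penalty structure. The procedure is
deterministic, never crosses chromosomes, recovers a noiseless step
exactly, and is idempotent on piecewise-constant input.

A segment is called amplified when **both**

* the purity-corrected copy number
  `CN_t = (2·2^m − 2(1−p))/p ≥ cn_threshold` (default 3, i.e. at least
  one extra copy after correcting for dilution), and
* the raw segment mean `m ≥ min_log2` (default 0.5).

The second condition is the detection floor: purity correction can
inflate arbitrarily small ratio shifts at low purity, so a diluted
signal that no longer stands out of coverage noise must not be called.
It is this floor that makes a modest 4-copy gain fade out of reach as
purity drops (expected ratio log2(1.2) ≈ 0.26 at 20% purity) while
10-copy amplifications remain callable. No positivity criterion is
inherited from elsewhere; both numbers are package defaults chosen from
the noiseless geometry of the dilution fixture and exposed in config.

## Rearrangements

A soft-clip of ≥ `min_clip` (10 bp) marks a breakpoint at the clip
boundary (read start for a left clip, aligned end for a right clip);
the mate's junction-proximal coordinate approximates the partner side.
A pair is discordant iff its mates map to different chromosomes, their
outer span (leftmost start to rightmost aligned end) exceeds 2 kb, or
they align in the same direction. The span rule uses outer distance
because the published rule gives only "over 2 kb" without an anchor
point. Whether same-direction/discordant candidates are "filtered" in
or out is ambiguous in the source description; they are **kept**,
consistent with the following sentence's "kept for fusion detection",
and this reading is flagged here deliberately.

Evidence sharing side chromosomes and orientations is clustered by
single linkage with a 50 bp window per side (evidence processed in
sorted order, cluster coordinates are per-side medians). Geometry
determines the class: different chromosomes → translocation; same
chromosome, same-direction junction → inversion; forward junction
(left side `+`, right side `-`) → long deletion (only > 2 kb spans
reach this stage); reversed junction → tandem duplication. A cluster
with both sides outside the baited panel is dropped; an event passes
with ≥ 3 split reads or ≥ 5 discordant pairs. The support thresholds
and window are not derived from any published value and are
config-exposed.

## Validation experiments

*Sensitivity vs depth.* Full-depth pileups are thinned to each grid
depth by hypergeometric draws (alt vs ref, then forward vs reverse
within each class), which preserves the expected MAF exactly; the
cascade is re-run and detection fractions are binned by **true** MAF
((0, 0.10], (0.10, 0.20), [0.20, 1] — edge handling is a package
decision). Averages and s.e.m. are taken across replicates (default
10). The plateau depth is the smallest grid depth within ε = 0.002 of
the curve's maximum.

*Dilution LOD.* For each purity in {0.5, 0.4, 0.3, 0.2, 0.1} coverage
is simulated and the full CNV pipeline re-run; a gene is detected when
an amplified segment overlaps one of its bins, and its LOD is the
lowest purity still detected. The bundled fixture sets
CCND1/FGF3/FGF4/FGF19 to 10 copies and AKT1 to 4: true HCC1143-like
copy numbers are not published, so AKT1 is given the lowest amplified
CN to make it the first to fall below detection — a modeling choice
that reproduces the qualitative ordering, not a measured value.

*Concordance.* Standard 2×2 statistics with exact fractions alongside
floats. `paper_mode` reports PPV under the label "specificity", the
convention used when every compared sample is sequencing-positive and
no true negatives exist.

## Synthetic data: what it does and does not emulate

The generator reproduces the statistical structure of a validation
experiment: MAF spectra (germline pools uniform over pooled-heterozygote
fractions k/20, 5–100%; cell-line pools truncated Beta(1.2, 12) on
[0.01, 1], placing ≈97.5% of mass below MAF 0.30), Poisson depth,
binomial allele sampling, binomial strand split (symmetric by default,
with a bias knob to exercise the strand filter), purity mixing, smooth
GC bias, and junction-spanning read-pair geometry. It does **not**
emulate base-quality error profiles, PCR duplicates, mappability,
FFPE artifacts, alignment ambiguity at indels, or subclonal structure
beyond a single MAF per site. Passing tests therefore demonstrate that
the callers implement their rules correctly and behave as expected
under the stated sampling models — not that the thresholds would
achieve the same operating characteristics on real FFPE libraries.

Default study conditions: depth 500× for SNV work (400× for the indel
experiment, 800× for coverage work, consistent with panels sequenced
near the 800× mark), background error rate 0.001, purity grid 0.5→0.1.
Problem sizes in the test suite and acceptance script (e.g. 719 / 1653
/ 1365 sites for the titration experiments, 260-bin coverage panel,
≤ 10⁴ Monte-Carlo draws) are the package's chosen working scale.

## Determinism

Every generator takes an explicit seed or `numpy` Generator; the
pipeline derives per-stage child seeds from one top-level seed via
`SeedSequence`, records them in the run manifest, and produces
byte-identical outputs across runs. Per-gene GC assignments in the toy
panels hash gene names with CRC-32 rather than Python's randomized
`hash()`.

## Known limitations

* The CNV module calls amplifications only; deletions/LOH and
  allele-specific copy number are out of scope.
* Breakpoints are cluster medians, not base-pair-exact junction
  sequences (no split-read realignment).
* The beta-binomial prior is a plain surrogate for a tissue-aware
  somatic prior; its parameters are placeholders, which is why it is
  not a gate.
* The GC correction assumes a mostly copy-neutral panel; a panel
  dominated by amplified targets would mis-center the profile.
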