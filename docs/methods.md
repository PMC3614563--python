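# Methods

This note documents the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would otherwise have to reverse-engineer.

## Study design and data model

The package targets the matched single-patient design: one blood sample (pure
germline) and k tumor samples ordered biologically (primary, metastasis,
recurrence). All inputs are post-alignment summaries — per-sample variant
tables (VCF or TSV) carrying depth, alternate-read count, Phred quality,
variant class, a coding/splice flag and a known-variant flag, and a per-exon
read-count matrix with per-sample total mapped reads. Alignment, duplicate
marking, raw calling and functional annotation are upstream concerns consumed
as columns, not re-implemented.

Coordinate conventions live in one module (`io_formats`): BED exon intervals
are 0-based half-open, variant positions 1-based; a variant at position p is
inside exon [s, e) iff s < p ≤ e. Every writer/reader pair round-trips
exactly (floats are serialized with `%.17g` and parsed in round-trip mode).

## Somatic variant selection

Quality thresholds are inclusive: Phred ≥ 20 for SNVs, ≥ 50 for indels
(indel calls from short-read pileups carry far more artifacts, hence the
stricter bound), depth ≥ 3. The alternate-support rule (≥ 3 alt reads and
≥ 10% of coverage) applies by default only to the primary tumor — the sample
where low-fraction calls are least reliable because of normal-tissue dilution
— and is configurable to any sample set. Depth is interpreted as total site
coverage, not alt reads, for samples outside the alt-support set.

Rarity filtering keeps functional variants whose key is absent from a
user-supplied blacklist of chrom:pos:ref:alt keys standing in for dbSNP,
1000 Genomes and unrelated control exomes; no live database queries.

Blood subtraction is deliberately aggressive: any blood record with ≥ 1
supporting read excludes the variant everywhere (override:
`min_blood_reads`). Experience with cross-tumor "unique" calls is that they
show low-level support in the other samples on inspection; a conservative
subtraction costs little sensitivity for clonal mutations.

All three filters are pure per-record (or per-key) predicates, so they are
idempotent and commute — property-tested, and convenient because stage order
becomes a presentation choice.

## Allele-frequency dynamics

Exome AF is alt reads / depth (missing at zero depth, never an exception).
Sanger chromatograms give an allele *proportion* r = alt peak / ref peak;
f = r/(1+r) maps it to a frequency comparable with exome AF. The map is
strictly increasing, with exact inverse r = f/(1−f) (round trip checked to
1e−12).

Rising-variant selection compares the primary AF with the maximum over later
samples. The default is a *relative* rise of ≥ 10% (f_later ≥ 1.1·f_primary):
on the packaged validation set the absolute reading would exclude a validated
riser at 0.17 → 0.21, so relative is the only self-consistent default; both
modes are exposed.

Concordance pools one (exome, Sanger) pair per variant per tumor sample,
drops incomplete pairs, and computes Spearman's ρ with average ranks
(duplicated AF values are common at two decimals) and the t-approximation
p-value; a per-sample stratified report is also available. On the packaged
24-mutation validation table this gives ρ = 0.783 over 66 pairs.

Purity: for clonal heterozygous somatic variants in copy-neutral regions,
E[AF] = π/2, so π̂ = 2·median(AF), clipped to [0, 1]. The median resists the
few variants that actually sit in undetected CNVs; the pipeline feeds only
variants outside its own CNV calls. With 20 variants at ~150× this recovers
π to about ±0.03.

## Copy-number detection

Per-exon counts are normalized to RPKM; the tumor/blood log₂ RPKM ratio is
the segmentation signal. Exons with blood count < 10 are masked rather than
zero-filled — the ratio denominator is too unstable there (threshold
configurable).

The per-exon test models the library-scaled counts as normal with Poisson
variances and applies the Geary–Hinkley transformation for ratios of normal
variables: with R the observed library-scaled ratio, s the library-size
ratio, t = √n_b (R − 1)/√(R² + 1/s). t = 0 exactly at R = 1, sign flips under
R → 1/R, and |t| grows monotonically with the deviation. The two-sided tail
2(1 − Φ(|t|)) is used; the transformation's defining property — approximate
standard normality under the null — is verified by simulation (empirical
P(X/Y ≤ r) matches Φ(t) for normal X, Y, and the null rejection rate at 150×
is 0.046–0.049 at nominal 0.05, slightly anticonservative as expected of the
normal approximation to Poisson).

Segmentation is a from-scratch CBS-style recursive splitter. For a segment of
n exons the candidate split is the arc (i, j] maximizing
|Z| = |Q_j − Q_i|·√(n/(k(n−k)))/σ, where Q is the mean-centered prefix sum,
k = j − i, and σ the segment's sample standard deviation — algebraically the
usual two-sample mean-shift statistic, computed in one vectorized pass per
arc width. Split significance is a permutation test (default 1000
permutations, seeded): the split is accepted when (hits+1)/(N+1) < α with
α = 0.01. Two pure optimizations keep this fast without changing any
decision: the permutation loop stops as soon as the exceedance count already
implies p > α, and each permutation scan prunes arc widths whose upper bound
(max Q − min Q)·c(k) cannot reach the observed maximum. Accepted splits
recurse on the three resulting pieces; minimum arc width is 3 exons.

Smoothing merges adjacent same-chromosome segments whose means share a sign
and differ by ≤ 0.2 (exon-count-weighted mean; large lesions are often split
by stretches without exonic data), then drops segments with < 100 exons or
|mean| < 0.1. The 100-exon floor encodes the policy of trusting exome depth
only for large rearrangements; the 0.1 call threshold keeps low-purity
primary-tumor signals (attenuated to |log₂ ratio| ≈ 0.13–0.4) callable while
rejecting baseline wobble. All three are configuration.

Segment significance is Fisher's method over member exons,
X = −2Σln pᵢ ~ χ²(2k); for real lesions X is enormous and the tail
underflows — it is reported as 1e−300, never 0. Input p-values are validated
to lie in (0, 1], which the per-exon test guarantees by construction.

## Synthetic cohorts

The generator emulates: a shared lognormal per-exon capture effect
(σ = 0.3 by default) multiplying Poisson sequencing noise — shared between
samples, which is exactly why the tumor/blood ratio works and why the ratio
test stays calibrated regardless of capture variability; mean exon depths of
174× (blood) and 130/162/146× (tumors), matching deep-exome practice;
tumor-shared copy-number lesions whose depth effect and somatic/germline AFs
follow the one-clone purity algebra above, including loss of heterozygosity
with the lost allele chosen per variant; and simulated Sanger peak heights
with Gaussian frequency noise (σ = 0.06).

Default purities are 0.40 (primary), 0.85 (metastasis), 0.90 (recurrence):
the primary dilute, the later samples pure, which reproduces the
characteristic pattern of jointly rising AFs and magnified CNV log ratios
(a CN=1 loss shows ≈ −0.32 at π = 0.4 versus ≈ −0.80 at π = 0.85). These are
configuration, not estimates.

`mean_depth` is the expected read count per exon; for ~100 bp reads on
~200 bp exons this is on the same scale as per-base coverage, and only
ratios matter downstream. Library totals are set at 250 000 mapped reads per
1× mean depth.

Not emulated (so passing tests do not speak to): GC-dependent bias that
differs *between* samples, mappability artifacts, FFPE damage, sequencing
error (no false-positive raw calls), subclonal structure (one clone per
tumor — appropriate for cohorts where no new mutations arise between
samples), and focal CNVs below the 100-exon floor.

## Numerical choices and degenerate inputs

* Per-exon p-values and Fisher tails are floored at 1e−300.
* Zero depth yields a missing AF; empty purity input yields no estimate.
* A flat or constant segment (σ = 0) never splits; an empty chromosome
  yields no segments and no error.
* Segment partition before smoothing is exhaustive and non-overlapping over
  unmasked exons (property-tested).
* One global pipeline seed fans out to per-stage child seeds through
  `numpy.random.SeedSequence.spawn`, all below 2³¹; identical config + seed
  reproduces every output file byte for byte, and the config hash recorded
  in the run report makes accidental config drift visible.

## Problem sizes used in the test and acceptance suites

Calibration and closed-form recovery use 10⁴-exon cohorts at 150×; segment
recovery uses ten 2 400-exon cohorts (three chromosomes, one 360-exon
deletion, one 350-exon amplification at π = 0.85) plus 2 000-exon null
cohorts; purity recovery uses 20 copy-neutral somatic variants per purity
level. These sizes put Monte-Carlo noise well inside the stated tolerances
(e.g. the standard error of a 10⁴-exon mean log ratio is ≈ 0.002 against a
±0.02 tolerance) while keeping the whole suite interactive.

## Known limitations

* The CNV caller reports total copy-number changes only: no allele-specific
  copy number, no breakpoint refinement beyond exon boundaries, no
  LOH calling from the depth channel (LOH is visible in the AF channel).
* The Geary–Hinkley normal approximation degrades at low counts; the blood
  mask (default < 10 reads) is the guard, and heavily overdispersed data
  would need a larger mask or an explicit overdispersion term.
* π̂ = 2·median(AF) assumes clonal heterozygous variants in diploid regions;
  subclonal mutations bias it downward.
* The permutation splitter is quadratic per segment in the worst case;
  chromosome tracks far beyond ~10⁴ unmasked exons would benefit from a
  windowed scan.
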