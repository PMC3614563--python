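# trioexome

Matched tumor–normal exome analysis for single-patient, multi-sample cancer
studies: one blood (germline) sample plus several tumor samples from the same
patient — typically a primary tumor, a metastasis, and a recurrence after
therapy. From per-sample variant calls and per-exon read counts, the package

* selects **somatic mutations** by quality control, rarity filtering and
  subtraction of every variant seen in the blood;
* tracks **mutant allele frequency (AF) trajectories** across the ordered
  tumors, converts Sanger chromatogram peak heights to comparable
  frequencies, selects variants whose AF rises, and quantifies
  exome-vs-Sanger concordance;
* estimates **tumor purity** from copy-neutral somatic AFs;
* calls **large copy-number variants** from tumor/blood read-depth ratios;
* and ships a **synthetic cohort generator** with known ground truth, so every
  stage has a parameter-recovery test without access to patient data.

It is a library first (`import trioexome`), with narrative scripts under
`examples/` and a thin `trioexome` CLI (`simulate`, `filter`, `somatic`,
`track`, `cnv`, `run`) for shell use.

## The model

**Somatic filtering.** A call passes quality control when its Phred quality is
≥ 20 (SNV) or ≥ 50 (indel) and depth ≥ 3; in the primary tumor the alternate
allele must additionally be supported by ≥ 3 reads making up ≥ 10% of
coverage. Functional (coding or canonical-splice) variants absent from
population/control blacklists are kept; a variant is somatic when its
(chrom, pos, ref, alt) key never appears in the blood sample.

**Purity algebra.** With tumor purity π (malignant-cell fraction) and local
copy number c, a segment's expected depth ratio against the diploid blood is
((1−π)·2 + π·c)/2, so its log₂ ratio is log₂(2(1−π) + πc) − 1; a clonal
somatic variant with m alternate copies per tumor cell has expected
AF = πm / (πc + 2(1−π)) — π/2 in diploid regions, π/(2−π) on the retained
allele of a one-copy loss. Purity is estimated as π̂ = 2·median(AF) over
copy-neutral somatic variants. A parallel rise of *all* AFs across samples is
the signature of increasing purity, not of per-variant selection.

**Per-exon ratio test.** Counts are normalized to RPKM (reads per kilobase of
exon model per million mapped reads) and the exon statistic is the
Geary–Hinkley transform of the tumor/blood ratio R:
t = √n_b (R − 1) / √(R² + 1/s), with n_b the blood count and s the library
size ratio; t is approximately standard normal under no copy-number change,
giving a two-sided p = 2(1 − Φ(|t|)) per exon.

**Segmentation and calling.** Per chromosome, a circular-binary-segmentation
style splitter recursively finds the boundary pair maximizing the two-sample
mean-shift statistic on log ratios, accepting splits by a seeded permutation
test (α = 0.01). Adjacent same-sign segments with similar means are merged;
segments with < 100 exons or |mean log₂ ratio| < 0.1 are dropped — only large
lesions are trusted from exome depth. Member exon p-values combine by
Fisher's method, −2Σln pᵢ ~ χ²(2k).

**Sanger conversion.** A chromatogram's allele proportion r = alt peak / ref
peak converts to frequency f = r/(1+r), the algebraic inverse of r = f/(1−f).

## Worked example

Calling planted lesions in a simulated tumor at 85% purity
(`python examples/04_cnv_calling.py`):

```
sample chrom  start    end  n_exons  mean_log_ratio    combined_p call
 tumor  chr1 200000 559200      360       -0.806019 1.000000e-300  del
 tumor  chr2 150000 499200      350        0.513770 1.000000e-300  amp

expected mean log2 ratio at purity 0.85:
  CN=1 deletion:      -0.798
  CN=3 amplification: +0.511
```

Both planted lesions are recovered at exon resolution with mean log ratios
matching the closed-form purity-attenuated expectations; the Fisher-combined
p-values underflow (reported as 1e-300) because hundreds of exons deviate in
the same direction.

Concordance on the packaged validated-mutation set
(`python examples/03_allele_trajectories.py`):

```
pooled exome-vs-Sanger Spearman rho = 0.78 (p = 8.37e-15, n = 66 pairs)
```

The two technologies rank mutant AFs almost identically across the three
tumors, so rising trajectories reflect real frequency changes rather than
exome measurement noise.

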