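"""Generate a synthetic matched cohort and inspect its ground truth.

The cohort mimics a single-patient design: blood plus primary (OV), metastatic
(OMN) and recurrent (REC) tumor samples that share one large deletion, one
amplification and a set of clonal somatic SNVs, but differ in tumor purity.
"""

from trioexome import SimulationConfig, simulate_cohort

config = SimulationConfig(seed=7)
model, coverage, variants, truth = simulate_cohort(config)

print(f"exons: {len(model)}, variant records: {len(variants)}")
for sample in config.sample_names:
    print(f"  mean depth {sample}: {coverage.column(sample).mean():.1f} "
          f"(configured {config.mean_depth[sample]:.0f})")

print("\nplanted copy-number lesions and their expected log2 depth ratios:")
print(truth.segments[["chrom", "copy_number", "log_ratio_OV", "log_ratio_OMN",
                      "log_ratio_REC"]].to_string(index=False))

somatic = truth.variants[~truth.variants["germline"]]
print("\nexpected somatic allele fractions (first 3 variants):")
print(somatic[["chrom", "pos", "af_OV", "af_OMN", "af_REC"]].head(3).to_string(index=False))
print("\nAFs rise with purity (0.40 -> 0.85 -> 0.90): the same clone, sampled "
      "with less and less normal-tissue dilution.")
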