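"""Somatic variant selection: quality control, rarity filter, blood subtraction.

Prints per-stage record counts; the somatic keys recovered at the end are
compared against the generator's ground truth.
"""

from trioexome import (
    QualityCriteria,
    SimulationConfig,
    apply_quality_filters,
    call_somatic,
    filter_functional_rare,
    simulate_cohort,
)

_, _, variants, truth = simulate_cohort(SimulationConfig(seed=3))

# the alternate-read-support rule (>=3 reads and >=10% of coverage) applies to
# the primary tumor only, as in the reference analysis
criteria = QualityCriteria(alt_support_samples=("OV",))
quality = apply_quality_filters(variants, criteria)
rare = filter_functional_rare(quality)  # functional & never seen in controls

blood = [v for v in rare if v.sample == "blood"]
tumors = [v for v in rare if v.sample != "blood"]
calls = call_somatic(tumors, blood)

print(f"raw records:              {len(variants)}")
print(f"after quality filters:    {len(quality)}")
print(f"after rare/functional:    {len(rare)}")
print(f"somatic per sample:       {calls.counts()}")
print(f"somatic keys recovered:   {len(calls.union_keys)} "
      f"(planted: {len(truth.somatic_keys)})")
print(f"exact truth recovery:     {calls.union_keys == truth.somatic_keys}")
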