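import pytest

from trioexome import (
    SimulationConfig,
    SomaticVariantSpec,
    TruthSegment,
    VariantRecord,
    simulate_cohort,
)


def make_variant(
    chrom="chr1",
    pos=1000,
    ref="A",
    alt="T",
    sample="OV",
    depth=100,
    alt_reads=30,
    qual=60.0,
    var_class="snv",
    functional=True,
    known=False,
):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, sample=sample, depth=depth,
        alt_reads=alt_reads, qual=qual, var_class=var_class,
        functional=functional, known=known,
    )


def small_config(**overrides):
    """A reduced matched cohort: 4 chromosomes x 500 exons, one deletion and
    one amplification, 30 germline heterozygotes, 12 clonal somatic SNVs."""
    somatic = [SomaticVariantSpec("chr3", 30 + 40 * i) for i in range(8)]
    somatic += [
        SomaticVariantSpec("chr1", 200),
        SomaticVariantSpec("chr1", 250),
        SomaticVariantSpec("chr2", 150),
        SomaticVariantSpec("chr4", 100),
    ]
    defaults = dict(
        n_exons=2000,
        n_chromosomes=4,
        truth_segments=[
            TruthSegment("chr1", 150, 350, copy_number=1),
            TruthSegment("chr2", 100, 280, copy_number=3),
        ],
        germline_het_count=30,
        somatic_variants=somatic,
        seed=20240915,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    """(model, coverage, variants, truth) for the reduced default cohort."""
    return simulate_cohort(small_config())
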