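"""Synthetic matched blood + multi-tumor exome cohorts with known ground truth.

The generator emulates a single-patient study design: one blood (pure normal)
sample and several tumor samples (primary, metastasis, recurrence) that share
the same clonal copy-number lesions and somatic variants but differ in tumor
purity. Read counts follow a shared lognormal per-exon capture effect times
Poisson sequencing noise; the capture effect is shared between samples, which
is exactly why tumor/blood depth ratios are informative about copy number.

Purity algebra (one clone per tumor, no subclonal structure):

* a copy-number-``c`` segment at purity ``pi`` has expected depth factor
  ``((1 - pi) * 2 + pi * c) / 2``, hence expected log2 ratio
  ``log2(2(1 - pi) + pi * c) - 1``;
* a clonal somatic variant with ``m`` alternate copies per tumor cell has
  expected allele fraction ``pi * m / (pi * c + (1 - pi) * 2)`` (``pi / 2`` in
  diploid regions, ``pi / (2 - pi)`` on the retained allele of a one-copy loss);
* a germline heterozygote adds ``(1 - pi) * 1`` alternate copies from the
  normal-cell fraction, so loss of heterozygosity moves its AF toward 0 or 1
  depending on which parental allele the lesion removed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import CoverageMatrix, ExonModel, VariantRecord

__all__ = [
    "TruthSegment",
    "SomaticVariantSpec",
    "SimulationConfig",
    "TruthSet",
    "simulate_cohort",
    "make_null_cohort",
    "expected_log_ratio",
    "expected_allele_fraction",
]

_BASES = np.array(list("ACGT"))

#: Reads per sample scales with mean depth; ~250k on-target exome reads per 1x.
_READS_PER_DEPTH = 250_000


def expected_log_ratio(purity: float, copy_number: int) -> float:
    """Expected log2 tumor/blood depth ratio of a CN=``copy_number`` segment."""
    return float(np.log2((1.0 - purity) * 2.0 + purity * copy_number) - 1.0)


def expected_allele_fraction(
    purity: float, copy_number: int, alt_copies_tumor: int, germline: bool
) -> float:
    """Expected alternate-allele fraction under the one-clone mixture model."""
    normal_alt = 1.0 if germline else 0.0
    num = purity * alt_copies_tumor + (1.0 - purity) * normal_alt
    den = purity * copy_number + (1.0 - purity) * 2.0
    return float(num / den) if den > 0 else float("nan")


@dataclass(frozen=True)
class TruthSegment:
    """A planted copy-number lesion shared by all tumor samples.

    Exon indices are local to ``chrom`` and half-open: exons
    ``first_exon .. last_exon - 1`` carry ``copy_number`` copies per tumor cell.
    """

    chrom: str
    first_exon: int
    last_exon: int
    copy_number: int


@dataclass(frozen=True)
class SomaticVariantSpec:
    """A planted clonal somatic SNV, placed at the midpoint of one exon.

    ``on_retained_allele`` decides the variant's copy count inside a CNV:
    True puts it on the allele the lesion did not touch (1 copy); False puts
    it on the affected allele (0 copies after a loss, ``c - 1`` after a gain).
    ``present_in`` defaults to every tumor sample.
    """

    chrom: str
    exon: int
    present_in: tuple[str, ...] | None = None
    on_retained_allele: bool = True


def _alt_copies(copy_number: int, on_retained: bool) -> int:
    """Alternate-allele copies per tumor cell given the local lesion."""
    if copy_number == 0:
        return 0
    if copy_number == 2 or on_retained:
        return 1
    return max(copy_number - 1, 0)


def _default_truth_segments() -> list[TruthSegment]:
    return [
        TruthSegment("chr1", 400, 800, copy_number=1),
        TruthSegment("chr2", 300, 650, copy_number=3),
    ]


def _default_somatic() -> list[SomaticVariantSpec]:
    specs = [SomaticVariantSpec("chr3", 40 + 60 * i) for i in range(12)]
    specs += [SomaticVariantSpec("chr4", 70 + 55 * i) for i in range(8)]
    specs += [SomaticVariantSpec("chr1", 500), SomaticVariantSpec("chr1", 600)]
    specs += [SomaticVariantSpec("chr2", 400), SomaticVariantSpec("chr2", 500)]
    return specs


@dataclass
class SimulationConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults mirror the matched ovarian cohort the pipeline targets: blood at
    174x and tumors at 130/162/146x mean exon depth, purities 0.40 (primary),
    0.85 (metastasis), 0.90 (recurrence), one large single-copy deletion and
    one single-copy amplification, ~60 germline heterozygotes and 24 clonal
    somatic SNVs shared by all tumors.
    """

    n_exons: int = 6000
    n_chromosomes: int = 4
    exon_length_bp: int = 200
    exon_spacing_bp: int = 800
    sample_names: tuple[str, ...] = ("blood", "OV", "OMN", "REC")
    mean_depth: dict = field(
        default_factory=lambda: {"blood": 174.0, "OV": 130.0, "OMN": 162.0, "REC": 146.0}
    )
    purity: dict = field(default_factory=lambda: {"OV": 0.40, "OMN": 0.85, "REC": 0.90})
    truth_segments: list[TruthSegment] = field(default_factory=_default_truth_segments)
    germline_het_count: int = 60
    somatic_variants: list[SomaticVariantSpec] = field(default_factory=_default_somatic)
    overdispersion: float = 0.3
    germline_known_fraction: float = 0.9
    germline_loh_on_retained_prob: float = 0.5
    sanger_noise_sd: float = 0.06
    seed: int = 0

    @property
    def blood(self) -> str:
        return self.sample_names[0]

    @property
    def tumors(self) -> tuple[str, ...]:
        return self.sample_names[1:]

    def __post_init__(self) -> None:
        if self.n_exons < self.n_chromosomes or self.n_chromosomes < 1:
            raise ConfigError("need at least one exon per chromosome")
        for s in self.sample_names:
            if self.mean_depth.get(s, 0) <= 0:
                raise ConfigError(f"mean_depth for {s!r} must be positive")
        for t in self.tumors:
            pi = self.purity.get(t)
            if pi is None or not (0.0 <= pi <= 1.0):
                raise ConfigError(f"purity for {t!r} must lie in [0, 1]")
        sizes = self.chromosome_sizes()
        by_chrom: dict[str, list[TruthSegment]] = {}
        for seg in self.truth_segments:
            if seg.chrom not in sizes:
                raise ConfigError(f"truth segment on unknown chromosome {seg.chrom!r}")
            if not (0 <= seg.first_exon < seg.last_exon <= sizes[seg.chrom]):
                raise ConfigError(f"truth segment {seg} outside chromosome bounds")
            if seg.copy_number < 0:
                raise ConfigError("copy_number must be nonnegative")
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.first_exon)
            for a, b in zip(segs, segs[1:]):
                if b.first_exon < a.last_exon:
                    raise ConfigError(f"overlapping truth segments on {chrom}")
        for spec in self.somatic_variants:
            if spec.chrom not in sizes or not (0 <= spec.exon < sizes[spec.chrom]):
                raise ConfigError(f"somatic variant {spec} placed outside any exon")
            if spec.present_in is not None:
                unknown = set(spec.present_in) - set(self.tumors)
                if unknown:
                    raise ConfigError(f"somatic variant in unknown samples {sorted(unknown)}")

    def chromosome_sizes(self) -> dict[str, int]:
        base, extra = divmod(self.n_exons, self.n_chromosomes)
        return {
            f"chr{i + 1}": base + (1 if i < extra else 0)
            for i in range(self.n_chromosomes)
        }


@dataclass
class TruthSet:
    """Ground truth of one simulated cohort, for parameter-recovery tests.

    ``segments`` rows: chrom, first_exon, last_exon, copy_number, start_bp,
    end_bp, plus one ``log_ratio_<tumor>`` column per tumor with the expected
    log2 depth ratio. ``variants`` rows: key fields, germline flag, exon_id,
    plus ``af_<sample>`` expected allele-fraction columns. ``sanger`` holds
    simulated chromatogram peak heights for the somatic variants.
    """

    segments: pd.DataFrame
    variants: pd.DataFrame
    purities: dict
    sanger: pd.DataFrame | None = None

    @property
    def germline_keys(self) -> set[tuple[str, int, str, str]]:
        g = self.variants[self.variants["germline"]]
        return {(r.chrom, int(r.pos), r.ref, r.alt) for r in g.itertuples(index=False)}

    @property
    def somatic_keys(self) -> set[tuple[str, int, str, str]]:
        s = self.variants[~self.variants["germline"]]
        return {(r.chrom, int(r.pos), r.ref, r.alt) for r in s.itertuples(index=False)}


def _build_exon_model(config: SimulationConfig) -> ExonModel:
    rows = []
    for chrom, n in config.chromosome_sizes().items():
        span = config.exon_length_bp + config.exon_spacing_bp
        for i in range(n):
            start = i * span
            rows.append((chrom, start, start + config.exon_length_bp, f"{chrom}_e{i + 1}"))
    return ExonModel(pd.DataFrame(rows, columns=["chrom", "start", "end", "exon_id"]))


def _copy_numbers(config: SimulationConfig, model: ExonModel) -> np.ndarray:
    """Per-exon tumor copy number (shared by all tumor samples)."""
    cn = np.full(len(model), 2, dtype=np.int64)
    exons = model.exons
    for seg in config.truth_segments:
        on_chrom = np.flatnonzero((exons["chrom"] == seg.chrom).to_numpy())
        cn[on_chrom[seg.first_exon:seg.last_exon]] = seg.copy_number
    return cn


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExonModel, CoverageMatrix, list[VariantRecord], TruthSet]:
    """Draw one cohort: exon model, coverage matrix, called variants, ground truth.

    Fully reproducible from ``config.seed``; distinct seeds give distinct draws.
    """
    rng = np.random.default_rng(config.seed)
    model = _build_exon_model(config)
    n = len(model)
    cn = _copy_numbers(config, model)

    # Shared capture efficiency per exon: lognormal with mean 1.
    sigma = config.overdispersion
    capture = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n)) if sigma > 0 else np.ones(n)

    counts = np.empty((n, len(config.sample_names)), dtype=np.int64)
    totals: dict[str, int] = {}
    for j, sample in enumerate(config.sample_names):
        depth = config.mean_depth[sample]
        if sample == config.blood:
            factor = np.ones(n)
        else:
            pi = config.purity[sample]
            factor = ((1.0 - pi) * 2.0 + pi * cn) / 2.0
        counts[:, j] = rng.poisson(depth * capture * factor)
        totals[sample] = int(round(depth * _READS_PER_DEPTH))
    cov = CoverageMatrix(model, counts, list(config.sample_names), totals)

    exons = model.exons
    chrom_index = {
        chrom: np.flatnonzero((exons["chrom"] == chrom).to_numpy())
        for chrom in config.chromosome_sizes()
    }

    somatic_rows = [
        (chrom_index[s.chrom][s.exon], False, s.on_retained_allele,
         tuple(s.present_in) if s.present_in is not None else config.tumors)
        for s in config.somatic_variants
    ]
    taken = {row[0] for row in somatic_rows}
    free = np.setdiff1d(np.arange(n), np.fromiter(taken, dtype=np.int64, count=len(taken)))
    if config.germline_het_count > len(free):
        raise ConfigError("more germline heterozygotes requested than free exons")
    germ_idx = rng.choice(free, size=config.germline_het_count, replace=False)
    germ_retained = rng.random(config.germline_het_count) < config.germline_loh_on_retained_prob
    germ_known = rng.random(config.germline_het_count) < config.germline_known_fraction
    placements = somatic_rows + [
        (int(i), True, bool(r), config.sample_names) for i, r in zip(germ_idx, germ_retained)
    ]

    records: list[VariantRecord] = []
    truth_rows = []
    sanger_rows = []
    for v_idx, (exon_i, germline, on_retained, present_in) in enumerate(placements):
        row = exons.iloc[exon_i]
        pos = int(row["start"]) + (int(row["end"]) - int(row["start"])) // 2 + 1
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        known = bool(germ_known[v_idx - len(somatic_rows)]) if germline else False
        m = _alt_copies(int(cn[exon_i]), on_retained)
        af_by_sample: dict[str, float] = {}
        for sample in config.sample_names:
            if sample == config.blood:
                af = 0.5 if germline else 0.0
            else:
                pi = config.purity[sample]
                c = int(cn[exon_i])
                af = expected_allele_fraction(pi, c, m, germline)
            af_by_sample[sample] = af
            if sample != config.blood and sample not in present_in:
                continue
            depth = int(cov.column(sample)[exon_i])
            if depth == 0 or af == 0.0:
                continue
            alt_reads = int(rng.binomial(depth, af))
            if alt_reads == 0:
                continue
            records.append(
                VariantRecord(
                    chrom=str(row["chrom"]), pos=pos, ref=str(ref), alt=str(alt),
                    sample=sample, depth=depth, alt_reads=alt_reads, qual=99.0,
                    var_class="snv", functional=True, known=known,
                )
            )
        if not germline:
            for sample in present_in:
                observed = float(np.clip(
                    af_by_sample[sample] + rng.normal(0.0, config.sanger_noise_sd), 0.01, 0.99
                ))
                sanger_rows.append(
                    (f"{row['chrom']}:{pos}:{ref}:{alt}", sample,
                     round(1000 * (1 - observed)), round(1000 * observed))
                )
        truth_rows.append(
            {"chrom": str(row["chrom"]), "pos": pos, "ref": str(ref), "alt": str(alt),
             "germline": germline, "known": known, "exon_id": str(row["exon_id"]),
             "copy_number": int(cn[exon_i]), "on_retained_allele": on_retained,
             **{f"af_{s}": af_by_sample[s] for s in config.sample_names}}
        )

    seg_rows = []
    for seg in config.truth_segments:
        idx = chrom_index[seg.chrom][seg.first_exon:seg.last_exon]
        seg_rows.append(
            {"chrom": seg.chrom, "first_exon": seg.first_exon, "last_exon": seg.last_exon,
             "copy_number": seg.copy_number,
             "start_bp": int(exons["start"].iloc[idx[0]]), "end_bp": int(exons["end"].iloc[idx[-1]]),
             **{f"log_ratio_{t}": expected_log_ratio(config.purity[t], seg.copy_number)
                for t in config.tumors}}
        )
    truth = TruthSet(
        segments=pd.DataFrame(seg_rows),
        variants=pd.DataFrame(truth_rows),
        purities=dict(config.purity),
        sanger=pd.DataFrame(sanger_rows, columns=["variant_key", "sample", "peak_ref", "peak_alt"]),
    )
    return model, cov, records, truth


def make_null_cohort(
    n_exons: int,
    mean_depth: float = 150.0,
    seed: int = 0,
    overdispersion: float = 0.3,
    exon_length_bp: int = 200,
) -> CoverageMatrix:
    """Blood/tumor pair with identical per-exon rates: no CNV, purity irrelevant.

    Used to calibrate the per-exon ratio test: both columns are Poisson draws
    from the same lognormal-modulated rate, with equal library totals.
    """
    if n_exons < 1:
        raise ConfigError("n_exons must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [("chr1", i * 1000, i * 1000 + exon_length_bp, f"chr1_e{i + 1}") for i in range(n_exons)]
    model = ExonModel(pd.DataFrame(rows, columns=["chrom", "start", "end", "exon_id"]))
    capture = (
        np.exp(rng.normal(-0.5 * overdispersion**2, overdispersion, size=n_exons))
        if overdispersion > 0 else np.ones(n_exons)
    )
    rate = mean_depth * capture
    counts = np.column_stack([rng.poisson(rate), rng.poisson(rate)])
    total = int(round(mean_depth * _READS_PER_DEPTH))
    return CoverageMatrix(model, counts, ["blood", "tumor"], {"blood": total, "tumor": total})


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML/JSON mapping."""
    d = dict(d)
    if "truth_segments" in d:
        d["truth_segments"] = [
            TruthSegment(**s) if isinstance(s, dict) else TruthSegment(*s)
            for s in d["truth_segments"]
        ]
    if "somatic_variants" in d:
        d["somatic_variants"] = [
            SomaticVariantSpec(**s) if isinstance(s, dict) else SomaticVariantSpec(*s)
            for s in d["somatic_variants"]
        ]
    if "sample_names" in d:
        d["sample_names"] = tuple(d["sample_names"])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
    return SimulationConfig(**d)
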