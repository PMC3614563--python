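"""Allele-frequency dynamics across ordered tumor samples.

Tracks the mutant allele frequency (AF) of each somatic variant across an
ordered cohort (blood, primary tumor, metastasis, recurrence), converts Sanger
chromatogram peak heights to comparable frequencies, selects variants whose AF
rises along the trajectory, quantifies exome-vs-Sanger concordance, and turns
copy-neutral somatic AFs into a tumor-purity estimate.

AF definitions
--------------
* exome: alternate reads / total reads at the site;
* Sanger: the chromatogram gives an allele *proportion* r = alt peak height /
  ref peak height, converted to a frequency as f = 1 / (1 + 1/r) = r / (1 + r)
  (the algebraic inverse of r = f / (1 - f)).

For clonal somatic variants in copy-neutral regions AF ≈ pi/2 where pi is the
tumor purity, so pi is estimated as 2x the median copy-neutral somatic AF.
A parallel rise of all trajectories is therefore the signature of increasing
purity rather than of per-variant selection.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InsufficientDataError, ValidationError
from .io_formats import VariantRecord

__all__ = [
    "SangerTrace",
    "FrequencySeries",
    "ConcordanceResult",
    "PurityEstimate",
    "allele_frequency",
    "proportion_to_frequency",
    "build_frequency_series",
    "select_rising_variants",
    "concordance",
    "concordance_by_sample",
    "estimate_purity",
    "load_validation_cohort",
]


def allele_frequency(alt_reads: int, depth: int) -> float:
    """Alternate reads over total reads; NaN (missing) at zero depth."""
    if depth == 0:
        return float("nan")
    if not (0 <= alt_reads <= depth):
        raise ValidationError(f"alt_reads {alt_reads} outside [0, depth={depth}]")
    return alt_reads / depth


@dataclass(frozen=True)
class SangerTrace:
    """Chromatogram peak heights at one site in one sample."""

    peak_ref: float
    peak_alt: float

    def __post_init__(self) -> None:
        if self.peak_ref < 0 or self.peak_alt < 0:
            raise ValidationError("peak heights must be nonnegative")
        if self.peak_ref == 0 and self.peak_alt == 0:
            raise ValidationError("at least one peak must be nonzero")


def proportion_to_frequency(trace: SangerTrace) -> float:
    """Map the peak-height proportion r = alt/ref to a frequency r/(1+r).

    Strictly increasing in r, with limits 0 (no alt peak) and 1 (no ref peak).
    """
    if trace.peak_alt == 0:
        return 0.0
    if trace.peak_ref == 0:
        return 1.0
    r = trace.peak_alt / trace.peak_ref
    return r / (1.0 + r)


@dataclass
class FrequencySeries:
    """AF trajectory of one variant across the ordered cohort samples.

    ``af_exome`` / ``af_sanger`` map sample name to frequency; missing
    measurements are absent keys or NaN. Sample order is fixed cohort-wide.
    """

    key: str
    samples: tuple[str, ...]
    af_exome: dict = field(default_factory=dict)
    af_sanger: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for table in (self.af_exome, self.af_sanger):
            for s, f in table.items():
                if f is not None and not math.isnan(f) and not (0.0 <= f <= 1.0):
                    raise ValidationError(f"{self.key} {s}: frequency {f} outside [0, 1]")

    def exome(self, sample: str) -> float:
        v = self.af_exome.get(sample)
        return float("nan") if v is None else float(v)

    def sanger(self, sample: str) -> float:
        v = self.af_sanger.get(sample)
        return float("nan") if v is None else float(v)


def build_frequency_series(
    variants_by_sample: Mapping[str, Sequence[VariantRecord]],
    sample_order: Sequence[str],
    sanger: pd.DataFrame | None = None,
) -> list[FrequencySeries]:
    """Assemble per-variant trajectories from per-sample somatic variant lists.

    ``sanger``, if given, is a table with columns ``variant_key, sample`` and
    either ``peak_ref, peak_alt`` (converted here) or a direct ``af`` column.
    """
    order = tuple(sample_order)
    series: dict[str, FrequencySeries] = {}
    for sample in order:
        for v in variants_by_sample.get(sample, []):
            key = f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}"
            fs = series.setdefault(key, FrequencySeries(key, order))
            fs.af_exome[sample] = allele_frequency(v.alt_reads, v.depth)
    if sanger is not None and len(sanger):
        direct = "af" in sanger.columns
        for row in sanger.itertuples(index=False):
            fs = series.get(row.variant_key)
            if fs is None:
                fs = series.setdefault(row.variant_key, FrequencySeries(row.variant_key, order))
            f = float(row.af) if direct else proportion_to_frequency(
                SangerTrace(float(row.peak_ref), float(row.peak_alt))
            )
            fs.af_sanger[row.sample] = f
    return list(series.values())


def select_rising_variants(
    series: Iterable[FrequencySeries],
    threshold: float = 0.10,
    mode: str = "relative",
    baseline: str = "OV",
    later: Sequence[str] = ("OMN", "REC"),
) -> list[FrequencySeries]:
    """Variants whose exome AF rises from the primary to a later tumor.

    ``relative`` keeps a series when max AF over ``later`` >= baseline AF x
    (1 + threshold); ``absolute`` when it exceeds baseline + threshold.
    Missing later samples are ignored; a series with no later measurement is
    never selected. Relative is the default: a 10% relative rise is the
    reading consistent with validated low-AF risers like 0.17 -> 0.21.
    """
    if threshold < 0:
        raise ConfigError("threshold must be nonnegative")
    if mode not in ("relative", "absolute"):
        raise ConfigError(f"mode must be relative or absolute, got {mode!r}")
    selected = []
    for fs in series:
        base = fs.exome(baseline)
        laters = [fs.exome(s) for s in later]
        laters = [x for x in laters if not math.isnan(x)]
        if math.isnan(base) or not laters:
            continue
        peak = max(laters)
        cut = base * (1.0 + threshold) if mode == "relative" else base + threshold
        if peak >= cut:
            selected.append(fs)
    return selected


@dataclass(frozen=True)
class ConcordanceResult:
    """Spearman rank correlation between paired exome and Sanger frequencies."""

    rho: float
    p_value: float
    n_pairs: int


def _paired(series: Iterable[FrequencySeries], samples: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for fs in series:
        for s in samples:
            a, b = fs.exome(s), fs.sanger(s)
            if not math.isnan(a) and not math.isnan(b):
                xs.append(a)
                ys.append(b)
    return np.asarray(xs), np.asarray(ys)


def concordance(
    series: Iterable[FrequencySeries], samples: Sequence[str] = ("OV", "OMN", "REC")
) -> ConcordanceResult:
    """Pool (exome, Sanger) AF pairs over all variants and tumor samples.

    Each (variant, sample) pair with both measurements is one observation;
    ties get average ranks, the p-value uses the t approximation.
    """
    x, y = _paired(series, samples)
    if len(x) < 3:
        raise InsufficientDataError(f"need >= 3 complete pairs, have {len(x)}")
    rho, p = stats.spearmanr(x, y)
    return ConcordanceResult(rho=float(rho), p_value=float(p), n_pairs=len(x))


def concordance_by_sample(
    series: Sequence[FrequencySeries], samples: Sequence[str] = ("OV", "OMN", "REC")
) -> dict[str, ConcordanceResult]:
    """Per-sample stratified concordance (samples with < 3 pairs are skipped)."""
    out = {}
    for s in samples:
        try:
            out[s] = concordance(series, samples=(s,))
        except InsufficientDataError:
            continue
    return out


@dataclass(frozen=True)
class PurityEstimate:
    """Tumor-cell fraction inferred from copy-neutral clonal somatic AFs."""

    sample: str
    pi_hat: float
    n_variants: int
    method: str = "2x-median-AF"


def estimate_purity(
    copy_neutral_afs: Sequence[float], sample: str
) -> PurityEstimate | None:
    """pi_hat = 2 x median AF of copy-neutral clonal somatic variants, clipped to [0, 1].

    Assumes one clone per tumor and heterozygous variants in diploid regions
    (expected AF pi/2). Returns None when no usable AF is supplied.
    """
    afs = [a for a in copy_neutral_afs if not math.isnan(a)]
    if not afs:
        return None
    pi = float(np.clip(2.0 * np.median(afs), 0.0, 1.0))
    return PurityEstimate(sample=sample, pi_hat=pi, n_variants=len(afs))


def load_validation_cohort() -> list[FrequencySeries]:
    """The packaged Sanger-validated somatic mutation set of the reference cohort.

    24 validated somatic mutations from one matched ovarian-carcinoma cohort
    (primary OV, omental metastasis OMN, recurrence REC), with mutant AF
    measured both by exome sequencing and by Sanger peak heights; Sanger
    values are missing (NA) for two frameshift indels.
    """
    with importlib.resources.files("trioexome.data").joinpath(
        "validated_somatic_af.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        fs = FrequencySeries(key=f"{row.position}:{row.gene}", samples=("OV", "OMN", "REC"))
        for s in ("OV", "OMN", "REC"):
            e = getattr(row, f"af_exome_{s}")
            g = getattr(row, f"af_sanger_{s}")
            if not pd.isna(e):
                fs.af_exome[s] = float(e)
            if not pd.isna(g):
                fs.af_sanger[s] = float(g)
        out.append(fs)
    return out
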