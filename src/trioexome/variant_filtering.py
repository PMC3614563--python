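"""Somatic variant selection for matched tumor-normal exomes.

Three stages, each a pure function over :class:`~trioexome.io_formats.VariantRecord`
lists: (1) quality control on call quality, depth, and alternate-read support;
(2) restriction to functional (coding / canonical splice) variants absent from
population and control-exome blacklists; (3) somatic calling by subtracting
every variant seen in the matched blood sample. All stages are idempotent and
commute, so the chain order is a presentation choice, not a semantic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ConfigError
from .io_formats import VariantRecord

__all__ = [
    "QualityCriteria",
    "SomaticCalls",
    "apply_quality_filters",
    "filter_functional_rare",
    "call_somatic",
]

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class QualityCriteria:
    """Thresholds for the quality-control stage; all bounds are inclusive.

    SNVs need Phred quality >= ``min_qual_snv`` (20), indels >= ``min_qual_indel``
    (50); every call needs depth >= ``min_depth`` (3 reads). For samples listed
    in ``alt_support_samples`` — conventionally the primary tumor, where calls
    at low allele fraction are least trustworthy — the alternate allele must
    additionally be supported by >= ``min_alt_reads`` reads making up >=
    ``min_alt_fraction`` of coverage. Empty ``alt_support_samples`` disables
    that extra rule; the pipeline sets it to the primary tumor sample.
    """

    min_qual_snv: float = 20.0
    min_qual_indel: float = 50.0
    min_depth: int = 3
    min_alt_reads: int = 3
    min_alt_fraction: float = 0.10
    alt_support_samples: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if min(self.min_qual_snv, self.min_qual_indel, self.min_depth, self.min_alt_reads) < 0:
            raise ConfigError("quality thresholds must be nonnegative")
        if not (0.0 <= self.min_alt_fraction <= 1.0):
            raise ConfigError("min_alt_fraction must lie in [0, 1]")

    def passes(self, v: VariantRecord) -> bool:
        min_qual = self.min_qual_snv if v.var_class == "snv" else self.min_qual_indel
        if v.qual < min_qual or v.depth < self.min_depth:
            return False
        if v.sample in self.alt_support_samples:
            if v.alt_reads < self.min_alt_reads:
                return False
            if v.depth == 0 or v.alt_reads / v.depth < self.min_alt_fraction:
                return False
        return True


def apply_quality_filters(
    variants: Sequence[VariantRecord], criteria: QualityCriteria = QualityCriteria()
) -> list[VariantRecord]:
    """Keep records meeting the quality criteria; input order is preserved."""
    if criteria.alt_support_samples and variants:
        present = {v.sample for v in variants}
        unknown = set(criteria.alt_support_samples) - present
        if unknown:
            raise ConfigError(
                f"alt_support_samples {sorted(unknown)} not among input samples {sorted(present)}"
            )
    return [v for v in variants if criteria.passes(v)]


def filter_functional_rare(
    variants: Sequence[VariantRecord],
    blacklist: Iterable[VariantKey] | None = None,
) -> list[VariantRecord]:
    """Keep functional (coding/splice) variants never seen in controls.

    If ``blacklist`` is given it overrides each record's ``known`` flag:
    a record is known iff its (chrom, pos, ref, alt) key is in the blacklist.
    """
    if blacklist is not None:
        keys = set(blacklist)
        return [v for v in variants if v.functional and v.key not in keys]
    return [v for v in variants if v.functional and not v.known]


@dataclass
class SomaticCalls:
    """Per-tumor somatic variant lists plus the union of somatic keys."""

    by_sample: dict[str, list[VariantRecord]] = field(default_factory=dict)

    @property
    def union_keys(self) -> set[VariantKey]:
        return {v.key for recs in self.by_sample.values() for v in recs}

    def counts(self) -> dict[str, int]:
        return {s: len(r) for s, r in self.by_sample.items()}


def call_somatic(
    tumor_variants: Sequence[VariantRecord],
    blood_variants: Sequence[VariantRecord],
    min_blood_reads: int = 1,
) -> SomaticCalls:
    """Somatic = tumor variants whose key never appears in the blood sample.

    Blood evidence excludes a variant regardless of blood-side quality; any
    blood record with >= ``min_blood_reads`` supporting reads counts as
    evidence (the aggressive default: cross-tumor "unique" calls usually show
    low-level support in the other samples and are artifacts).
    """
    blood_keys = {v.key for v in blood_variants if v.alt_reads >= min_blood_reads}
    calls = SomaticCalls()
    for v in tumor_variants:
        if v.key in blood_keys:
            continue
        calls.by_sample.setdefault(v.sample, []).append(v)
    return calls
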