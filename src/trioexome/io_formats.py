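"""Readers, writers and domain containers for every on-disk format the pipeline touches.

Coordinate conventions are centralized here and nowhere else:

* BED exon models are 0-based half-open ``[start, end)``.
* Variant positions are 1-based (VCF convention).
* A variant at 1-based position ``p`` lies inside exon ``[s, e)`` iff ``s < p <= e``.

Formats handled: BED (exon model), VCF v4.x or an equivalent TSV dialect (variants),
a tab-delimited per-exon coverage matrix with a ``totals.tsv`` sidecar, and SEG
(segmented copy-number output, with combined p-value and call appended).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

__all__ = [
    "ExonModel",
    "CoverageMatrix",
    "VariantRecord",
    "SegmentTable",
    "read_exon_model",
    "write_exon_model",
    "read_coverage",
    "write_coverage",
    "read_variant_table",
    "write_variant_table",
    "write_variant_vcf",
    "read_segments",
    "write_segments",
    "variant_in_exon",
]

EXON_COLUMNS = ("chrom", "start", "end", "exon_id")
SEG_COLUMNS = ("sample", "chrom", "start", "end", "n_exons", "mean_log_ratio", "combined_p", "call")
_SEG_HEADER = ("ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean", "combined.p", "call")
VARIANT_COLUMNS = (
    "chrom", "pos", "ref", "alt", "sample", "depth", "alt_reads",
    "qual", "var_class", "functional", "known",
)


def variant_in_exon(exon_start: int, exon_end: int, pos: int) -> bool:
    """True iff 1-based position ``pos`` falls inside 0-based half-open ``[exon_start, exon_end)``."""
    return exon_start < pos <= exon_end


def _genome_order(chroms: Iterable[str]) -> list[str]:
    """Chromosome ordering: numeric chromosomes first, then X, Y, MT, then lexical."""
    def key(c: str):
        name = c[3:] if c.lower().startswith("chr") else c
        if name.isdigit():
            return (0, int(name), "")
        rank = {"X": 23, "Y": 24, "M": 25, "MT": 25}.get(name.upper())
        return (0, rank, "") if rank is not None else (1, 0, name)
    return sorted(set(chroms), key=key)


@dataclass
class ExonModel:
    """Ordered set of capture-target exons: the denominator of RPKM normalization.

    ``exons`` holds columns chrom, start (0-based), end (exclusive), exon_id,
    sorted by (chrom, start) with chrom following ``genome_order``.
    """

    exons: pd.DataFrame
    genome_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        missing = set(EXON_COLUMNS) - set(self.exons.columns)
        if missing:
            raise SchemaError(f"exon model missing columns: {sorted(missing)}")
        df = self.exons.loc[:, list(EXON_COLUMNS)].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        bad = df["start"] >= df["end"]
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"exon {df['exon_id'].iloc[i]!r}: start {df['start'].iloc[i]} >= end {df['end'].iloc[i]}"
            )
        if df["exon_id"].duplicated().any():
            dup = df.loc[df["exon_id"].duplicated(), "exon_id"].iloc[0]
            raise ValidationError(f"duplicate exon_id {dup!r}")
        if not self.genome_order:
            self.genome_order = _genome_order(df["chrom"])
        rank = {c: i for i, c in enumerate(self.genome_order)}
        df = df.sort_values(
            by=["chrom", "start", "end"],
            key=lambda s: s.map(rank) if s.name == "chrom" else s,
            kind="mergesort",
        ).reset_index(drop=True)
        self.exons = df

    def __len__(self) -> int:
        return len(self.exons)

    @property
    def exon_ids(self) -> list[str]:
        return self.exons["exon_id"].tolist()

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.exons["end"] - self.exons["start"]).to_numpy()

    def locate(self, chrom: str, pos: int) -> str | None:
        """Exon id containing 1-based ``pos``, or None. First match wins on overlap."""
        sub = self.exons[self.exons["chrom"] == chrom]
        hit = sub[(sub["start"] < pos) & (pos <= sub["end"])]
        return None if hit.empty else str(hit["exon_id"].iloc[0])


def read_exon_model(path: str | Path) -> ExonModel:
    """Parse a BED (>=3 columns) into a sorted :class:`ExonModel`.

    A fourth column supplies exon ids; otherwise stable ids ``exon_<n>`` are
    assigned in file order before sorting.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(f"{path}:{lineno}: start {start} >= end {end}")
            exon_id = parts[3] if len(parts) >= 4 and parts[3] else f"exon_{len(rows) + 1}"
            rows.append((parts[0], start, end, exon_id))
    if not rows:
        raise ParseError(f"{path}: no intervals found")
    return ExonModel(pd.DataFrame(rows, columns=list(EXON_COLUMNS)))


def write_exon_model(model: ExonModel, path: str | Path) -> None:
    model.exons.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class CoverageMatrix:
    """Per-exon read counts for all samples of one cohort plus library sizes.

    Rows align with ``exon_model``; ``counts[i, j]`` is the read count of exon i
    in sample ``sample_names[j]``. The matched normal (blood) is by convention
    the first sample.
    """

    exon_model: ExonModel
    counts: np.ndarray
    sample_names: list[str]
    library_totals: dict[str, int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n_exons, n_samples = self.counts.shape
        if n_exons != len(self.exon_model) or n_samples != len(self.sample_names):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.exon_model)} exons x {len(self.sample_names)} samples"
            )
        if (self.counts < 0).any():
            raise ValidationError("negative read count")
        for j, name in enumerate(self.sample_names):
            if name not in self.library_totals:
                raise SchemaError(f"no library total for sample {name!r}")
            total = int(self.library_totals[name])
            if total <= 0:
                raise ValidationError(f"library total for {name!r} must be positive")
            if total < int(self.counts[:, j].sum()):
                raise ValidationError(
                    f"library total for {name!r} smaller than its column sum over exons"
                )

    def column(self, sample: str) -> np.ndarray:
        if sample not in self.sample_names:
            raise SchemaError(f"unknown sample {sample!r}; have {self.sample_names}")
        return self.counts[:, self.sample_names.index(sample)]


def write_coverage(cov: CoverageMatrix, path: str | Path, totals_path: str | Path | None = None) -> None:
    """Write the count matrix as TSV (`exon_id chrom start end <sample...>`) plus a totals sidecar."""
    path = Path(path)
    df = cov.exon_model.exons[["exon_id", "chrom", "start", "end"]].copy()
    for j, name in enumerate(cov.sample_names):
        df[name] = cov.counts[:, j]
    df.to_csv(path, sep="\t", index=False)
    totals_path = Path(totals_path) if totals_path else path.with_name("totals.tsv")
    pd.DataFrame(
        {"sample": cov.sample_names, "total_mapped_reads": [cov.library_totals[s] for s in cov.sample_names]}
    ).to_csv(totals_path, sep="\t", index=False)


def read_coverage(path: str | Path, totals_path: str | Path | None = None) -> CoverageMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    fixed = ["exon_id", "chrom", "start", "end"]
    missing = set(fixed) - set(df.columns)
    if missing:
        raise SchemaError(f"coverage matrix missing columns: {sorted(missing)}")
    samples = [c for c in df.columns if c not in fixed]
    if not samples:
        raise SchemaError("coverage matrix has no sample columns")
    totals_path = Path(totals_path) if totals_path else path.with_name("totals.tsv")
    totals_df = pd.read_csv(totals_path, sep="\t")
    if not {"sample", "total_mapped_reads"} <= set(totals_df.columns):
        raise SchemaError(f"{totals_path}: expected columns sample, total_mapped_reads")
    totals = dict(zip(totals_df["sample"], totals_df["total_mapped_reads"].astype(int)))
    model = ExonModel(df[["chrom", "start", "end", "exon_id"]])
    # ExonModel sorting may permute rows; realign counts to the sorted model.
    order = df.set_index("exon_id").loc[model.exon_ids]
    counts = order[samples].to_numpy()
    return CoverageMatrix(model, counts, samples, totals)


@dataclass(frozen=True)
class VariantRecord:
    """One called variant in one sample, with the evidence the filters need.

    ``functional`` marks protein-coding or canonical-splice-site consequences;
    ``known`` marks presence in population/control databases (dbSNP, 1000G,
    unrelated control exomes) supplied as a local blacklist.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    depth: int
    alt_reads: int
    qual: float
    var_class: str
    functional: bool
    known: bool

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref equals alt ({self.ref})")
        if not (0 <= self.alt_reads <= self.depth):
            raise ValidationError(
                f"{self.chrom}:{self.pos} ({self.sample}): alt_reads {self.alt_reads} "
                f"outside [0, depth={self.depth}]"
            )
        if self.qual < 0:
            raise ValidationError(f"{self.chrom}:{self.pos}: negative quality {self.qual}")
        if self.var_class not in ("snv", "indel"):
            raise ValidationError(f"{self.chrom}:{self.pos}: var_class must be snv or indel")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for cross-sample matching and blacklists."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def allele_fraction(self) -> float:
        return self.alt_reads / self.depth if self.depth > 0 else float("nan")


def infer_var_class(ref: str, alt: str) -> str:
    return "snv" if len(ref) == 1 and len(alt) == 1 else "indel"


def _bool_field(value, where: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "t", "yes"):
        return True
    if s in ("0", "false", "f", "no"):
        return False
    raise ValidationError(f"{where}: cannot interpret {value!r} as boolean")


def read_variant_table(path: str | Path, sample: str | None = None) -> list[VariantRecord]:
    """Read variants from VCF (``.vcf``/``.vcf.gz``) or the equivalent TSV dialect.

    Multi-allelic VCF rows are split into one record per alternate allele.
    Both routes yield identical :class:`VariantRecord` lists for the same data.
    """
    path = Path(path)
    if path.name.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(path, sample)
    return _read_variant_tsv(path)


def _read_vcf(path: Path, sample: str | None) -> list[VariantRecord]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample is None:
        if len(vcf.samples) == 1:
            sample = vcf.samples[0]
        else:
            declared = [
                line.split("=", 1)[1].strip()
                for line in vcf.raw_header.splitlines()
                if line.startswith("##sample=")
            ]
            if len(declared) != 1:
                raise SchemaError(
                    f"{path}: expected a single-sample VCF, a ##sample= header line, "
                    f"or an explicit sample name"
                )
            sample = declared[0]
    records: list[VariantRecord] = []
    for v in vcf:
        depth = v.INFO.get("DP")
        ao = v.INFO.get("AO")
        if depth is None or ao is None:
            raise SchemaError(f"{path} at {v.CHROM}:{v.POS}: INFO fields DP and AO are required")
        if v.QUAL is None:
            raise SchemaError(f"{path} at {v.CHROM}:{v.POS}: QUAL is required")
        alts = v.ALT

        def per_alt(value):
            # cyvcf2 yields scalars for single-alt rows, tuples for multi-alt
            # numeric fields, and comma-joined strings for Number=A strings
            if isinstance(value, str):
                return value.split(",")
            if isinstance(value, (tuple, list, np.ndarray)):
                return list(value)
            return [value]

        ao_list = per_alt(ao)
        func = v.INFO.get("FUNC")
        known = v.INFO.get("KNOWN")
        if func is None or known is None:
            raise SchemaError(f"{path} at {v.CHROM}:{v.POS}: INFO fields FUNC and KNOWN are required")
        func_list = per_alt(func)
        known_list = per_alt(known)
        vc = v.INFO.get("VC")
        vc_list = per_alt(vc) if vc is not None else [None] * len(alts)
        for lst, name in ((ao_list, "AO"), (func_list, "FUNC"), (known_list, "KNOWN"), (vc_list, "VC")):
            if len(lst) != len(alts):
                raise SchemaError(
                    f"{path} at {v.CHROM}:{v.POS}: INFO {name} has {len(lst)} values "
                    f"for {len(alts)} alt alleles"
                )
        for alt, a, f, k, c in zip(alts, ao_list, func_list, known_list, vc_list):
            where = f"{path} at {v.CHROM}:{v.POS}"
            records.append(
                VariantRecord(
                    chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt, sample=sample,
                    depth=int(depth), alt_reads=int(a), qual=float(v.QUAL),
                    var_class=(str(c) if c is not None else infer_var_class(v.REF, alt)),
                    functional=_bool_field(f, where), known=_bool_field(k, where),
                )
            )
    return records


def _read_variant_tsv(path: Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: variant TSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            VariantRecord(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
                sample=str(row.sample), depth=int(row.depth), alt_reads=int(row.alt_reads),
                qual=float(row.qual), var_class=str(row.var_class),
                functional=_bool_field(row.functional, f"{path} {row.chrom}:{row.pos}"),
                known=_bool_field(row.known, f"{path} {row.chrom}:{row.pos}"),
            )
        )
    return records


def write_variant_table(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write records in the TSV dialect (columns as VARIANT_COLUMNS, booleans as 0/1)."""
    df = pd.DataFrame(
        [
            (r.chrom, r.pos, r.ref, r.alt, r.sample, r.depth, r.alt_reads,
             r.qual, r.var_class, int(r.functional), int(r.known))
            for r in records
        ],
        columns=list(VARIANT_COLUMNS),
    )
    df.to_csv(path, sep="\t", index=False)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">
##INFO=<ID=AO,Number=A,Type=Integer,Description="Reads supporting each alternate allele">
##INFO=<ID=VC,Number=A,Type=String,Description="Variant class per alternate allele (snv or indel)">
##INFO=<ID=FUNC,Number=A,Type=Integer,Description="1 if protein-coding or canonical splice site">
##INFO=<ID=KNOWN,Number=A,Type=Integer,Description="1 if present in population/control databases">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variant_vcf(records: Sequence[VariantRecord], path: str | Path) -> None:
    """Write one sample's records as a sites-only VCF carrying the evidence in INFO.

    Records sharing (chrom, pos, ref) are emitted as one multi-allelic row.
    """
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValidationError(f"one VCF per sample; got records from {sorted(samples)}")
    grouped: dict[tuple[str, int, str], list[VariantRecord]] = {}
    for r in records:
        grouped.setdefault((r.chrom, r.pos, r.ref), []).append(r)
    buf = io.StringIO()
    header, columns = _VCF_HEADER.rsplit("#CHROM", 1)
    buf.write(header)
    if records:
        buf.write(f"##sample={records[0].sample}\n")
    buf.write("#CHROM" + columns)
    for (chrom, pos, ref), group in grouped.items():
        depths = {r.depth for r in group}
        quals = {r.qual for r in group}
        if len(depths) > 1 or len(quals) > 1:
            raise ValidationError(f"{chrom}:{pos}: alleles of one site must share depth and quality")
        info = ";".join(
            [
                f"DP={group[0].depth}",
                "AO=" + ",".join(str(r.alt_reads) for r in group),
                "VC=" + ",".join(r.var_class for r in group),
                "FUNC=" + ",".join(str(int(r.functional)) for r in group),
                "KNOWN=" + ",".join(str(int(r.known)) for r in group),
            ]
        )
        alt = ",".join(r.alt for r in group)
        buf.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{group[0].qual:g}\t.\t{info}\n")
    Path(path).write_text(buf.getvalue())


@dataclass
class SegmentTable:
    """Called copy-number segments (one row per segment per tumor sample)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.df) == 0:
            self.df = pd.DataFrame(columns=list(SEG_COLUMNS))
        missing = set(SEG_COLUMNS) - set(self.df.columns)
        if missing:
            raise SchemaError(f"segment table missing columns: {sorted(missing)}")
        df = self.df.loc[:, list(SEG_COLUMNS)].reset_index(drop=True)
        if len(df):
            df = df.astype({"start": np.int64, "end": np.int64, "n_exons": np.int64})
            if (df["start"] >= df["end"]).any():
                raise ValidationError("segment with start >= end")
            if (df["n_exons"] < 1).any():
                raise ValidationError("segment with fewer than one exon")
            del_mismatch = (df["call"] == "del") != (df["mean_log_ratio"] < 0)
            if del_mismatch.any():
                raise ValidationError("call=del must coincide with mean_log_ratio < 0")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SegmentTable) and self.df.equals(other.df)


def write_segments(table: SegmentTable, path: str | Path) -> None:
    """Serialize as SEG: standard columns plus combined.p and call appended."""
    out = table.df.copy()
    out.columns = list(_SEG_HEADER)
    # %.17g round-trips IEEE doubles, so read_segments(write_segments(t)) == t
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_segments(path: str | Path) -> SegmentTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if list(df.columns) != list(_SEG_HEADER):
        raise SchemaError(f"{path}: expected SEG columns {_SEG_HEADER}, got {list(df.columns)}")
    df.columns = list(SEG_COLUMNS)
    if len(df):
        df["combined_p"] = df["combined_p"].astype(float)
        df["mean_log_ratio"] = df["mean_log_ratio"].astype(float)
    return SegmentTable(df)
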