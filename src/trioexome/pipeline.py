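"""End-to-end orchestration: simulate/load -> filter -> somatic -> track -> CNV.

One :func:`run_pipeline` call performs the whole matched-cohort analysis and
writes every stage's tables under an output directory. A single global seed is
fanned out to per-stage child seeds by stable derivation, so a re-run with the
same config and seed reproduces every table byte for byte, and any stage run
standalone with its child seed reproduces its own output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .allele_dynamics import (
    ConcordanceResult,
    build_frequency_series,
    concordance,
    concordance_by_sample,
    estimate_purity,
    select_rising_variants,
)
from .cnv_caller import SegmentationParams, call_cnvs
from .errors import ConfigError, InsufficientDataError
from .io_formats import (
    SegmentTable,
    read_coverage,
    read_exon_model,
    read_variant_table,
    variant_in_exon,
    write_coverage,
    write_exon_model,
    write_segments,
    write_variant_table,
)
from .synthetic_data import SimulationConfig, config_from_dict, simulate_cohort
from .variant_filtering import (
    QualityCriteria,
    apply_quality_filters,
    call_somatic,
    filter_functional_rare,
)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "report_table1"]

STAGES = ("raw", "quality", "rare_functional", "somatic")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``simulation`` is set (the cohort is generated) or the input paths
    are. ``sample_order`` lists the blood sample first, then the tumors in
    biological order (primary, metastasis, recurrence); the alt-read-support
    quality rule is applied to the first tumor (the primary) unless
    ``criteria.alt_support_samples`` says otherwise.
    """

    outdir: str = "trioexome_run"
    seed: int = 0
    sample_order: tuple[str, ...] = ("blood", "OV", "OMN", "REC")
    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    exon_model_path: str | None = None
    coverage_path: str | None = None
    totals_path: str | None = None
    variant_paths: dict | None = None  # sample name -> VCF/TSV path
    sanger_path: str | None = None
    blacklist_path: str | None = None
    criteria: QualityCriteria = field(default_factory=QualityCriteria)
    rising_threshold: float = 0.10
    rising_mode: str = "relative"
    seg_params: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if len(self.sample_order) < 2:
            raise ConfigError("sample_order needs a blood sample and at least one tumor")
        if self.simulation is None and not (self.coverage_path and self.variant_paths):
            raise ConfigError("either a simulation config or input paths are required")

    @property
    def blood(self) -> str:
        return self.sample_order[0]

    @property
    def tumors(self) -> tuple[str, ...]:
        return self.sample_order[1:]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            raw["simulation"] = config_from_dict(raw["simulation"])
        if "criteria" in raw:
            c = dict(raw["criteria"])
            if "alt_support_samples" in c:
                c["alt_support_samples"] = tuple(c["alt_support_samples"])
            raw["criteria"] = QualityCriteria(**c)
        if "seg_params" in raw:
            raw["seg_params"] = SegmentationParams(**raw["seg_params"])
        if "sample_order" in raw:
            raw["sample_order"] = tuple(raw["sample_order"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config fields: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        def canon(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: canon(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): canon(v) for k, v in sorted(obj.items())}
            if isinstance(obj, (list, tuple)):
                return [canon(v) for v in obj]
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj
        payload = json.dumps(canon(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-stage record counts and the headline results of one run."""

    counts: dict  # sample -> stage -> int, stages as in STAGES
    somatic_union: int
    rising_variants: list
    concordance: ConcordanceResult | None
    concordance_per_sample: dict
    purity: dict  # tumor -> PurityEstimate | None
    cnv_calls: pd.DataFrame
    version: str
    config_hash: str

    def to_json(self) -> str:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, pd.DataFrame):
                return obj.to_dict(orient="records")
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            raise TypeError(f"cannot encode {type(obj)}")
        return json.dumps(dataclasses.asdict(self), default=enc, indent=2, sort_keys=True)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Stable per-stage seeds below 2**31 derived from one global seed."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def report_table1(report: RunReport, sample_order: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Per-sample counts along the filter chain (raw -> quality -> rare -> somatic)."""
    samples = list(sample_order) if sample_order else sorted(report.counts)
    rows = [
        {"sample": s, **{stage: report.counts.get(s, {}).get(stage, 0) for stage in STAGES}}
        for s in samples
    ]
    return pd.DataFrame(rows)


def _load_blacklist(path: str | Path) -> set:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "pos", "ref", "alt"])
    return {(str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples(index=False)}


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis; all tables are written under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_seed, seg_seed = _child_seeds(config.seed, 2)

    blacklist = _load_blacklist(config.blacklist_path) if config.blacklist_path else None
    sanger = None
    if config.simulation is not None:
        sim = replace(config.simulation, seed=sim_seed, sample_names=config.sample_order)
        model, cov, variants, truth = simulate_cohort(sim)
        sanger = truth.sanger
        inputs = outdir / "inputs"
        inputs.mkdir(exist_ok=True)
        write_exon_model(model, inputs / "exons.bed")
        write_coverage(cov, inputs / "coverage.tsv", inputs / "totals.tsv")
        write_variant_table(variants, inputs / "variants.tsv")
        if sanger is not None:
            sanger.to_csv(inputs / "sanger.tsv", sep="\t", index=False)
        truth.variants.to_csv(outdir / "truth_variants.tsv", sep="\t", index=False)
        truth.segments.to_csv(outdir / "truth_segments.tsv", sep="\t", index=False)
    else:
        cov = read_coverage(config.coverage_path, config.totals_path)
        model = cov.exon_model if config.exon_model_path is None else read_exon_model(config.exon_model_path)
        variants = []
        for sample, path in config.variant_paths.items():
            variants.extend(read_variant_table(path, sample=sample))
        if config.sanger_path:
            sanger = pd.read_csv(config.sanger_path, sep="\t")

    by_sample = {s: [v for v in variants if v.sample == s] for s in config.sample_order}
    counts = {s: {"raw": len(by_sample[s])} for s in config.sample_order}

    criteria = config.criteria
    if not criteria.alt_support_samples:
        criteria = replace(criteria, alt_support_samples=(config.tumors[0],))
    quality = apply_quality_filters(variants, criteria)
    rare = filter_functional_rare(quality, blacklist=blacklist)
    for s in config.sample_order:
        counts[s]["quality"] = sum(v.sample == s for v in quality)
        counts[s]["rare_functional"] = sum(v.sample == s for v in rare)

    blood_rare = [v for v in rare if v.sample == config.blood]
    tumor_rare = [v for v in rare if v.sample != config.blood]
    somatic = call_somatic(tumor_rare, blood_rare)
    for s in config.sample_order:
        counts[s]["somatic"] = len(somatic.by_sample.get(s, [])) if s != config.blood else 0
    write_variant_table(
        [v for s in config.tumors for v in somatic.by_sample.get(s, [])],
        outdir / "somatic_variants.tsv",
    )

    series = build_frequency_series(somatic.by_sample, config.sample_order, sanger)
    rising = select_rising_variants(
        series, threshold=config.rising_threshold, mode=config.rising_mode,
        baseline=config.tumors[0], later=config.tumors[1:],
    )
    _write_trajectories(series, config.sample_order, outdir / "af_trajectories.tsv",
                        {fs.key for fs in rising})
    try:
        conc = concordance(series, samples=config.tumors)
        conc_by = concordance_by_sample(series, samples=config.tumors)
    except InsufficientDataError:
        conc, conc_by = None, {}

    tumor_seeds = _child_seeds(seg_seed, len(config.tumors))
    seg_frames = []
    for t, t_seed in zip(config.tumors, tumor_seeds):
        table = call_cnvs(cov, config.blood, t, replace(config.seg_params, seed=t_seed))
        seg_frames.append(table.df)
    cnv_df = pd.concat(seg_frames, ignore_index=True) if seg_frames else SegmentTable(pd.DataFrame()).df
    write_segments(SegmentTable(cnv_df), outdir / "cnv_calls.seg")

    purity = {}
    for t in config.tumors:
        calls = cnv_df[cnv_df["sample"] == t]
        neutral_afs = []
        for v in somatic.by_sample.get(t, []):
            in_cnv = any(
                r.chrom == v.chrom and variant_in_exon(int(r.start), int(r.end), v.pos)
                for r in calls.itertuples(index=False)
            )
            if not in_cnv:
                neutral_afs.append(v.allele_fraction)
        purity[t] = estimate_purity(neutral_afs, t)

    report = RunReport(
        counts=counts,
        somatic_union=len(somatic.union_keys),
        rising_variants=sorted(fs.key for fs in rising),
        concordance=conc,
        concordance_per_sample=conc_by,
        purity=purity,
        cnv_calls=cnv_df,
        version=__version__,
        config_hash=config.config_hash(),
    )
    (outdir / "report.json").write_text(report.to_json())
    report_table1(report, config.sample_order).to_csv(outdir / "table1.tsv", sep="\t", index=False)
    return report


def _write_trajectories(series, sample_order, path, rising_keys) -> None:
    rows = []
    for fs in sorted(series, key=lambda f: f.key):
        row = {"variant_key": fs.key}
        for s in sample_order:
            row[f"af_exome_{s}"] = fs.af_exome.get(s)
            row[f"af_sanger_{s}"] = fs.af_sanger.get(s)
        row["rising"] = int(fs.key in rising_keys)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
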