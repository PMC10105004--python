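"""End-to-end orchestration: preprocess -> map -> stacks -> seed profiles ->
differential -> trimming profiles -> gene reports.

A run is described by a YAML :class:`RunConfig` (sample sheet, transcript
FASTA, seed table, annotation, thresholds).  Outputs are plain-text
tables (TSV/BED/JSON) in one output directory, plus a machine-readable
``manifest.json`` recording the configuration hash, package versions and
per-stage read-conservation tallies.  Read conservation is asserted at
every stage boundary; a stage failure aborts with a stage-named error
while earlier outputs are preserved.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .differential import seed_shift_summary, test_differential
from .mapping import build_index, map_readset, unique_sense_hits, write_bed
from .preprocess import preprocess_fastq
from .profiles import profiles_to_frame, read_length_distribution, trim_profiles
from .reports import gene_abundance, stack_map_export
from .seeds import load_seed_table, profile_viability
from .stacks import (
    call_stacks,
    classify_processed,
    gene_counts,
    gene_processing_summary,
    normalize_expression,
)

log = logging.getLogger("riscseed")


class ValidationError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class Thresholds:
    min_stack_reads: int = 10
    min_stacks: int = 3
    min_norm_reads: float = 10.0
    seed_length_min: int = 18
    seed_length_max: int = 25
    offset_window: tuple[int, int] = (-3, 1)
    alpha: float = 0.05
    one_location_frac: float = 0.9

    def validate(self) -> None:
        if min(self.min_stack_reads, self.min_stacks) < 1 or self.min_norm_reads <= 0:
            raise ValidationError("stack/normalized-read thresholds must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.seed_length_min > self.seed_length_max:
            raise ValidationError("seed length range is inverted")


@dataclass
class RunConfig:
    """Everything a pipeline run needs; numeric constants live here."""

    sample_sheet: Path
    transcripts: Path
    seed_table: Path
    annotation: Path
    thresholds: Thresholds = field(default_factory=Thresholds)
    rng_seed: int = 0
    report_gene: str | None = None
    adapter_kwargs: dict = field(default_factory=dict)

    def validate(self) -> pd.DataFrame:
        for name in ("sample_sheet", "transcripts", "seed_table", "annotation"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ValidationError(f"{name} path does not exist: {p}")
        self.thresholds.validate()
        sheet = pd.read_csv(self.sample_sheet, sep="\t")
        required = {"sample_id", "condition", "replicate", "fastq"}
        if not required <= set(sheet.columns):
            raise ValidationError(f"sample sheet must have columns {sorted(required)}")
        base = Path(self.sample_sheet).parent
        sheet["fastq"] = [
            str(p) if Path(p).is_absolute() else str(base / p) for p in sheet["fastq"]
        ]
        for p in sheet["fastq"]:
            if not Path(p).exists():
                raise ValidationError(f"FASTQ path does not exist: {p}")
        if sheet["condition"].nunique() != 2:
            raise ValidationError("exactly two conditions are required")
        return sheet

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        thresholds = Thresholds(**raw.get("thresholds", {}))
        if isinstance(thresholds.offset_window, list):
            thresholds.offset_window = tuple(thresholds.offset_window)
        return cls(
            sample_sheet=resolve(raw["sample_sheet"]),
            transcripts=resolve(raw["transcripts"]),
            seed_table=resolve(raw["seed_table"]),
            annotation=resolve(raw["annotation"]),
            thresholds=thresholds,
            rng_seed=int(raw.get("rng_seed", 0)),
            report_gene=raw.get("report_gene"),
            adapter_kwargs=raw.get("adapter_kwargs", {}),
        )

    def config_hash(self) -> str:
        payload = {
            **{k: str(v) for k, v in dataclasses.asdict(self).items()},
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage and return the manifest dict (also written to disk)."""
    sheet = config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = config.thresholds
    manifest: dict = {
        "config_hash": config.config_hash(),
        "versions": {"riscseed": __version__, "pandas": pd.__version__},
        "stages": [],
        "conservation": {},
    }

    def stage(name: str):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("preprocess")
        readsets = {}
        for row in sheet.itertuples():
            rs, summary = preprocess_fastq(
                row.fastq,
                sample_id=row.sample_id,
                condition=row.condition,
                replicate=int(row.replicate),
                **config.adapter_kwargs,
            )
            readsets[row.sample_id] = rs
            rs.to_tsv(outdir / f"{row.sample_id}.counts.tsv")
            conserved = (
                summary["records_in"]
                == summary["collapsed_total"]
                + summary["rejected_adapter"]
                + summary["rejected_length"]
            )
            manifest["conservation"][row.sample_id] = {**summary, "conserved": conserved}
            if not (conserved or summary["dedup_umi"]):
                raise RuntimeError(f"read conservation violated for {row.sample_id}")
    except Exception as e:  # noqa: BLE001 - stage boundary
        _abort(manifest, outdir, "preprocess", e)

    try:
        stage("map")
        index = build_index(config.transcripts)
        hits = {}
        for sid, rs in readsets.items():
            hits[sid] = map_readset(rs, index)
            write_bed(hits[sid], outdir / f"{sid}.hits.bed")
    except Exception as e:
        _abort(manifest, outdir, "map", e)

    try:
        stage("stacks")
        annotation = pd.read_csv(config.annotation, sep="\t")
        stacks_by_sample = {
            sid: call_stacks(h, thresholds.min_stack_reads) for sid, h in hits.items()
        }
        stack_rows = [
            (sid, s.gene_id, s.start, s.raw_count)
            for sid, stacks in stacks_by_sample.items()
            for s in stacks
        ]
        pd.DataFrame(
            stack_rows, columns=["sample_id", "gene_id", "start", "raw_count"]
        ).to_csv(outdir / "stacks.tsv", sep="\t", index=False)

        summaries = {}
        for condition, group in sheet.groupby("condition"):
            sids = list(group["sample_id"])
            counts = {sid: gene_counts(hits[sid]) for sid in sids}
            totals = {sid: readsets[sid].total_raw_reads for sid in sids}
            rpm = normalize_expression(counts, totals)
            summary = gene_processing_summary(
                {sid: stacks_by_sample[sid] for sid in sids}, rpm, annotation
            )
            summary = classify_processed(
                summary, thresholds.min_stacks, thresholds.min_norm_reads
            )
            summary.to_csv(outdir / f"processed_{condition}.tsv", sep="\t", index=False)
            summaries[condition] = summary
    except Exception as e:
        _abort(manifest, outdir, "stacks", e)

    try:
        stage("seedtox")
        table = load_seed_table(config.seed_table)
        length_range = (thresholds.seed_length_min, thresholds.seed_length_max)
        profile_rows = []
        for sid, rs in readsets.items():
            prof = profile_viability(rs, table, length_range)
            prof.histogram_frame().to_csv(
                outdir / f"{sid}.viability_histogram.tsv", sep="\t", index=False
            )
            profile_rows.append(
                (sid, prof.n_reads, prof.median, prof.q1, prof.q3,
                 prof.skipped_length, prof.skipped_seed)
            )
        pd.DataFrame(
            profile_rows,
            columns=["sample_id", "n_reads", "median", "q1", "q3",
                     "skipped_length", "skipped_seed"],
        ).to_csv(outdir / "viability_profiles.tsv", sep="\t", index=False)
    except Exception as e:
        _abort(manifest, outdir, "seedtox", e)

    try:
        stage("differential")
        conditions = sorted(sheet["condition"].unique())
        group_a = [readsets[s] for s in sheet.loc[sheet["condition"] == conditions[0], "sample_id"]]
        group_b = [readsets[s] for s in sheet.loc[sheet["condition"] == conditions[1], "sample_id"]]
        diff = test_differential(group_a, group_b)
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        shift = seed_shift_summary(diff, table, thresholds.alpha)
        with open(outdir / "seed_shift.json", "w") as fh:
            json.dump(
                {
                    "n_up": shift.n_up, "n_down": shift.n_down,
                    "median_up": shift.median_up, "median_down": shift.median_down,
                    "kruskal_statistic": shift.statistic, "kruskal_p": shift.p_value,
                    "label": shift.label,
                },
                fh, indent=2,
            )
    except Exception as e:
        _abort(manifest, outdir, "differential", e)

    try:
        stage("profiles")
        pooled = [h for hs in hits.values() for h in hs]
        pooled_stacks = call_stacks(pooled, thresholds.min_stack_reads)
        profs = trim_profiles(unique_sense_hits(pooled), pooled_stacks)
        profiles_to_frame(profs).to_csv(outdir / "trim_profiles.tsv", sep="\t", index=False)
        read_length_distribution(hits, (thresholds.seed_length_min, thresholds.seed_length_max)).to_csv(
            outdir / "read_lengths.tsv", sep="\t"
        )
    except Exception as e:
        _abort(manifest, outdir, "profiles", e)

    try:
        stage("report")
        if config.report_gene:
            totals = {sid: rs.total_raw_reads for sid, rs in readsets.items()}
            ab = gene_abundance(hits, totals, config.report_gene)
            ab.frame.to_csv(outdir / f"{config.report_gene}.abundance.tsv", sep="\t", index=False)
            stack_map_export(pooled, config.report_gene).to_csv(
                outdir / f"{config.report_gene}.stack_map.tsv", sep="\t", index=False
            )
    except Exception as e:
        _abort(manifest, outdir, "report", e)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _abort(manifest: dict, outdir: Path, stage: str, cause: Exception):
    manifest["failed_stage"] = stage
    with open(Path(outdir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    raise StageError(stage, cause) from cause
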