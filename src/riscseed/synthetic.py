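"""Synthetic Argonaute-pulldown small-RNA data with ground truth.

Emulates the sequencing-library design the pipeline consumes: replicated
samples of reads generated from implanted cleavage hotspots on a toy
transcriptome (5'-start jitter, insert lengths 18-25 nt) plus a
miRNA-like background, written as FASTQ records laid out as
``4 nt 5' UMI + insert + 2 nt 3' UMI + 3' adapter``.  Counts are drawn
negative-binomially per unique read variant (hotspot x jitter offset x
length), so a hotspot's expected total equals its configured mean while
toxic-seed enrichment — a multiplicative factor applied in the second
condition to reads whose seed viability falls below a threshold — can act
at the level where it belongs: the individual read, whose seed depends on
the jitter offset.

Every sample comes with a truth table (per-hotspot drawn counts, per-read
origin), so downstream stages are testable without external data.  Fixed
seeds give bit-identical outputs.

What this generator does *not* emulate: sequencing error, quality-score
variation (qualities are constant 'I'), PCR duplication beyond the UMI
layout, and genome-scale transcriptomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .preprocess import DEFAULT_ADAPTER, ReadSet
from .seeds import SeedViabilityTable, extract_seed

DEFAULT_LENGTH_DIST = {
    18: 0.05, 19: 0.10, 20: 0.20, 21: 0.25, 22: 0.20, 23: 0.10, 24: 0.07, 25: 0.03,
}
DEFAULT_JITTER_DIST = {-1: 0.1, 0: 0.8, 1: 0.1}


class ConfigError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


def _check_dist(dist: Mapping[int, float], lo: int, hi: int, what: str) -> None:
    if not dist:
        raise ConfigError(f"{what} distribution is empty")
    for k, p in dist.items():
        if not lo <= k <= hi:
            raise ConfigError(f"{what} support value {k} outside [{lo}, {hi}]")
        if p < 0:
            raise ConfigError(f"{what} probability for {k} is negative")
    if abs(sum(dist.values()) - 1.0) > 1e-6:
        raise ConfigError(f"{what} probabilities must sum to 1")


@dataclass
class Hotspot:
    """An implanted cleavage site: reads start near ``start`` on the gene."""

    start: int
    mean_count: float
    length_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    jitter_dist: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_JITTER_DIST))

    def validate(self) -> None:
        if self.mean_count <= 0:
            raise ConfigError("hotspot mean_count must be > 0")
        _check_dist(self.length_dist, 18, 25, "length")
        _check_dist(self.jitter_dist, -5, 5, "jitter")


@dataclass
class TranscriptSpec:
    gene_id: str
    biotype: str
    length: int


@dataclass
class BackgroundRead:
    """A miRNA-like background species with its own mean count."""

    sequence: str
    mean_count: float


@dataclass
class SyntheticConfig:
    """Full description of a simulated two-condition pulldown experiment."""

    rng_seed: int
    transcripts: list[TranscriptSpec]
    hotspots: dict[str, list[Hotspot]] = field(default_factory=dict)
    background: list[BackgroundRead] = field(default_factory=list)
    conditions: tuple[str, str] = ("A", "B")
    replicates_per_condition: int = 2
    toxic_enrichment: float = 1.0
    toxicity_threshold: float = 50.0
    adapter: str = DEFAULT_ADAPTER
    umi5_len: int = 4
    umi3_len: int = 2
    count_noise: float = 0.01  # NB dispersion; variance = m + d * m^2

    def validate(self) -> None:
        if not self.transcripts:
            raise ConfigError("at least one transcript is required")
        ids = [t.gene_id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate gene ids")
        lengths = {t.gene_id: t.length for t in self.transcripts}
        for t in self.transcripts:
            if t.length <= 0:
                raise ConfigError(f"transcript {t.gene_id} has non-positive length")
        for gene, spots in self.hotspots.items():
            if gene not in lengths:
                raise ConfigError(f"hotspot gene {gene} not in transcript list")
            for h in spots:
                h.validate()
                min_off = min(h.jitter_dist)
                max_off = max(h.jitter_dist)
                max_len = max(h.length_dist)
                if h.start + min_off < 0:
                    raise ConfigError(f"hotspot at {gene}:{h.start} underruns the transcript")
                if h.start + max_off + max_len > lengths[gene]:
                    raise ConfigError(
                        f"hotspot at {gene}:{h.start} overruns transcript of length {lengths[gene]}"
                    )
        for b in self.background:
            if b.mean_count <= 0:
                raise ConfigError("background mean_count must be > 0")
        if len(self.conditions) != 2 or len(set(self.conditions)) != 2:
            raise ConfigError("exactly two distinct condition labels required")
        if self.replicates_per_condition < 1:
            raise ConfigError("replicates_per_condition must be >= 1")
        if self.toxic_enrichment <= 0:
            raise ConfigError("toxic_enrichment must be > 0")
        if self.count_noise < 0:
            raise ConfigError("count_noise (NB dispersion) must be >= 0")

    def annotation_frame(self) -> pd.DataFrame:
        """Gene annotation table for the toy transcriptome (no miRNA loci)."""
        return pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in self.transcripts],
                "biotype": [t.biotype for t in self.transcripts],
                "is_mirna": False,
            }
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["transcripts"] = [TranscriptSpec(**t) for t in raw["transcripts"]]
        raw["hotspots"] = {
            g: [
                Hotspot(
                    start=h["start"],
                    mean_count=h["mean_count"],
                    length_dist={int(k): v for k, v in h["length_dist"].items()},
                    jitter_dist={int(k): v for k, v in h["jitter_dist"].items()},
                )
                for h in spots
            ]
            for g, spots in raw.get("hotspots", {}).items()
        }
        raw["background"] = [BackgroundRead(**b) for b in raw.get("background", [])]
        raw["conditions"] = tuple(raw.get("conditions", ("A", "B")))
        return cls(**raw)


@dataclass
class TruthTable:
    """Ground truth of one simulation run.

    ``hotspot_counts``: drawn read count per (condition, replicate, gene,
    hotspot).  ``reads``: one row per emitted unique read per sample, with
    origin (hotspot | background), source gene, 5'-offset from the hotspot
    start, length, sequence and count.  Per sample, the read counts sum to
    the number of FASTQ records emitted.
    """

    hotspot_counts: pd.DataFrame
    reads: pd.DataFrame

    def sample_total(self, sample_id: str) -> int:
        sub = self.reads[self.reads["sample_id"] == sample_id]
        return int(sub["count"].sum())


def generate_transcriptome(config: SyntheticConfig) -> dict[str, str]:
    """Draw the toy transcriptome (uniform {A,C,G,T}) for a configuration.

    Deterministic for a fixed ``rng_seed``; one sequence per configured
    gene, in configuration order.
    """
    config.validate()
    rng = np.random.default_rng([config.rng_seed, 0])
    bases = np.array(list("ACGT"))
    out: dict[str, str] = {}
    for t in config.transcripts:
        out[t.gene_id] = "".join(rng.choice(bases, size=t.length))
    return out


def write_fasta(transcripts: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for gene, seq in transcripts.items():
            fh.write(f">{gene}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def random_background(
    n: int = 40,
    mean_count: float = 80.0,
    lengths: Sequence[int] = (20, 21, 22, 23),
    rng_seed: int = 0,
) -> list[BackgroundRead]:
    """Draw n distinct miRNA-like background species with uniform random seeds."""
    rng = np.random.default_rng([rng_seed, 99])
    bases = np.array(list("ACGT"))
    seqs: set[str] = set()
    out = []
    while len(out) < n:
        L = int(rng.choice(np.asarray(lengths)))
        s = "".join(rng.choice(bases, size=L))
        if s in seqs:
            continue
        seqs.add(s)
        out.append(BackgroundRead(sequence=s, mean_count=mean_count))
    return out


def default_config(rng_seed: int = 0, toxic_enrichment: float = 1.0) -> SyntheticConfig:
    """The standard simulated experiment: 6 genes, 16 hotspots, 40 background
    species, 2 conditions x 2 replicates.

    Five protein-coding genes carry 4/3/3/2/1 hotspots (means 30-60 reads)
    and one lincRNA carries 3, so the processed-mRNA definition is
    exercised on both sides of each criterion; the background emulates a
    miRNA population at mean 80 reads per species.
    """
    transcripts = [
        TranscriptSpec("GENE1", "protein_coding", 900),
        TranscriptSpec("GENE2", "protein_coding", 700),
        TranscriptSpec("GENE3", "protein_coding", 600),
        TranscriptSpec("GENE4", "protein_coding", 500),
        TranscriptSpec("GENE5", "protein_coding", 400),
        TranscriptSpec("LINC1", "lincRNA", 600),
    ]
    hotspots = {
        "GENE1": [Hotspot(100, 60.0), Hotspot(300, 50.0), Hotspot(520, 60.0), Hotspot(760, 40.0)],
        "GENE2": [Hotspot(90, 50.0), Hotspot(300, 45.0), Hotspot(550, 50.0)],
        "GENE3": [Hotspot(80, 40.0), Hotspot(260, 50.0), Hotspot(450, 40.0)],
        "GENE4": [Hotspot(120, 60.0), Hotspot(330, 60.0)],
        "GENE5": [Hotspot(200, 30.0)],
        "LINC1": [Hotspot(100, 50.0), Hotspot(280, 50.0), Hotspot(440, 50.0)],
    }
    return SyntheticConfig(
        rng_seed=rng_seed,
        transcripts=transcripts,
        hotspots=hotspots,
        background=random_background(rng_seed=rng_seed),
        toxic_enrichment=toxic_enrichment,
    )


def sharp_hotspot_config(rng_seed: int = 0) -> SyntheticConfig:
    """A recovery-study design: hotspots without 5'-start jitter.

    With all reads of a hotspot sharing one 5' start (jitter mass at 0)
    and means of 50-80 reads, the planted truth is unambiguous: each
    hotspot yields exactly one stack and each gene's processed label
    follows from its hotspot count and biotype.  Used to measure stack
    recovery and processed-mRNA classification against ground truth.
    """
    point = {0: 1.0}
    transcripts = [
        TranscriptSpec("GENE1", "protein_coding", 800),
        TranscriptSpec("GENE2", "protein_coding", 700),
        TranscriptSpec("GENE3", "protein_coding", 600),
        TranscriptSpec("GENE4", "protein_coding", 500),
        TranscriptSpec("LINC1", "lincRNA", 600),
    ]
    def spot(start, mean):
        return Hotspot(start, mean, jitter_dist=dict(point))
    hotspots = {
        "GENE1": [spot(100, 80.0), spot(300, 60.0), spot(520, 70.0), spot(700, 50.0)],
        "GENE2": [spot(90, 60.0), spot(300, 55.0), spot(550, 60.0)],
        "GENE3": [spot(80, 50.0), spot(260, 70.0)],
        "GENE4": [spot(200, 60.0)],
        "LINC1": [spot(100, 60.0), spot(280, 60.0), spot(440, 60.0)],
    }
    return SyntheticConfig(
        rng_seed=rng_seed,
        transcripts=transcripts,
        hotspots=hotspots,
        background=random_background(rng_seed=rng_seed),
    )


def background_only_config(
    rng_seed: int = 0,
    background: list[BackgroundRead] | None = None,
    toxic_enrichment: float = 1.0,
    n_background: int = 60,
    mean_count: float = 50.0,
) -> SyntheticConfig:
    """A differential-study design: pure miRNA-like background, no hotspots.

    Used for type-I error calibration (``toxic_enrichment = 1``) and for
    toxic-shift power studies (enrichment > 1 with a toxic/nontoxic
    sequence mix).
    """
    return SyntheticConfig(
        rng_seed=rng_seed,
        transcripts=[TranscriptSpec("DUMMY1", "protein_coding", 200)],
        background=background
        if background is not None
        else random_background(n=n_background, mean_count=mean_count, rng_seed=rng_seed),
        toxic_enrichment=toxic_enrichment,
    )


def toxic_mix_background(
    table: SeedViabilityTable,
    n_toxic: int = 20,
    n_nontoxic: int = 20,
    mean_count: float = 150.0,
    toxic_below: float = 30.0,
    nontoxic_above: float = 80.0,
) -> list[BackgroundRead]:
    """Deterministic background of reads with known-toxic and known-viable seeds.

    Seeds are picked lexicographically from the table below/above the given
    viability cutoffs and embedded at guide positions 2-7 of a 21 nt read.
    """
    toxic = sorted(s for s, v in table.viability.items() if v < toxic_below)[:n_toxic]
    nontoxic = sorted(s for s, v in table.viability.items() if v > nontoxic_above)[:n_nontoxic]
    if len(toxic) < n_toxic or len(nontoxic) < n_nontoxic:
        raise ConfigError("table does not provide enough toxic/nontoxic seeds")
    tail = "ACGTACGTACGTAC"  # fixed filler to 21 nt
    return [
        BackgroundRead(sequence="A" + s + tail, mean_count=mean_count)
        for s in toxic + nontoxic
    ]


def _draw_nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _variant_mean(
    base_mean: float,
    sequence: str,
    condition_is_b: bool,
    config: SyntheticConfig,
    table: SeedViabilityTable | None,
) -> float:
    if not condition_is_b or config.toxic_enrichment == 1.0:
        return base_mean
    if table is None:
        raise ConfigError("toxic_enrichment != 1 requires a seed viability table")
    viability = table.get(extract_seed(sequence))
    if viability is not None and viability < config.toxicity_threshold:
        return base_mean * config.toxic_enrichment
    return base_mean


def generate_counts(
    config: SyntheticConfig,
    transcripts: Mapping[str, str],
    table: SeedViabilityTable | None = None,
) -> tuple[list[ReadSet], TruthTable]:
    """Draw per-sample unique-read counts and the matching truth table.

    This is the in-memory core of the generator; :func:`generate_readset`
    wraps it with UMI/adapter FASTQ emission.  Reads whose drawn count is
    zero are omitted.
    """
    config.validate()
    samples: list[ReadSet] = []
    hotspot_rows = []
    read_rows = []
    for ci, condition in enumerate(config.conditions):
        is_b = ci == 1
        for rep in range(1, config.replicates_per_condition + 1):
            sample_id = f"{condition}_{rep}"
            rng = np.random.default_rng([config.rng_seed, 1, ci, rep])
            entries: dict[str, int] = {}
            for gene in sorted(config.hotspots):
                tseq = transcripts[gene]
                for hi, spot in enumerate(config.hotspots[gene]):
                    spot_total = 0
                    for off in sorted(spot.jitter_dist):
                        for L in sorted(spot.length_dist):
                            p = spot.jitter_dist[off] * spot.length_dist[L]
                            if p <= 0:
                                continue
                            insert = tseq[spot.start + off : spot.start + off + L]
                            mean = _variant_mean(
                                spot.mean_count * p, insert, is_b, config, table
                            )
                            c = _draw_nb(rng, mean, config.count_noise)
                            if c > 0:
                                entries[insert] = entries.get(insert, 0) + c
                                spot_total += c
                                read_rows.append(
                                    (sample_id, condition, rep, "hotspot", gene, hi, off, L, insert, c)
                                )
                    hotspot_rows.append((condition, rep, gene, hi, spot_total))
            for b in config.background:
                mean = _variant_mean(b.mean_count, b.sequence, is_b, config, table)
                c = _draw_nb(rng, mean, config.count_noise)
                if c > 0:
                    entries[b.sequence] = entries.get(b.sequence, 0) + c
                    read_rows.append(
                        (sample_id, condition, rep, "background", None, None, None,
                         len(b.sequence), b.sequence, c)
                    )
            samples.append(
                ReadSet(sample_id=sample_id, entries=entries, condition=condition, replicate=rep)
            )
    truth = TruthTable(
        hotspot_counts=pd.DataFrame(
            hotspot_rows, columns=["condition", "replicate", "gene_id", "hotspot", "count"]
        ),
        reads=pd.DataFrame(
            read_rows,
            columns=[
                "sample_id", "condition", "replicate", "origin", "gene_id",
                "hotspot", "offset", "length", "sequence", "count",
            ],
        ).astype({"hotspot": "Int64", "offset": "Int64", "length": "Int64"}),
    )
    return samples, truth


def generate_readset(
    config: SyntheticConfig,
    transcripts: Mapping[str, str],
    outdir,
    table: SeedViabilityTable | None = None,
) -> tuple[dict[str, Path], TruthTable]:
    """Write one FASTQ file per sample plus truth tables.

    Every record is ``umi5 + insert + umi3 + adapter`` with constant 'I'
    qualities; UMIs are drawn uniformly per record.  Returns the map of
    sample id to FASTQ path and the truth table.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    readsets, truth = generate_counts(config, transcripts, table)
    bases = np.array(list("ACGT"))
    paths: dict[str, Path] = {}
    for ci, condition in enumerate(config.conditions):
        for rep in range(1, config.replicates_per_condition + 1):
            sample_id = f"{condition}_{rep}"
            rs = next(r for r in readsets if r.sample_id == sample_id)
            rng = np.random.default_rng([config.rng_seed, 2, ci, rep])
            path = outdir / f"{sample_id}.fastq"
            serial = 0
            with open(path, "w") as fh:
                for insert, count in rs.entries.items():
                    for _ in range(count):
                        u5 = "".join(rng.choice(bases, size=config.umi5_len))
                        u3 = "".join(rng.choice(bases, size=config.umi3_len))
                        full = u5 + insert + u3 + config.adapter
                        fh.write(f"@{sample_id}.{serial}\n{full}\n+\n{'I' * len(full)}\n")
                        serial += 1
            paths[sample_id] = path
    truth.hotspot_counts.to_csv(outdir / "truth_hotspot_counts.tsv", sep="\t", index=False)
    truth.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    return paths, truth
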