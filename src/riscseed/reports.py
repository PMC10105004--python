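"""Per-gene reporting: abundance, stack maps, query clusters, sequence tracks.

These are the gene-centric exports used to characterize one transcript of
interest (e.g. a death-ligand ORF): how many RISC-bound reads derive from
it, what share of the RISC they occupy, where each read copy sits along
the ORF, the composition of a query-anchored read cluster, and per-
nucleotide tracks (base identity, paired/unpaired state from a dot-
bracket secondary-structure string).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import Hit, SENSE, TranscriptIndex, find_query_matches
from .seeds import SeedViabilityTable, canonicalize, SEED_SLICE


@dataclass
class GeneAbundance:
    """Per-sample raw counts, totals and percent-of-RISC for one gene.

    ``frame`` has one row per sample (gene_reads, total_reads, percent);
    the means and standard errors are taken across the supplied samples,
    treated as replicates (SE = SD/sqrt(r), ddof 1).
    """

    gene_id: str
    frame: pd.DataFrame
    mean_gene_reads: float
    sem_gene_reads: float
    mean_total_reads: float
    sem_total_reads: float
    mean_percent: float
    sem_percent: float


def _gene_read_count(hits: Iterable[Hit], gene: str) -> int:
    # every gene-matching read counts once per gene, regardless of how many
    # positions it occupies within the gene
    per_seq: dict[str, int] = {}
    for h in hits:
        if h.orientation == SENSE and h.transcript_id == gene:
            per_seq[h.sequence] = h.count
    return sum(per_seq.values())


def gene_abundance(
    hits_by_sample: Mapping[str, Sequence[Hit]],
    totals: Mapping[str, int],
    gene: str,
) -> GeneAbundance:
    """Tally a gene's raw reads and percent of total reads per sample."""
    rows = []
    for sample in hits_by_sample:
        total = totals[sample]
        if total <= 0:
            raise ValueError(f"sample {sample} has zero total reads")
        g = _gene_read_count(hits_by_sample[sample], gene)
        rows.append((sample, g, total, 100.0 * g / total))
    frame = pd.DataFrame(rows, columns=["sample", "gene_reads", "total_reads", "percent"])

    def mean_sem(col: str) -> tuple[float, float]:
        v = frame[col].to_numpy(float)
        sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return float(v.mean()), sem

    mg, sg = mean_sem("gene_reads")
    mt, st = mean_sem("total_reads")
    mp, sp = mean_sem("percent")
    return GeneAbundance(
        gene_id=gene,
        frame=frame,
        mean_gene_reads=mg, sem_gene_reads=sg,
        mean_total_reads=mt, sem_total_reads=st,
        mean_percent=mp, sem_percent=sp,
    )


def stack_map_export(hits: Iterable[Hit], gene: str | None = None) -> pd.DataFrame:
    """One interval row per read copy, for stack-map plotting.

    A unique sequence with count c contributes c identical rows (each
    horizontal line of the plot is one read).  Replicate-combined maps are
    produced by passing the concatenated hits of both replicates.  Rows
    are sorted by start, then length, then sequence.
    """
    rows = []
    for h in hits:
        if h.orientation != SENSE:
            continue
        if gene is not None and h.transcript_id != gene:
            continue
        rows.extend([(h.transcript_id, h.start, h.end, h.sequence)] * h.count)
    df = pd.DataFrame(rows, columns=["transcript_id", "start", "end", "sequence"])
    if not df.empty:
        df["length"] = df["end"] - df["start"]
        df = df.sort_values(["start", "length", "sequence"]).drop(columns="length")
    return df.reset_index(drop=True)


def parse_dotbracket(structure: str) -> np.ndarray:
    """Dot-bracket string -> boolean paired/unpaired track.

    Accepts only ``.``, ``(`` and ``)``; brackets must balance.  Returns a
    boolean array, True at paired positions (brackets).
    """
    depth = 0
    paired = np.empty(len(structure), dtype=bool)
    for i, ch in enumerate(structure):
        if ch == ".":
            paired[i] = False
        elif ch == "(":
            depth += 1
            paired[i] = True
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced dot-bracket string at position {i}")
            paired[i] = True
        else:
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    if depth != 0:
        raise ValueError("unbalanced dot-bracket string: unclosed '('")
    return paired


def read_dotbracket(path) -> np.ndarray:
    """Parse the dot-bracket line of a plain RNAfold output file.

    RNAfold prints the sequence line(s) followed by the structure line
    (optionally with a trailing free energy in parentheses separated by
    whitespace); header lines start with '>'.
    """
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(">"):
                continue
            token = line.split()[0]
            if set(token) <= set(".()"):
                return parse_dotbracket(token)
    raise ValueError(f"no dot-bracket line found in {path}")


def sequence_track(sequence: str, structure: str | None = None) -> pd.DataFrame:
    """Per-position track: 1-based position, base (RNA alphabet), paired flag."""
    bases = list(canonicalize(sequence).replace("T", "U"))
    df = pd.DataFrame({"position": np.arange(1, len(bases) + 1), "base": bases})
    if structure is not None:
        paired = parse_dotbracket(structure)
        if len(paired) != len(bases):
            raise ValueError("structure length does not match sequence length")
        df["paired"] = paired
    return df


@dataclass
class ClusterReport:
    """Composition of a query-anchored read cluster.

    ``variants`` holds one row per 5'-offset species (offset, sequence,
    count, fraction of cluster reads, seed, viability); fractions sum to 1
    over reported species.  ``cluster_share`` is the cluster's share of
    all of the gene's reads.
    """

    gene_id: str
    anchor_start: int
    variants: pd.DataFrame
    cluster_share: float


def cluster_report(
    hits: Sequence[Hit],
    query: str,
    table: SeedViabilityTable,
    index: TranscriptIndex | None = None,
    anchor_start: int | None = None,
    transcript_id: str | None = None,
    offset_window: tuple[int, int] = (-3, 1),
) -> ClusterReport:
    """Break a query-anchored cluster down by 5'-offset species.

    Each species is a distinct read sequence whose 5' start lies within
    the offset window of the query's anchor.  A species starting 1 nt
    5' of another carries a seed shifted by one position, so offsets map
    directly onto seed changes.
    """
    match = find_query_matches(
        hits, query, anchor_start=anchor_start, transcript_id=transcript_id,
        index=index, offset_window=offset_window,
    )
    total = sum(h.count for h in match.hits)
    rows = []
    for h in sorted(match.hits, key=lambda h: (h.start, h.sequence)):
        seed = canonicalize(h.sequence)[SEED_SLICE] if len(h.sequence) >= 7 else None
        rows.append(
            (
                h.start - match.anchor_start,
                h.sequence,
                h.count,
                h.count / total if total else 0.0,
                seed,
                table.get(seed) if seed else None,
            )
        )
    variants = pd.DataFrame(
        rows, columns=["offset", "sequence", "count", "fraction", "seed", "viability"]
    )
    gene_total = _gene_read_count(hits, match.transcript_id)
    share = total / gene_total if gene_total else 0.0
    return ClusterReport(
        gene_id=match.transcript_id,
        anchor_start=match.anchor_start,
        variants=variants,
        cluster_share=share,
    )
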