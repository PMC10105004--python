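"""5'-start stack calling and processed-mRNA classification.

Site-specific processing of an mRNA leaves a footprint in Argonaute-bound
small RNAs: many raw reads sharing the same 5' start on the transcript.
A *stack* is a (gene, 5'-start) group with at least ``min_stack_reads``
raw reads (default 10).  A gene is a *processed mRNA* when it is
protein-coding, carries three or more stacks, and has at least 10
normalized reads (reads per million, averaged across replicates).

Stacks are called per sample on unique sense hits; replicate pooling is a
plotting convenience, not part of calling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import Hit, unique_sense_hits

DEFAULT_MIN_STACK_READS = 10
DEFAULT_MIN_STACKS = 3
DEFAULT_MIN_NORM_READS = 10.0
DEFAULT_ONE_LOCATION_FRAC = 0.9


@dataclass
class Stack:
    """A (gene, 5'-start) read group passing the stack threshold.

    ``members`` maps each member sequence to its raw count; all members
    share the same gene, start and sense orientation.
    """

    gene_id: str
    start: int
    raw_count: int
    members: dict[str, int] = field(default_factory=dict)


def call_stacks(hits: Iterable[Hit], min_stack_reads: int = DEFAULT_MIN_STACK_READS) -> list[Stack]:
    """Group unique sense hits by (gene, 5' start) and keep groups >= threshold.

    Input hits should come from one sample (or an explicitly pooled
    replicate combination).  Non-unique and antisense hits are ignored.
    Output is deterministically ordered by (gene, start).
    """
    groups: dict[tuple[str, int], dict[str, int]] = {}
    for h in unique_sense_hits(hits):
        key = (h.transcript_id, h.start)
        members = groups.setdefault(key, {})
        members[h.sequence] = members.get(h.sequence, 0) + h.count
    out = []
    for (gene, start) in sorted(groups):
        members = groups[(gene, start)]
        total = sum(members.values())
        if total >= min_stack_reads:
            out.append(Stack(gene_id=gene, start=start, raw_count=total, members=dict(sorted(members.items()))))
    return out


def gene_counts(hits: Iterable[Hit]) -> dict[str, int]:
    """Raw read count per gene over unique sense hits."""
    counts: dict[str, int] = {}
    for h in unique_sense_hits(hits):
        counts[h.transcript_id] = counts.get(h.transcript_id, 0) + h.count
    return dict(sorted(counts.items()))


def normalize_expression(
    counts_by_sample: Mapping[str, Mapping[str, int]],
    totals: Mapping[str, int],
) -> pd.DataFrame:
    """Reads-per-million per gene and sample, with replicate mean and SEM.

    ``RPM = 1e6 * gene raw reads / total_raw_reads`` of the sample; the
    supplied samples are treated as replicates, so the returned frame
    carries per-sample columns plus ``mean`` and ``sem`` (SD/sqrt(r),
    ddof 1; SEM is 0 for a single replicate).  Library-size scaling is the
    default normalization; callers may rescale columns with their own
    per-sample factors before averaging.
    """
    samples = list(counts_by_sample)
    for s in samples:
        if totals[s] <= 0:
            raise ValueError(f"sample {s} has zero total reads")
    genes = sorted({g for c in counts_by_sample.values() for g in c})
    data = {
        s: [1e6 * counts_by_sample[s].get(g, 0) / totals[s] for g in genes]
        for s in samples
    }
    df = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    values = df.to_numpy(float)
    df["mean"] = values.mean(axis=1)
    if len(samples) > 1:
        df["sem"] = values.std(axis=1, ddof=1) / np.sqrt(len(samples))
    else:
        df["sem"] = 0.0
    return df


def gene_processing_summary(
    stacks_by_sample: Mapping[str, Sequence[Stack]],
    rpm: pd.DataFrame,
    annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble per-gene summaries: stack count, normalized reads, biotype.

    Stack counts are tallied per sample and averaged across the supplied
    replicates (genes absent from a sample contribute 0); normalized reads
    come from the ``mean`` column of :func:`normalize_expression`.
    ``annotation`` needs columns ``gene_id`` and ``biotype`` (optionally
    ``is_mirna``).
    """
    samples = list(stacks_by_sample)
    per_sample: dict[str, dict[str, int]] = {}
    for s in samples:
        tally: dict[str, int] = {}
        for st in stacks_by_sample[s]:
            tally[st.gene_id] = tally.get(st.gene_id, 0) + 1
        per_sample[s] = tally
    genes = sorted(set(rpm.index) | {g for t in per_sample.values() for g in t})
    ann = annotation.set_index("gene_id")
    rows = []
    for g in genes:
        counts = [per_sample[s].get(g, 0) for s in samples]
        rows.append(
            {
                "gene_id": g,
                "biotype": ann["biotype"].get(g, np.nan),
                "stack_count": float(np.mean(counts)) if counts else 0.0,
                "normalized_reads": float(rpm["mean"].get(g, 0.0)),
            }
        )
    return pd.DataFrame(rows)


def classify_processed(
    summaries: pd.DataFrame,
    min_stacks: int = DEFAULT_MIN_STACKS,
    min_norm_reads: float = DEFAULT_MIN_NORM_READS,
) -> pd.DataFrame:
    """Flag processed mRNAs: protein-coding, >= min_stacks stacks, >= min RPM.

    Genes with missing biotype annotation are dropped with a warning —
    the processed call is undefined without a biotype.
    """
    df = summaries.copy()
    missing = df["biotype"].isna()
    if missing.any():
        warnings.warn(
            f"excluding {int(missing.sum())} gene(s) with unknown biotype from "
            "processed-mRNA classification"
        )
        df = df[~missing].copy()
    df["processed"] = (
        (df["biotype"] == "protein_coding")
        & (df["stack_count"] >= min_stacks)
        & (df["normalized_reads"] >= min_norm_reads)
    )
    return df.reset_index(drop=True)


def top_stack_fraction(
    stacks: Sequence[Stack], gene_read_counts: Mapping[str, int]
) -> dict[str, float]:
    """Per gene, the largest stack's share of the gene's unique sense reads."""
    best: dict[str, int] = {}
    for st in stacks:
        best[st.gene_id] = max(best.get(st.gene_id, 0), st.raw_count)
    return {
        g: (best.get(g, 0) / gene_read_counts[g] if gene_read_counts.get(g) else 0.0)
        for g in sorted(gene_read_counts)
    }


def _composite_rank(df: pd.DataFrame) -> pd.Series:
    """Average of the stack-count and expression rank positions.

    Both ranks are descending (1 = most stacks / highest expression); ties
    within each rank take the average position, and the final ordering
    breaks composite ties lexicographically by gene id.
    """
    stack_rank = df["stack_count"].rank(ascending=False, method="average")
    expr_rank = df["normalized_reads"].rank(ascending=False, method="average")
    return (stack_rank + expr_rank) / 2.0


def rank_top_processed(
    risc_summaries: pd.DataFrame,
    total_summaries: pd.DataFrame,
    annotation: pd.DataFrame,
    top_n: int = 50,
    one_location_frac: float = DEFAULT_ONE_LOCATION_FRAC,
    top_stack_fractions: Mapping[str, float] | None = None,
) -> list[str]:
    """Rank processed genes jointly in RISC and total small-RNA data.

    Processed genes are ranked within each dataset by the composite of
    stack-count and expression ranks; genes in the top ``top_n`` of both
    datasets are kept, then genes flagged as miRNA loci (``is_mirna`` in
    the annotation) and genes whose reads fall primarily in a single
    location (top stack >= ``one_location_frac`` of gene reads) are
    dropped.  Returns gene ids ordered by their RISC composite rank.
    """
    ann = annotation.set_index("gene_id")

    def top_set(summaries: pd.DataFrame) -> pd.DataFrame:
        df = summaries[summaries.get("processed", True)].copy()
        df["composite"] = _composite_rank(df)
        df = df.sort_values(["composite", "gene_id"]).head(top_n)
        return df

    risc_top = top_set(risc_summaries)
    total_top = top_set(total_summaries)
    shared = [g for g in risc_top["gene_id"] if g in set(total_top["gene_id"])]

    out = []
    for g in shared:
        if "is_mirna" in ann.columns and bool(ann["is_mirna"].get(g, False)):
            continue
        if top_stack_fractions is not None and top_stack_fractions.get(g, 0.0) >= one_location_frac:
            continue
        out.append(g)
    return out
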