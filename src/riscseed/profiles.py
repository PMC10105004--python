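"""5'-start and 3'-end trimming heterogeneity around abundant stacks.

mRNA processing is not perfectly precise: reads in a stack neighborhood
can start a few nucleotides up- or downstream of the dominant start, and
reads sharing the dominant start can end at different lengths.  These
profiles tally that heterogeneity for the most abundant stacks (default
top 10), plus overall read-length distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import Hit, SENSE
from .stacks import Stack

DEFAULT_WINDOW = 5


def most_abundant_read(stack: Stack) -> str:
    """The member sequence with the largest raw count; ties break to the
    lexicographically smallest sequence."""
    if not stack.members:
        raise ValueError("empty stack")
    best = max(stack.members.values())
    return min(s for s, c in stack.members.items() if c == best)


@dataclass
class TrimProfile:
    """Heterogeneity profile of one stack.

    ``five_prime`` maps 5'-start offset (0 = the stack's dominant start,
    negative = upstream) to raw read count within the window;
    ``three_prime`` maps read length to count among reads starting exactly
    at offset 0.
    """

    gene_id: str
    anchor_start: int
    anchor_sequence: str
    five_prime: dict[int, int] = field(default_factory=dict)
    three_prime: dict[int, int] = field(default_factory=dict)


def top_stacks(stacks: Sequence[Stack], n: int = 10) -> list[Stack]:
    """The n most abundant stacks, ties broken by (gene, start)."""
    return sorted(stacks, key=lambda s: (-s.raw_count, s.gene_id, s.start))[:n]


def five_prime_profile(
    gene_hits: Iterable[Hit], stack: Stack, window: int = DEFAULT_WINDOW
) -> TrimProfile:
    """Tally 5' starts within +/- window of the stack's dominant start.

    The anchor (offset 0) is the 5' start of the stack's most abundant
    read — by construction the stack's own start, since all members share
    it.  Sense hits on the stack's gene with start offsets in
    ``[-window, +window]`` are counted; hits outside never contribute.
    """
    anchor_seq = most_abundant_read(stack)
    anchor = stack.start
    tally = {off: 0 for off in range(-window, window + 1)}
    for h in gene_hits:
        if h.orientation != SENSE or h.transcript_id != stack.gene_id:
            continue
        off = h.start - anchor
        if -window <= off <= window:
            tally[off] += h.count
    return TrimProfile(
        gene_id=stack.gene_id,
        anchor_start=anchor,
        anchor_sequence=anchor_seq,
        five_prime=tally,
    )


def three_prime_profile(gene_hits: Iterable[Hit], profile: TrimProfile) -> TrimProfile:
    """Tally read lengths among reads starting exactly at the anchor (offset 0)."""
    lengths: dict[int, int] = {}
    for h in gene_hits:
        if (
            h.orientation == SENSE
            and h.transcript_id == profile.gene_id
            and h.start == profile.anchor_start
        ):
            lengths[h.length] = lengths.get(h.length, 0) + h.count
    profile.three_prime = dict(sorted(lengths.items()))
    return profile


def trim_profiles(
    gene_hits: Sequence[Hit], stacks: Sequence[Stack], n: int = 10, window: int = DEFAULT_WINDOW
) -> list[TrimProfile]:
    """5' and 3' profiles for the top-n stacks."""
    out = []
    for st in top_stacks(stacks, n):
        prof = five_prime_profile(gene_hits, st, window)
        out.append(three_prime_profile(gene_hits, prof))
    return out


def read_length_distribution(
    hits_by_sample: Mapping[str, Sequence[Hit]],
    length_range: tuple[int, int] = (18, 25),
) -> pd.DataFrame:
    """Per-sample read-length fractions with replicate mean and SD.

    Counts sense hits with lengths inside the inclusive range, normalized
    to fractions per sample.  Columns: one per sample, plus ``mean`` and
    ``sd`` across the supplied samples (treated as replicates).
    """
    lo, hi = length_range
    lengths = list(range(lo, hi + 1))
    data = {}
    for sample, hits in hits_by_sample.items():
        tally = dict.fromkeys(lengths, 0)
        for h in hits:
            if h.orientation == SENSE and lo <= h.length <= hi:
                tally[h.length] += h.count
        total = sum(tally.values())
        data[sample] = [tally[l] / total if total else 0.0 for l in lengths]
    df = pd.DataFrame(data, index=pd.Index(lengths, name="length"))
    values = df.to_numpy(float)
    df["mean"] = values.mean(axis=1)
    df["sd"] = values.std(axis=1, ddof=1) if values.shape[1] > 1 else 0.0
    return df


def profiles_to_frame(profiles: Sequence[TrimProfile]) -> pd.DataFrame:
    """Long-format export of trim profiles (stack_id, axis, position, count)."""
    rows = []
    for p in profiles:
        sid = f"{p.gene_id}:{p.anchor_start}"
        for off, c in sorted(p.five_prime.items()):
            rows.append((sid, "five_prime_offset", off, c))
        for length, c in sorted(p.three_prime.items()):
            rows.append((sid, "three_prime_length", length, c))
    return pd.DataFrame(rows, columns=["stack_id", "axis", "position", "count"])
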