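"""Exact full-length placement of small-RNA reads on a transcript set.

For 18-25 nt reads matched against a defined set of transcript or ORF
sequences, a 100 %-identity full-length alignment is exactly a substring
occurrence, so the matcher enumerates every occurrence of each read (and
of its reverse complement) across the transcript set.  A read is *unique*
when it has exactly one placement set-wide; gene-level analyses downstream
use unique sense hits only, while sense/antisense totals support shRNA
strand analyses.

Uniqueness is necessarily defined relative to the supplied transcript
set — the set is the universe, not the genome.  Coordinates are 0-based
half-open internally and in BED output; report helpers print 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .preprocess import ReadSet

SENSE = "sense"
ANTISENSE = "antisense"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    return sequence.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Hit:
    """One placement of a counted read on a transcript.

    ``transcript[start:end]`` equals the read sequence (sense) or its
    reverse complement (antisense).  ``unique`` is set per *sequence*
    across the whole transcript set, not per placement.
    """

    sequence: str
    count: int
    transcript_id: str
    start: int
    end: int
    orientation: str
    unique: bool

    @property
    def length(self) -> int:
        return self.end - self.start


class TranscriptIndex:
    """All-occurrence substring matcher over a transcript set."""

    def __init__(self, transcripts: Mapping[str, str]):
        if not transcripts:
            raise ValueError("transcript set is empty")
        ids = list(transcripts)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate transcript ids")
        self.transcripts: dict[str, str] = {
            tid: str(seq).upper() for tid, seq in sorted(transcripts.items())
        }

    def __len__(self) -> int:
        return len(self.transcripts)

    def length_of(self, transcript_id: str) -> int:
        return len(self.transcripts[transcript_id])

    def find_all(self, query: str) -> list[tuple[str, int, str]]:
        """Every occurrence of ``query`` as (transcript_id, start, orientation).

        Sense occurrences are matches of the query itself; antisense
        occurrences are matches of its reverse complement, reported in
        transcript coordinates.  Order is deterministic: transcript id,
        then start, sense before antisense at equal positions.
        """
        q = query.upper()
        rc = reverse_complement(q)
        out: list[tuple[str, int, str]] = []
        for tid, seq in self.transcripts.items():
            occ: list[tuple[int, str]] = []
            for probe, orient in ((q, SENSE), (rc, ANTISENSE)):
                i = seq.find(probe)
                while i >= 0:
                    occ.append((i, orient))
                    i = seq.find(probe, i + 1)
            # a palindromic probe (q == rc) would be reported twice; dedupe
            if q == rc:
                occ = [(i, SENSE) for i, _ in occ]
            occ = sorted(set(occ), key=lambda x: (x[0], x[1] != SENSE))
            out.extend((tid, i, orient) for i, orient in occ)
        return out


def build_index(source) -> TranscriptIndex:
    """Build a :class:`TranscriptIndex` from a dict, SeqRecords, or a FASTA path."""
    if isinstance(source, TranscriptIndex):
        return source
    if isinstance(source, Mapping):
        return TranscriptIndex(source)
    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        pairs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(source), "fasta")]
    else:
        pairs = [(r.id, str(r.seq)) for r in source]
    if len({tid for tid, _ in pairs}) != len(pairs):
        raise ValueError("duplicate transcript ids")
    return TranscriptIndex(dict(pairs))


def map_readset(readset: ReadSet, index: TranscriptIndex) -> list[Hit]:
    """Place every unique sequence of a collapsed sample on the transcript set.

    Every occurrence is reported; the ``unique`` flag marks sequences with
    exactly one placement across the whole set (sense and antisense
    combined).  Sequences containing N never match.  Output order follows
    the lexicographic sequence order of the read set.
    """
    hits: list[Hit] = []
    for seq, count in readset.entries.items():
        occ = index.find_all(seq)
        unique = len(occ) == 1
        for tid, start, orient in occ:
            hits.append(
                Hit(
                    sequence=seq,
                    count=count,
                    transcript_id=tid,
                    start=start,
                    end=start + len(seq),
                    orientation=orient,
                    unique=unique,
                )
            )
    return hits


def unique_sense_hits(hits: Iterable[Hit]) -> list[Hit]:
    return [h for h in hits if h.unique and h.orientation == SENSE]


def hits_to_bed(hits: Iterable[Hit]) -> pd.DataFrame:
    """Hits as a BED6 frame: chrom = transcript, score = raw count, strand = +/-."""
    rows = [
        (
            h.transcript_id,
            h.start,
            h.end,
            h.sequence,
            h.count,
            "+" if h.orientation == SENSE else "-",
        )
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"]
    )


def write_bed(hits: Iterable[Hit], path) -> None:
    hits_to_bed(hits).to_csv(path, sep="\t", index=False, header=False)


def anchor_position(index: TranscriptIndex, query: str) -> tuple[str, int]:
    """Locate a query sequence that must have exactly one sense placement."""
    occ = [(tid, i) for tid, i, orient in index.find_all(query) if orient == SENSE]
    if not occ:
        raise ValueError("query not found on any transcript")
    if len(occ) > 1:
        raise ValueError(f"query is not uniquely placed ({len(occ)} sense occurrences)")
    return occ[0]


@dataclass
class QueryMatchResult:
    """Reads clustering at a query-anchored 5' position.

    ``offset_counts`` tallies raw reads per 5'-start offset relative to the
    anchor, restricted to the offset window; ``fractions`` are each
    offset's share of the cluster's reads (the pie-chart data).
    """

    transcript_id: str
    anchor_start: int
    hits: list[Hit]
    offset_counts: dict[int, int]
    fractions: dict[int, float]

    @property
    def total(self) -> int:
        return sum(self.offset_counts.values())


def find_query_matches(
    hits: Iterable[Hit],
    query: str,
    anchor_start: int | None = None,
    transcript_id: str | None = None,
    index: TranscriptIndex | None = None,
    offset_window: tuple[int, int] = (-3, 1),
) -> QueryMatchResult:
    """Collect sense hits whose 5' start falls near a query's anchor position.

    The anchor is the query's unique sense placement (located through
    ``index`` when not given explicitly).  Hits on the anchor transcript
    with 5' start in ``[anchor - 3, anchor + 1]`` (default window) belong
    to the cluster; counts are tallied per offset.
    """
    if anchor_start is None or transcript_id is None:
        if index is None:
            raise ValueError("provide either (transcript_id, anchor_start) or an index")
        transcript_id, anchor_start = anchor_position(index, query)
    lo, hi = offset_window
    matched = [
        h
        for h in hits
        if h.orientation == SENSE
        and h.transcript_id == transcript_id
        and lo <= h.start - anchor_start <= hi
    ]
    offset_counts: dict[int, int] = {}
    for h in matched:
        off = h.start - anchor_start
        offset_counts[off] = offset_counts.get(off, 0) + h.count
    total = sum(offset_counts.values())
    fractions = {
        off: (c / total if total else 0.0) for off, c in sorted(offset_counts.items())
    }
    return QueryMatchResult(
        transcript_id=transcript_id,
        anchor_start=anchor_start,
        hits=matched,
        offset_counts=dict(sorted(offset_counts.items())),
        fractions=fractions,
    )
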