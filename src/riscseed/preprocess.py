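"""Raw FASTQ to per-sample tables of unique small-RNA sequences.

Library layout: each sequenced record is a 4 nt 5' UMI, the small-RNA
insert, a 2 nt 3' UMI, then the 3' sequencing adapter.  Preprocessing
removes the adapter (exact match of its leading bases), strips the UMIs,
filters on insert length, and collapses identical sequences into a
(sequence -> count) table — the unit every downstream stage consumes.

Read conservation holds at this boundary:
``records_in == collapsed_total + rejected_adapter + rejected_length``.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

#: Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

DEFAULT_UMI5_LEN = 4
DEFAULT_UMI3_LEN = 2
#: Permissive length gate applied at preprocessing; the analysis-level
#: 18-25 nt filter belongs to seed profiling, not here.
DEFAULT_LENGTH_RANGE = (15, 45)


@dataclass
class ReadSet:
    """Unique small-RNA sequences of one sample with raw counts.

    ``entries`` maps uppercase DNA sequences to raw read counts and is kept
    in lexicographic key order for deterministic output.
    """

    sample_id: str
    entries: dict[str, int] = field(default_factory=dict)
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.entries = {k: int(v) for k, v in sorted(self.entries.items())}

    @property
    def total_raw_reads(self) -> int:
        return sum(self.entries.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sequence": list(self.entries), "count": list(self.entries.values())}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: str, condition: str = "", replicate: int = 0) -> "ReadSet":
        df = pd.read_csv(path, sep="\t")
        return cls(
            sample_id=sample_id,
            entries=dict(zip(df["sequence"].astype(str), df["count"].astype(int))),
            condition=condition,
            replicate=replicate,
        )


def trim_adapter(sequence: str, adapter: str = DEFAULT_ADAPTER, min_overlap: int = 6) -> str | None:
    """Remove the 3' adapter from a raw record by exact match at the 3' end.

    The leftmost position whose entire remaining suffix matches the adapter
    (or, for partial run-through at the 3' end, a prefix of the adapter of
    at least ``min_overlap`` bases) marks the insert/adapter junction; the
    suffix from there on is removed.  Requiring the match to run to the
    read's 3' end keeps an adapter-like k-mer inside the insert from being
    mistaken for the junction.  Records with no qualifying match are
    rejected (``None``).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    s = sequence.upper()
    a = adapter.upper()
    min_overlap = max(min_overlap, 1)
    for i in range(0, len(s) - min_overlap + 1):
        tail = s[i:]
        if len(tail) >= len(a):
            if tail.startswith(a):
                return s[:i]
        elif a.startswith(tail):
            return s[:i]
    return None


def strip_umis(
    insert: str,
    umi5_len: int = DEFAULT_UMI5_LEN,
    umi3_len: int = DEFAULT_UMI3_LEN,
) -> tuple[str, str, str]:
    """Split an adapter-trimmed insert into (sRNA, 5' UMI, 3' UMI).

    The first ``umi5_len`` and last ``umi3_len`` bases are unique molecular
    identifiers flanking the sequenced small RNA; both are returned so that
    callers may optionally deduplicate.  Inserts not strictly longer than
    the combined UMI length contain no sRNA and raise ``ValueError``.
    """
    if len(insert) <= umi5_len + umi3_len:
        raise ValueError(
            f"insert of length {len(insert)} too short for {umi5_len}+{umi3_len} nt UMIs"
        )
    umi5 = insert[:umi5_len]
    umi3 = insert[len(insert) - umi3_len :]
    return insert[umi5_len : len(insert) - umi3_len], umi5, umi3


def collapse(records: Iterable, dedup_umi: bool = False) -> dict[str, int]:
    """Collapse preprocessed records into a unique-sequence count table.

    ``records`` are either bare sequences or (sequence, umi5, umi3) tuples.
    With ``dedup_umi`` on, records sharing sequence *and* both UMIs count
    once (PCR-duplicate removal); the default counts every record.  Keys
    come back in lexicographic order.
    """
    counts: dict[str, int] = {}
    seen: set[tuple[str, str, str]] = set()
    for rec in records:
        if isinstance(rec, str):
            seq, key = rec, None
        else:
            seq = rec[0]
            key = (rec[0], rec[1], rec[2])
        if dedup_umi:
            if key is None:
                raise ValueError("UMI deduplication requires (sequence, umi5, umi3) records")
            if key in seen:
                continue
            seen.add(key)
        counts[seq] = counts.get(seq, 0) + 1
    return dict(sorted(counts.items()))


def preprocess_records(
    sequences: Iterable[str],
    sample_id: str,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 6,
    umi5_len: int = DEFAULT_UMI5_LEN,
    umi3_len: int = DEFAULT_UMI3_LEN,
    length_range: tuple[int, int] = DEFAULT_LENGTH_RANGE,
    dedup_umi: bool = False,
    condition: str = "",
    replicate: int = 0,
) -> tuple[ReadSet, dict]:
    """Run adapter trimming, UMI stripping, length filtering and collapsing.

    Returns the collapsed :class:`ReadSet` plus a summary dict with the
    per-stage tallies (``records_in``, ``rejected_adapter``,
    ``rejected_length``, ``collapsed_total``, ``unique_sequences``).
    Rejection is a counted outcome, never an error.  Reads containing N
    survive preprocessing (they are simply unmatchable downstream).
    """
    lo, hi = length_range
    kept: list[tuple[str, str, str]] = []
    n_in = rej_adapter = rej_length = 0
    for raw in sequences:
        n_in += 1
        insert = trim_adapter(raw, adapter, min_overlap)
        if insert is None:
            rej_adapter += 1
            continue
        if len(insert) <= umi5_len + umi3_len:
            rej_length += 1
            continue
        srna, u5, u3 = strip_umis(insert, umi5_len, umi3_len)
        if not lo <= len(srna) <= hi:
            rej_length += 1
            continue
        kept.append((srna, u5, u3))

    entries = collapse(kept, dedup_umi=dedup_umi)
    readset = ReadSet(sample_id=sample_id, entries=entries, condition=condition, replicate=replicate)
    summary = {
        "sample_id": sample_id,
        "records_in": n_in,
        "rejected_adapter": rej_adapter,
        "rejected_length": rej_length,
        "collapsed_total": readset.total_raw_reads,
        "unique_sequences": len(entries),
        "dedup_umi": dedup_umi,
    }
    if not dedup_umi:
        assert n_in == readset.total_raw_reads + rej_adapter + rej_length
    return readset, summary


def read_fastq_sequences(path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (gzip transparently handled)."""
    path = str(path)
    if path.endswith(".gz"):
        with gzip.open(path, "rt") as fh:
            for rec in SeqIO.parse(fh, "fastq"):
                yield str(rec.seq)
    else:
        for rec in SeqIO.parse(path, "fastq"):
            yield str(rec.seq)


def preprocess_fastq(path, sample_id: str, **kwargs) -> tuple[ReadSet, dict]:
    """Preprocess one FASTQ file; see :func:`preprocess_records` for options."""
    readset, summary = preprocess_records(read_fastq_sequences(path), sample_id, **kwargs)
    summary["fastq"] = str(path)
    return readset, summary


def write_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
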