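import numpy as np
import pandas as pd
import pytest

from riscseed.mapping import Hit, TranscriptIndex
from riscseed.seeds import SeedViabilityTable, example_seed_table, synthetic_viability_table


@pytest.fixture(scope="session")
def fixture_table() -> SeedViabilityTable:
    """Packaged small seed-viability table (3 published entries + synthetic filler)."""
    return example_seed_table()


@pytest.fixture(scope="session")
def full_table() -> SeedViabilityTable:
    """Deterministic synthetic table covering all 4,096 seeds."""
    return synthetic_viability_table(0)


@pytest.fixture
def toy_index() -> TranscriptIndex:
    return TranscriptIndex(
        {
            "T1": "AAACCCGGGTTT",
            "T2": "TTTTACGTACGTAAAACCCCGGGG",
        }
    )


def make_hit(sequence, count, transcript_id="G1", start=0, orientation="sense", unique=True):
    return Hit(
        sequence=sequence,
        count=count,
        transcript_id=transcript_id,
        start=start,
        end=start + len(sequence),
        orientation=orientation,
        unique=unique,
    )


@pytest.fixture
def make_hits():
    return make_hit


def naive_find_all(transcripts: dict, query: str, revcomp) -> list:
    """Brute-force oracle: check every offset of every transcript, both strands."""
    q = query.upper()
    rc = revcomp(q)
    out = []
    for tid in sorted(transcripts):
        seq = transcripts[tid].upper()
        m = len(q)
        for i in range(len(seq) - m + 1):
            window = seq[i : i + m]
            if window == q:
                out.append((tid, i, "sense"))
            elif window == rc:
                out.append((tid, i, "antisense"))
    return out


@pytest.fixture(scope="session")
def brute_force_mapper():
    return naive_find_all
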