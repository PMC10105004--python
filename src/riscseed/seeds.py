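"""6mer seed extraction and seed-viability scoring.

Short RNAs loaded into the RNA-induced silencing complex (RISC) repress
targets chiefly through nucleotides 2-7 of the guide strand, the *6mer
seed*.  Arrayed screens that tested every one of the 4,096 possible 6mer
seeds in a neutral siRNA backbone assign each seed a *viability*: the
percent cell viability observed when that seed is loaded into the RISC,
averaged across cell lines.  Low viability marks a toxic seed.

This module houses the seed-viability lookup table, extracts seeds from
read sequences, and turns a set of counted reads into a seed-viability
profile: a counts-weighted distribution, its median and quartiles, and
the integer-binned "seed viability graph" (viability on the x-axis, read
count on the y-axis).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats

SEED_LENGTH = 6
#: Seed occupies positions 2-7 (1-based, inclusive) of the guide strand.
SEED_SLICE = slice(1, 7)

_VALID_BASES = frozenset("ACGT")


def canonicalize(sequence: str) -> str:
    """Uppercase a nucleotide string and rewrite U as T (RNA -> DNA alphabet)."""
    return sequence.upper().replace("U", "T")


def extract_seed(sequence: str) -> str:
    """Return the 6mer seed (positions 2-7, 1-based) of a guide sequence.

    The input is canonicalized (uppercased, U -> T) first.  Sequences
    shorter than 7 nt have no complete seed and raise ``ValueError``.
    """
    s = canonicalize(sequence)
    if len(s) < 7:
        raise ValueError(
            f"sequence of length {len(s)} has no complete 6mer seed (need >= 7 nt)"
        )
    return s[SEED_SLICE]


def all_seeds() -> list[str]:
    """Enumerate all 4,096 6mers over {A,C,G,T} in lexicographic order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=SEED_LENGTH)]


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (2.5 -> 3, -2.5 -> -3)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass
class SeedViabilityTable:
    """Mapping of 6mer seed -> percent cell viability.

    A complete table has exactly 4,096 entries, one per 6mer over
    {A,C,G,T}; lookups canonicalize U -> T so RNA-alphabet queries work.
    """

    viability: dict[str, float]
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for seed, value in self.viability.items():
            key = canonicalize(seed)
            if len(key) != SEED_LENGTH or not set(key) <= _VALID_BASES:
                raise ValueError(f"invalid seed key: {seed!r}")
            if key in clean:
                raise ValueError(f"duplicate seed after canonicalization: {key}")
            v = float(value)
            if not math.isfinite(v):
                raise ValueError(f"non-finite viability for seed {key}")
            clean[key] = v
        self.viability = clean

    def __len__(self) -> int:
        return len(self.viability)

    def __contains__(self, seed: str) -> bool:
        return canonicalize(seed) in self.viability

    def __getitem__(self, seed: str) -> float:
        return self.viability[canonicalize(seed)]

    def get(self, seed: str, default: float | None = None) -> float | None:
        return self.viability.get(canonicalize(seed), default)

    @property
    def complete(self) -> bool:
        """True when every one of the 4,096 seeds has an entry."""
        return len(self.viability) == 4 ** SEED_LENGTH

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"seed": sorted(self.viability), "viability": [self.viability[s] for s in sorted(self.viability)]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_seed_table(path, provenance: str | None = None) -> SeedViabilityTable:
    """Load a seed-viability table from a CSV with columns ``seed`` and ``viability``.

    Keys are canonicalized (U -> T); duplicate keys after canonicalization,
    non-6mer keys, and missing columns are errors.  Completeness against the
    4,096-seed universe is exposed via :attr:`SeedViabilityTable.complete`,
    not enforced — partial fixture tables are legitimate inputs.
    """
    df = pd.read_csv(path)
    missing = {"seed", "viability"} - set(df.columns)
    if missing:
        raise ValueError(f"seed table {path} missing column(s): {sorted(missing)}")
    return SeedViabilityTable(
        viability=dict(zip(df["seed"].astype(str), df["viability"].astype(float))),
        provenance=provenance or str(path),
    )


def example_seed_table() -> SeedViabilityTable:
    """Load the small seed-viability fixture packaged with riscseed.

    The fixture holds the published human-average viabilities for the three
    seeds used as worked examples (ACTGGG 37.6%, GACTGG 28%, ACAAAG 80%);
    all other rows are synthetic filler for testing, as marked in the file.
    """
    with resources.as_file(
        resources.files("riscseed").joinpath("data/seed_viability_example.csv")
    ) as p:
        return load_seed_table(p, provenance="packaged example (3 published entries + synthetic filler)")


def synthetic_viability_table(rng_seed: int = 0) -> SeedViabilityTable:
    """Build a synthetic, deterministic seed-viability table over all 4,096 seeds.

    This is a stand-in for a real screen-derived table, for simulations and
    tests only.  It mimics the screens' qualitative structure — G/C-rich
    seeds skew toxic (low viability), A/U-rich seeds skew viable — via a
    composition score plus seeded noise, clipped to [0, 110] percent.
    """
    rng = np.random.default_rng([rng_seed, 4096])
    seeds = all_seeds()
    g = np.array([s.count("G") for s in seeds]) / SEED_LENGTH
    c = np.array([s.count("C") for s in seeds]) / SEED_LENGTH
    base = 105.0 - 95.0 * g - 45.0 * c
    noise = rng.normal(0.0, 10.0, size=len(seeds))
    values = np.clip(base + noise, 0.0, 110.0)
    return SeedViabilityTable(
        viability=dict(zip(seeds, values.round(1))),
        provenance="synthetic (composition model + seeded noise)",
    )


@dataclass
class SeedProfile:
    """Counts-weighted seed-viability distribution of a read population.

    ``reads`` holds one row per unique contributing sequence (sequence,
    count, length, seed, viability).  Summary statistics are weighted by
    read counts: conceptually the viability is "printed once per read".
    ``histogram`` is the seed viability graph — viability rounded to the
    nearest integer (halves away from zero) versus total read count.
    """

    reads: pd.DataFrame
    median: float
    q1: float
    q3: float
    histogram: dict[int, int]
    n_reads: int
    skipped_length: int = 0
    skipped_seed: int = 0

    def expanded(self) -> np.ndarray:
        """Viability values repeated once per read (count-weighted expansion)."""
        if self.reads.empty:
            return np.array([], dtype=float)
        return np.repeat(
            self.reads["viability"].to_numpy(float), self.reads["count"].to_numpy(int)
        )

    def histogram_frame(self) -> pd.DataFrame:
        bins = sorted(self.histogram)
        return pd.DataFrame(
            {"viability_bin": bins, "read_count": [self.histogram[b] for b in bins]}
        )


def _iter_seq_counts(reads) -> Iterable[tuple[str, int]]:
    """Normalize the accepted read containers to (sequence, count) pairs."""
    entries = getattr(reads, "entries", None)
    if entries is not None:  # a preprocess.ReadSet
        yield from entries.items()
        return
    for item in reads:
        seq = getattr(item, "sequence", None)
        if seq is not None:  # a mapping.Hit
            yield seq, item.count
        else:
            s, c = item
            yield s, int(c)


def profile_viability(
    reads,
    table: SeedViabilityTable,
    length_range: tuple[int, int] = (18, 25),
) -> SeedProfile:
    """Attach seed viabilities to counted reads and summarize the distribution.

    Parameters
    ----------
    reads
        A ``ReadSet``, an iterable of ``Hit`` objects, or (sequence, count)
        pairs.
    table
        Seed-viability lookup.
    length_range
        Inclusive read-length filter; only 18-25 nt reads contribute by
        default.  Reads outside the range, and reads whose seed is absent
        from the table (e.g. contains N), are skipped and tallied.
    """
    lo, hi = length_range
    rows = []
    skipped_length = 0
    skipped_seed = 0
    for seq, count in _iter_seq_counts(reads):
        n = len(seq)
        if n < lo or n > hi:
            skipped_length += count
            continue
        seed = canonicalize(seq)[SEED_SLICE]
        value = table.get(seed)
        if value is None:
            skipped_seed += count
            continue
        rows.append((seq, int(count), n, seed, value))

    df = pd.DataFrame(rows, columns=["sequence", "count", "length", "seed", "viability"])
    if df.empty:
        return SeedProfile(
            reads=df, median=float("nan"), q1=float("nan"), q3=float("nan"),
            histogram={}, n_reads=0,
            skipped_length=skipped_length, skipped_seed=skipped_seed,
        )

    expanded = np.repeat(df["viability"].to_numpy(float), df["count"].to_numpy(int))
    q1, med, q3 = np.percentile(expanded, [25, 50, 75])
    hist: dict[int, int] = {}
    for v, c in zip(df["viability"], df["count"]):
        b = round_half_away(v)
        hist[b] = hist.get(b, 0) + int(c)
    return SeedProfile(
        reads=df, median=float(med), q1=float(q1), q3=float(q3),
        histogram=hist, n_reads=int(df["count"].sum()),
        skipped_length=skipped_length, skipped_seed=skipped_seed,
    )


def compare_distributions(groups: Mapping[str, object]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across seed-viability distributions.

    ``groups`` maps a label to either a :class:`SeedProfile` (expanded to
    one value per read) or an array of viability values.  Requires at least
    two non-empty groups.  Ties are handled by midranks; if every value in
    every group is identical the statistic is 0 and p is 1 by convention.
    """
    samples = []
    for label, g in groups.items():
        arr = g.expanded() if isinstance(g, SeedProfile) else np.asarray(g, dtype=float)
        if arr.size:
            samples.append(arr)
    if len(samples) < 2:
        raise ValueError("need at least two non-empty groups")
    try:
        stat, p = scipy.stats.kruskal(*samples)
    except ValueError:
        # all observations identical: zero rank variance, H = 0 by definition
        return 0.0, 1.0
    return float(stat), float(p)
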