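"""Differential loading of unique small RNAs between two conditions.

Each unique sequence's pooled counts in conditions A and B are compared
with an exact conditional binomial test: given the sequence's total count
n = a + b, under the null its A-share is Binomial(n, N_A / (N_A + N_B)),
where N_A and N_B are the pooled library sizes.  P-values over all tested
sequences are Benjamini-Hochberg adjusted.  The seed-viability shift of
significantly up- versus down-loaded reads summarizes whether a condition
drives the RISC toward toxic (low-viability) seed content.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .preprocess import ReadSet
from .seeds import SeedViabilityTable, canonicalize, compare_distributions, SEED_SLICE

DEFAULT_MIN_TOTAL = 10
#: Pseudocount added to mean RPM before computing fold changes.
RPM_PSEUDOCOUNT = 0.5


def _pooled_counts(readsets: Sequence[ReadSet]) -> tuple[dict[str, int], int]:
    counts: dict[str, int] = {}
    total = 0
    for rs in readsets:
        total += rs.total_raw_reads
        for seq, c in rs.entries.items():
            counts[seq] = counts.get(seq, 0) + c
    return counts, total


def _mean_rpm(readsets: Sequence[ReadSet], seq: str) -> float:
    vals = [1e6 * rs.entries.get(seq, 0) / rs.total_raw_reads for rs in readsets]
    return float(np.mean(vals))


def test_differential(
    readsets_a: Sequence[ReadSet],
    readsets_b: Sequence[ReadSet],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Test every unique sequence for differential abundance between conditions.

    Replicates are pooled within each condition.  Sequences with pooled
    count below ``min_total`` are untestable and excluded before the BH
    adjustment.  The returned frame has one row per tested sequence:
    mean RPM per condition, log2 fold change (B over A, with a 0.5 RPM
    pseudocount), raw and BH-adjusted p-values, direction (``up`` = more
    abundant in B), and the 6mer seed where defined.
    """
    counts_a, total_a = _pooled_counts(readsets_a)
    counts_b, total_b = _pooled_counts(readsets_b)
    if total_a <= 0 or total_b <= 0:
        raise ValueError("each condition needs a positive pooled library size")
    p_null = total_a / (total_a + total_b)

    rows = []
    for seq in sorted(set(counts_a) | set(counts_b)):
        a = counts_a.get(seq, 0)
        b = counts_b.get(seq, 0)
        if a + b < min_total:
            continue
        p = binomtest(a, a + b, p_null).pvalue
        rpm_a = _mean_rpm(readsets_a, seq)
        rpm_b = _mean_rpm(readsets_b, seq)
        lfc = float(
            np.log2((rpm_b + RPM_PSEUDOCOUNT) / (rpm_a + RPM_PSEUDOCOUNT))
        )
        seed = canonicalize(seq)[SEED_SLICE] if len(seq) >= 7 else None
        rows.append((seq, a, b, rpm_a, rpm_b, lfc, p, seed))

    df = pd.DataFrame(
        rows,
        columns=[
            "sequence", "count_a", "count_b", "mean_rpm_a", "mean_rpm_b",
            "log2_fold_change", "p_value", "seed",
        ],
    )
    if df.empty:
        df["adj_p"] = pd.Series(dtype=float)
        df["direction"] = pd.Series(dtype=object)
        return df
    df["adj_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["direction"] = np.where(
        df["log2_fold_change"] > 0, "up",
        np.where(df["log2_fold_change"] < 0, "down", "none"),
    )
    return df


# not a test case, despite the name pytest would otherwise collect
test_differential.__test__ = False  # type: ignore[attr-defined]


@dataclass
class SeedShiftSummary:
    """Seed-viability composition of significantly shifted RISC content.

    ``label`` is ``"toxic shift"`` when the median viability of
    up-regulated reads falls below that of down-regulated reads (the RISC
    gained toxic seeds), ``"nontoxic shift"`` for the reverse, ``None``
    when either group is empty or the medians tie.
    """

    n_up: int
    n_down: int
    median_up: float | None
    median_down: float | None
    statistic: float | None
    p_value: float | None
    label: str | None
    table: pd.DataFrame


def seed_shift_summary(
    differential: pd.DataFrame,
    table: SeedViabilityTable,
    alpha: float = 0.05,
) -> SeedShiftSummary:
    """Partition significant reads into up/down and compare seed viabilities.

    Reads at ``adj_p < alpha`` are split by direction; each read's seed
    viability is attached (reads whose seed is absent from the table are
    dropped).  Group medians are over unique significant sequences, and a
    Kruskal-Wallis test compares the two viability distributions when both
    groups are non-empty.
    """
    sig = differential[(differential["adj_p"] < alpha) & (differential["direction"] != "none")].copy()
    sig["viability"] = [
        table.get(s) if s is not None else None for s in sig["seed"]
    ]
    sig = sig[sig["viability"].notna()].copy()
    up = sig.loc[sig["direction"] == "up", "viability"].to_numpy(float)
    down = sig.loc[sig["direction"] == "down", "viability"].to_numpy(float)

    median_up = float(np.median(up)) if up.size else None
    median_down = float(np.median(down)) if down.size else None
    stat = p = None
    if up.size and down.size:
        stat, p = compare_distributions({"up": up, "down": down})
    label = None
    if median_up is not None and median_down is not None:
        if median_up < median_down:
            label = "toxic shift"
        elif median_up > median_down:
            label = "nontoxic shift"
    return SeedShiftSummary(
        n_up=int(up.size),
        n_down=int(down.size),
        median_up=median_up,
        median_down=median_down,
        statistic=stat,
        p_value=p,
        label=label,
        table=sig.reset_index(drop=True),
    )
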