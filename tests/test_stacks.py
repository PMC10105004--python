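import numpy as np
import pandas as pd
import pytest

from riscseed.stacks import (
    call_stacks,
    classify_processed,
    gene_counts,
    gene_processing_summary,
    normalize_expression,
    rank_top_processed,
    top_stack_fraction,
)


def brute_force_stacks(hits, threshold):
    """Oracle: exhaustively group unique sense hits by (gene, start)."""
    groups = {}
    for h in hits:
        if h.unique and h.orientation == "sense":
            groups.setdefault((h.transcript_id, h.start), 0)
            groups[(h.transcript_id, h.start)] += h.count
    return sorted((g, s, c) for (g, s), c in groups.items() if c >= threshold)


class TestCallStacks:
    def test_twelve_reads_one_stack(self, make_hits):
        hits = [make_hits("A" * (18 + i), 4, "G1", 100) for i in range(3)]
        stacks = call_stacks(hits)
        assert len(stacks) == 1
        assert stacks[0].raw_count == 12
        assert stacks[0].start == 100

    def test_nine_reads_below_threshold(self, make_hits):
        hits = [make_hits("A" * 20, 9, "G1", 100)]
        assert call_stacks(hits) == []

    def test_ten_reads_meet_threshold(self, make_hits):
        # "at least 10 raw reads mapping with the same 5' start site"
        hits = [make_hits("A" * 20, 10, "G1", 100)]
        assert len(call_stacks(hits)) == 1

    def test_mixed_starts(self, make_hits):
        hits = (
            [make_hits("A" * (18 + i), 2, "G1", 100) for i in range(5)]  # 10 reads, varied lengths
            + [make_hits("C" * 20, 11, "G1", 130)]
            + [make_hits("G" * 20, 3, "G1", 200)]
        )
        stacks = call_stacks(hits)
        assert [(s.start, s.raw_count) for s in stacks] == [(100, 10), (130, 11)]

    def test_non_unique_and_antisense_ignored(self, make_hits):
        hits = [
            make_hits("A" * 20, 50, "G1", 100, unique=False),
            make_hits("C" * 20, 50, "G1", 100, orientation="antisense"),
        ]
        assert call_stacks(hits) == []

    def test_matches_grouping_oracle_on_random_hits(self, make_hits):
        rng = np.random.default_rng(42)
        for _ in range(20):
            hits = [
                make_hits(
                    "".join(rng.choice(list("ACGT"), size=20)),
                    int(rng.integers(1, 15)),
                    f"G{rng.integers(3)}",
                    int(rng.integers(0, 10)),
                )
                for _ in range(60)
            ]
            called = [(s.gene_id, s.start, s.raw_count) for s in call_stacks(hits)]
            assert called == brute_force_stacks(hits, 10)

    def test_threshold_monotonicity(self, make_hits):
        rng = np.random.default_rng(3)
        hits = [
            make_hits("".join(rng.choice(list("ACGT"), size=20)), int(rng.integers(1, 20)),
                      "G1", int(rng.integers(0, 5)))
            for _ in range(40)
        ]
        previous = None
        for threshold in (1, 5, 10, 20, 40):
            n = len(call_stacks(hits, threshold))
            if previous is not None:
                assert n <= previous
            previous = n


class TestNormalizeExpression:
    def test_rpm_definition(self):
        df = normalize_expression({"s1": {"G1": 50}}, {"s1": 1_000_000})
        assert df.loc["G1", "s1"] == pytest.approx(50.0)

    def test_replicate_mean_and_sem(self):
        df = normalize_expression(
            {"s1": {"G1": 40}, "s2": {"G1": 60}}, {"s1": 1_000_000, "s2": 1_000_000}
        )
        assert df.loc["G1", "mean"] == pytest.approx(50.0)
        assert df.loc["G1", "sem"] == pytest.approx(10.0)

    def test_gene_absent_in_one_sample_is_zero(self):
        df = normalize_expression(
            {"s1": {"G1": 10}, "s2": {}}, {"s1": 1000, "s2": 1000}
        )
        assert df.loc["G1", "s2"] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression({"s1": {"G1": 1}}, {"s1": 0})


class TestClassifyProcessed:
    def _summary(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "biotype", "stack_count", "normalized_reads"]
        )

    @pytest.mark.parametrize(
        "biotype,stacks,rpm,expected",
        [
            ("protein_coding", 3, 15.0, True),
            ("protein_coding", 2, 1000.0, False),
            ("protein_coding", 5, 9.0, False),
            ("lincRNA", 5, 100.0, False),
        ],
    )
    def test_definition(self, biotype, stacks, rpm, expected):
        out = classify_processed(self._summary([("G1", biotype, stacks, rpm)]))
        assert bool(out.loc[0, "processed"]) is expected

    def test_unknown_biotype_excluded_with_warning(self):
        df = self._summary([("G1", np.nan, 5, 100.0), ("G2", "protein_coding", 5, 100.0)])
        with pytest.warns(UserWarning, match="unknown biotype"):
            out = classify_processed(df)
        assert list(out["gene_id"]) == ["G2"]


class TestRankTopProcessed:
    def _summaries(self, genes, stack_counts, rpms):
        return pd.DataFrame(
            {
                "gene_id": genes,
                "biotype": "protein_coding",
                "stack_count": stack_counts,
                "normalized_reads": rpms,
                "processed": True,
            }
        )

    def test_intersection_of_top_ranks(self):
        genes = [f"G{i:02d}" for i in range(12)]
        # G00-G03 engineered to rank top-4 in both datasets
        risc = self._summaries(genes, list(range(12, 0, -1)), list(range(1200, 0, -100)))
        total = self._summaries(genes, list(range(12, 0, -1)), list(range(1200, 0, -100)))
        ann = pd.DataFrame({"gene_id": genes, "biotype": "protein_coding", "is_mirna": False})
        out = rank_top_processed(risc, total, ann, top_n=4)
        assert out == ["G00", "G01", "G02", "G03"]

    def test_mirna_flagged_gene_excluded(self):
        genes = ["G1", "G2"]
        s = self._summaries(genes, [5, 4], [100, 90])
        ann = pd.DataFrame(
            {"gene_id": genes, "biotype": "protein_coding", "is_mirna": [True, False]}
        )
        assert rank_top_processed(s, s, ann, top_n=2) == ["G2"]

    def test_one_location_gene_excluded(self):
        genes = ["G1", "G2"]
        s = self._summaries(genes, [5, 4], [100, 90])
        ann = pd.DataFrame({"gene_id": genes, "biotype": "protein_coding", "is_mirna": False})
        fractions = {"G1": 0.95, "G2": 0.4}
        assert rank_top_processed(s, s, ann, top_n=2, top_stack_fractions=fractions) == ["G2"]


def test_top_stack_fraction(make_hits):
    hits = [
        make_hits("A" * 20, 95, "G1", 100),
        make_hits("C" * 20, 5, "G1", 200),
    ]
    stacks = call_stacks(hits, min_stack_reads=1)
    fractions = top_stack_fraction(stacks, gene_counts(hits))
    assert fractions["G1"] == pytest.approx(0.95)


def test_gene_processing_summary_averages_stack_counts(make_hits):
    hits_a = [make_hits("A" * (18 + i), 10, "G1", s) for i, s in enumerate([10, 50, 90])]
    hits_b = [make_hits("A" * (18 + i), 10, "G1", s) for i, s in enumerate([10, 50])]
    stacks = {"s1": call_stacks(hits_a), "s2": call_stacks(hits_b)}
    rpm = normalize_expression(
        {"s1": gene_counts(hits_a), "s2": gene_counts(hits_b)}, {"s1": 1000, "s2": 1000}
    )
    ann = pd.DataFrame({"gene_id": ["G1"], "biotype": ["protein_coding"]})
    summary = gene_processing_summary(stacks, rpm, ann)
    assert summary.loc[0, "stack_count"] == pytest.approx(2.5)
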