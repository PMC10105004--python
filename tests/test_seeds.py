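import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from riscseed.seeds import (
    SeedProfile,
    SeedViabilityTable,
    all_seeds,
    compare_distributions,
    extract_seed,
    load_seed_table,
    profile_viability,
    round_half_away,
    synthetic_viability_table,
)


class TestExtractSeed:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            # antisense strand of a published non-targeting control siRNA
            ("UAAUCUAACAUGUAAACCAAA", "AATCTA"),
            ("AACUGGGUUGAGA", "ACTGGG"),  # RNA alphabet canonicalized
            ("ACGTACG", "CGTACG"),  # minimal length
        ],
    )
    def test_positions_2_to_7(self, sequence, expected):
        assert extract_seed(sequence) == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            extract_seed("ACGTAC")


def test_seed_space_is_4096_distinct_6mers():
    seeds = all_seeds()
    assert len(seeds) == 4096
    assert len(set(seeds)) == 4096
    assert all(len(s) == 6 and set(s) <= set("ACGT") for s in seeds)


class TestSeedTable:
    def test_published_worked_examples(self, fixture_table):
        assert fixture_table["ACTGGG"] == pytest.approx(37.6)
        assert fixture_table["GACTGG"] == pytest.approx(28.0)
        assert fixture_table["ACAAAG"] == pytest.approx(80.0)
        # RNA-alphabet queries hit the same entries
        assert fixture_table["ACUGGG"] == pytest.approx(37.6)

    def test_synthetic_table_is_complete_and_deterministic(self, full_table):
        assert len(full_table) == 4096
        assert full_table.complete
        again = synthetic_viability_table(0)
        assert again.viability == full_table.viability

    def test_duplicate_after_canonicalization_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("seed,viability\nACUGGG,1\nACTGGG,2\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_seed_table(p)

    def test_invalid_key_and_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("seed,viability\nACTGG,1\n")
        with pytest.raises(ValueError, match="invalid seed"):
            load_seed_table(p)
        p.write_text("kmer,viability\nACTGGG,1\n")
        with pytest.raises(ValueError, match="missing column"):
            load_seed_table(p)


class TestProfileViability:
    def _table(self, mapping):
        return SeedViabilityTable(viability=mapping, provenance="test")

    def test_two_point_weighted_median(self):
        table = self._table({"AAAAAA": 10.0, "CCCCCC": 90.0})
        prof = profile_viability(
            [("TAAAAAACCCCCCCCCCC", 1), ("TCCCCCCAAAAAAAAAAA", 1)], table
        )
        assert prof.median == pytest.approx(50.0)

    def test_integer_binning_rounds_half_away(self):
        table = self._table({"AAAAAA": 37.6, "CCCCCC": 80.0})
        reads = [("TAAAAAAGGGGGGGGGGG", 3), ("TCCCCCCGGGGGGGGGGG", 1)]
        prof = profile_viability(reads, table)
        assert prof.histogram == {38: 3, 80: 1}
        assert round_half_away(2.5) == 3
        assert round_half_away(-2.5) == -3

    def test_single_seed_single_bin(self):
        table = self._table({"AAAAAA": 42.0})
        reads = [("TAAAAAAGGGGGGGGGGG", 5), ("TAAAAAATTTTTTTTTTT", 7)]
        prof = profile_viability(reads, table)
        assert prof.histogram == {42: 12}
        assert prof.n_reads == 12

    def test_length_filter_and_skip_tallies(self):
        table = self._table({"AAAAAA": 42.0})
        reads = [
            ("TAAAAAAGGGGGGGGGGG", 2),  # 18 nt, kept
            ("TAAAAAAGG", 3),  # 9 nt, outside 18-25
            ("TNAAAAAGGGGGGGGGGG", 4),  # seed contains N -> not in table
        ]
        prof = profile_viability(reads, table)
        assert prof.n_reads == 2
        assert prof.skipped_length == 3
        assert prof.skipped_seed == 4

    def test_histogram_mass_equals_contributing_reads(self, full_table):
        rng = np.random.default_rng(7)
        seeds = rng.choice(sorted(full_table.viability), size=50, replace=False)
        reads = [("G" + s + "ACGTACGTACG", int(c)) for s, c in zip(seeds, rng.integers(1, 40, 50))]
        prof = profile_viability(reads, full_table)
        assert sum(prof.histogram.values()) == prof.n_reads == sum(c for _, c in reads)

    @given(shift=st.integers(min_value=-30, max_value=30))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariance_of_median_and_bins(self, shift):
        base = {"AAAAAA": 20.0, "CCCCCC": 55.0, "GGGGGG": 71.0}
        reads = [
            ("TAAAAAAGGGGGGGGGGG", 3),
            ("TCCCCCCGGGGGGGGGGG", 2),
            ("TGGGGGGAAAAAAAAAAA", 5),
        ]
        p0 = profile_viability(reads, SeedViabilityTable(dict(base)))
        p1 = profile_viability(
            reads, SeedViabilityTable({k: v + shift for k, v in base.items()})
        )
        assert p1.median == pytest.approx(p0.median + shift)
        assert p1.histogram == {b + shift: c for b, c in p0.histogram.items()}

    def test_sampled_median_converges_to_table_median(self, full_table):
        # reads drawn with uniform random seeds: the profile median approaches
        # the table's median viability
        rng = np.random.default_rng(11)
        seeds = sorted(full_table.viability)
        draw = rng.integers(0, len(seeds), size=100_000)
        counts = np.bincount(draw, minlength=len(seeds))
        reads = [
            ("G" + s + "ACGTACGTACG", int(c)) for s, c in zip(seeds, counts) if c
        ]
        prof = profile_viability(reads, full_table)
        table_median = float(np.median(list(full_table.viability.values())))
        assert prof.median == pytest.approx(table_median, abs=2.0)


class TestCompareDistributions:
    def test_identical_groups_have_zero_statistic(self):
        h, p = compare_distributions({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert h == 0.0
        assert p == 1.0

    def test_small_worked_case_matches_rank_formula(self):
        # {1,2,3} vs {4,5,6}: rank sums 6 and 15, no ties
        # H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 27/7
        h, p = compare_distributions({"a": [1, 2, 3], "b": [4, 5, 6]})
        assert h == pytest.approx(27 / 7)

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            compare_distributions({"a": [1.0, 2.0], "b": []})
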