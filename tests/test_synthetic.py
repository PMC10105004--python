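import numpy as np
import pandas as pd
import pytest

from riscseed.mapping import build_index, map_readset
from riscseed.preprocess import preprocess_fastq
from riscseed.synthetic import (
    ConfigError,
    Hotspot,
    SyntheticConfig,
    TranscriptSpec,
    background_only_config,
    default_config,
    generate_counts,
    generate_readset,
    generate_transcriptome,
    write_fasta,
)


def small_config(seed=0, **kwargs):
    base = dict(
        rng_seed=seed,
        transcripts=[
            TranscriptSpec("G1", "protein_coding", 300),
            TranscriptSpec("G2", "protein_coding", 250),
            TranscriptSpec("G3", "lincRNA", 200),
        ],
        hotspots={
            "G1": [Hotspot(50, 40.0), Hotspot(150, 30.0)],
            "G2": [Hotspot(60, 35.0)],
        },
        replicates_per_condition=2,
    )
    base.update(kwargs)
    return SyntheticConfig(**base)


class TestTranscriptome:
    def test_deterministic_for_fixed_seed(self, tmp_path):
        cfg = small_config(seed=7)
        t1 = generate_transcriptome(cfg)
        t2 = generate_transcriptome(small_config(seed=7))
        assert t1 == t2
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        write_fasta(t1, p1)
        write_fasta(t2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_one_record_per_gene_dna_alphabet(self):
        tr = generate_transcriptome(small_config())
        assert set(tr) == {"G1", "G2", "G3"}
        assert all(set(s) <= set("ACGT") for s in tr.values())
        assert len(tr["G1"]) == 300

    def test_zero_transcripts_rejected(self):
        with pytest.raises(ConfigError):
            generate_transcriptome(small_config(transcripts=[]))

    def test_hotspot_overrunning_transcript_rejected(self):
        cfg = small_config(hotspots={"G3": [Hotspot(190, 20.0)]})
        with pytest.raises(ConfigError, match="overruns"):
            cfg.validate()


class TestGenerateCounts:
    def test_truth_hotspot_counts_match_reads(self):
        cfg = small_config(seed=3)
        tr = generate_transcriptome(cfg)
        samples, truth = generate_counts(cfg, tr)
        for s in samples:
            sub = truth.reads[truth.reads["sample_id"] == s.sample_id]
            assert int(sub["count"].sum()) == s.total_raw_reads
            hot = truth.hotspot_counts[
                (truth.hotspot_counts["condition"] == s.condition)
                & (truth.hotspot_counts["replicate"] == s.replicate)
            ]
            assert hot["count"].sum() == sub[sub["origin"] == "hotspot"]["count"].sum()

    def test_marginal_hotspot_mean_matches_configuration(self):
        # 200 replicate draws per hotspot; sample mean within 3 standard errors
        cfg = small_config(seed=11, replicates_per_condition=100)
        tr = generate_transcriptome(cfg)
        _, truth = generate_counts(cfg, tr)
        d = cfg.count_noise
        for gene, spots in cfg.hotspots.items():
            for hi, spot in enumerate(spots):
                counts = truth.hotspot_counts[
                    (truth.hotspot_counts["gene_id"] == gene)
                    & (truth.hotspot_counts["hotspot"] == hi)
                ]["count"].to_numpy()
                assert len(counts) == 200
                m = spot.mean_count
                se = np.sqrt((m + d * m**2) / len(counts))
                assert abs(counts.mean() - m) < 3 * se + 1e-9

    def test_null_enrichment_draws_identical_parameters(self):
        # with enrichment 1 the generator never consults the seed table
        cfg = small_config(seed=5, toxic_enrichment=1.0)
        tr = generate_transcriptome(cfg)
        samples, _ = generate_counts(cfg, tr, table=None)
        assert {s.condition for s in samples} == {"A", "B"}

    def test_enrichment_without_table_rejected(self):
        cfg = small_config(toxic_enrichment=4.0)
        tr = generate_transcriptome(cfg)
        with pytest.raises(ConfigError, match="table"):
            generate_counts(cfg, tr)

    def test_toxic_enrichment_scales_condition_b(self, full_table):
        from riscseed.synthetic import toxic_mix_background

        background = toxic_mix_background(full_table, mean_count=200.0)
        toxic_seqs = {b.sequence for b in background
                      if full_table[b.sequence[1:7]] < 30}
        means = {"A": [], "B": []}
        for i in range(20):
            cfg = background_only_config(
                rng_seed=100 + i, background=background, toxic_enrichment=4.0
            )
            tr = generate_transcriptome(cfg)
            samples, _ = generate_counts(cfg, tr, full_table)
            for s in samples:
                toxic_total = sum(c for q, c in s.entries.items() if q in toxic_seqs)
                means[s.condition].append(toxic_total)
        ratio = np.mean(means["B"]) / np.mean(means["A"])
        assert ratio == pytest.approx(4.0, rel=0.1)


class TestGenerateReadset:
    def test_fastq_layout_and_truth_consistency(self, tmp_path):
        cfg = small_config(seed=2)
        tr = generate_transcriptome(cfg)
        paths, truth = generate_readset(cfg, tr, tmp_path)
        assert set(paths) == {"A_1", "A_2", "B_1", "B_2"}
        for sample_id, path in paths.items():
            lines = path.read_text().splitlines()
            assert len(lines) % 4 == 0
            n_records = len(lines) // 4
            assert n_records == truth.sample_total(sample_id)
            for seq_line in lines[1::4]:
                assert seq_line.endswith(cfg.adapter)
                insert = seq_line[: -len(cfg.adapter)][cfg.umi5_len : -cfg.umi3_len]
                assert any(insert in t for t in tr.values()) or any(
                    insert == b.sequence for b in cfg.background
                )

    def test_fixed_seed_bit_identical_fastq(self, tmp_path):
        cfg = small_config(seed=9)
        tr = generate_transcriptome(cfg)
        paths1, _ = generate_readset(cfg, tr, tmp_path / "r1")
        paths2, _ = generate_readset(small_config(seed=9), tr, tmp_path / "r2")
        for sid in paths1:
            assert paths1[sid].read_bytes() == paths2[sid].read_bytes()

    def test_preprocess_and_mapping_recover_every_truth_insert(self, tmp_path):
        cfg = small_config(seed=4)
        tr = generate_transcriptome(cfg)
        paths, truth = generate_readset(cfg, tr, tmp_path)
        index = build_index(tr)
        for sample_id, path in paths.items():
            rs, summary = preprocess_fastq(path, sample_id=sample_id)
            sub = truth.reads[truth.reads["sample_id"] == sample_id]
            expected = dict(zip(sub["sequence"], sub["count"]))
            # collisions between hotspot and background sequences are not
            # expected at these scales
            assert rs.entries == {k: int(v) for k, v in sorted(expected.items())}
            hits = map_readset(rs, index)
            mapped = {h.sequence for h in hits if h.orientation == "sense"}
            hotspot_seqs = set(sub.loc[sub["origin"] == "hotspot", "sequence"])
            assert hotspot_seqs <= mapped
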