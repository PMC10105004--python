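# riscseed

Analysis of Argonaute-pulldown small-RNA sequencing (Ago-RP-Seq): detect
mRNA-derived small RNAs bound to the RNA-induced silencing complex (RISC),
and predict their effect on cell viability through their 6mer seed.

## The problem

Beyond miRNAs, the RISC takes up fragments of processed mRNAs.  Which RNA
a guide silences is determined largely by its **6mer seed** — nucleotides
2–7 — and arrayed screens of all 4,096 possible seeds assign each one a
**seed viability**: the percent cell viability observed when that seed is
expressed in a neutral siRNA backbone (low = toxic; seed-based silencing
of survival-gene networks kills cells, a phenomenon known as DISE).
`riscseed` is for researchers asking, of a pulldown experiment: which
mRNAs are being processed into RISC-loaded fragments, where on the
transcript, how precisely — and is the RISC's overall seed content
shifting toward toxic sequences between two conditions?

## What it computes

- **Preprocessing** of small-RNA FASTQ with the layout
  `4 nt 5' UMI + insert + 2 nt 3' UMI + 3' adapter` into unique-sequence
  count tables, with read-conservation accounting.
- **Exact full-length placement** of reads on a transcript set, both
  strands (for 18–25 nt reads at 100 % identity, substring occurrence *is*
  full-length alignment); BED6 export.  Uniqueness is defined over the
  supplied transcript set.
- **Stacks and processed mRNAs**: a *stack* is ≥ 10 raw reads sharing a
  (gene, 5' start); a *processed mRNA* is protein-coding with ≥ 3 stacks
  and ≥ 10 reads per million (replicate-averaged).  Top processed genes
  are ranked jointly in RISC and total small-RNA data.
- **Seed-viability profiles**: counts-weighted medians/quartiles and the
  integer-binned "seed viability graph" of any read population
  (18–25 nt filter), plus Kruskal–Wallis comparisons between groups.
- **Differential loading**: per unique sequence, an exact conditional
  binomial test of its count split between conditions against the library
  size ratio, BH-adjusted; significant reads are partitioned into up/down
  and their seed-viability medians classify a **toxic shift** of the RISC.
- **Trimming heterogeneity**: 5'-start (−5..+5) and 3'-end profiles around
  the most abundant stacks; read-length distributions.
- **Gene reports**: percent-of-RISC abundance, read-level stack maps,
  query-anchored cluster breakdowns (e.g. which 5'-offset species of an
  shRNA-like site dominate and what seeds they carry), and per-nucleotide
  sequence / dot-bracket pairing tracks.
- **Synthetic data**: a generator emitting ground-truthed FASTQ (implanted
  hotspots with 5' jitter, negative-binomial counts, miRNA-like
  background, tunable toxic-seed enrichment between two conditions), so
  the whole pipeline is testable without any download.

See `docs/methods.md` for the model, defaults and their rationale.

## Worked example

Simulate the default two-condition experiment with 4-fold enrichment of
toxic-seed reads in condition B, then run the core analyses:

```python
import riscseed as rs

table = rs.synthetic_viability_table(0)          # synthetic 4,096-seed table
config = rs.default_config(rng_seed=1, toxic_enrichment=4.0)
transcripts = rs.generate_transcriptome(config)
samples, truth = rs.generate_counts(config, transcripts, table)

index = rs.build_index(transcripts)
hits = {s.sample_id: rs.map_readset(s, index) for s in samples}
stacks = rs.call_stacks(hits["A_1"])
print(f"{len(stacks)} stacks in sample A_1; first: "
      f"{stacks[0].gene_id}:{stacks[0].start} ({stacks[0].raw_count} reads)")

profile = rs.profile_viability(samples[0], table)
print(f"A_1 RISC median seed viability: {profile.median:.1f}% "
      f"(IQR {profile.q1:.1f}-{profile.q3:.1f}, n={profile.n_reads} reads)")

diff = rs.test_differential(samples[:2], samples[2:])
shift = rs.seed_shift_summary(diff, table)
print(f"{shift.n_up} up / {shift.n_down} down at adj. p < 0.05; "
      f"median viability up {shift.median_up:.1f}% vs down {shift.median_down:.1f}% "
      f"-> {shift.label}")
```

Output:

```
17 stacks in sample A_1; first: GENE1:99 (10 reads)
A_1 RISC median seed viability: 76.1% (IQR 60.2-91.0, n=4099 reads)
19 up / 18 down at adj. p < 0.05; median viability up 47.1% vs down 78.4% -> toxic shift
```

Reading this: 17 sites on the toy transcriptome accumulated ≥ 10 reads
with a shared 5' start in sample A_1 (the implanted hotspots plus their
jitter satellites); the RISC's overall seed content is benign (median
76 %); and between conditions, the reads gained by the RISC carry markedly
more toxic seeds (median 47 %) than the reads lost (median 78 %) — the
planted toxic shift is detected.

The same analyses are available from the shell:

```bash
riscseed simulate --seed 1 --out sim/
riscseed run-all run.yaml --out results/   # sample sheet + paths in YAML
```

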