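# Methods

## The analysis in brief

`riscseed` analyses Argonaute-pulldown small-RNA sequencing (Ago-RP-Seq):
sequencing of the small RNAs bound to the RNA-induced silencing complex
(RISC).  Its purpose is to detect and characterize mRNA-derived small RNAs —
fragments of processed mRNAs loaded into the RISC — and to predict their
effect on cell viability through their 6mer seed (guide positions 2–7).
Arrayed screens of all 4,096 possible 6mer seeds assign each seed a
*viability*: the percent cell viability observed when a short RNA carrying
that seed is expressed, averaged across cell lines.  Low viability marks a
toxic seed; death induced this way (seed-based silencing of survival-gene
networks) is known as DISE.

The pipeline stages are:

1. **Preprocess** — raw reads are laid out as `4 nt 5' UMI + insert + 2 nt
   3' UMI + 3' adapter`.  The adapter is removed by exact matching at the
   3' end, UMIs are stripped, and identical sequences are collapsed to
   (sequence → raw count) tables.
2. **Map** — each unique sequence is placed on a supplied transcript set by
   exact full-length substring search, both strands.  For 18–25 nt reads at
   100 % identity over the whole read, substring occurrence and full-length
   alignment coincide, so no aligner heuristics are involved.  A read is
   *unique* when it has exactly one placement across the supplied set.
3. **Stacks** — unique sense hits are grouped by (gene, 5' start).  A group
   with ≥ 10 raw reads is a *stack*; a gene is a *processed mRNA* when it is
   protein-coding, carries ≥ 3 stacks, and has ≥ 10 normalized reads
   (reads per million, averaged across replicates).
4. **Seed viability** — each 18–25 nt read contributes its seed's viability
   once per raw read; distributions are summarized as counts-weighted
   medians/quartiles and as the integer-binned "seed viability graph".
5. **Differential / seed shift** — unique sequences are tested for
   differential RISC loading between two conditions; the seed-viability
   medians of significantly up- versus down-loaded reads summarize whether
   the RISC shifted toward toxic content.
6. **Trimming profiles and gene reports** — 5'-start (−5..+5) and 3'-end
   heterogeneity around the most abundant stacks, read-length
   distributions, per-gene abundance (percent of RISC), read-level stack
   maps, query-anchored cluster breakdowns, and per-nucleotide sequence /
   dot-bracket pairing tracks.

## Statistical model and numeric choices

**Exact matching and uniqueness.**  Uniqueness is defined over the supplied
transcript set — the set is the universe.  When the set is a handful of
ORFs rather than a genome, "unique" means unique among those ORFs; this is
the right reading for targeted per-gene analyses and is stated prominently
because it differs from genome-wide uniqueness.  Coordinates are 0-based
half-open internally and in BED exports.

**Stack threshold.**  The stack definition is "at least 10 raw reads with
the same 5' start" (`min_stack_reads = 10`, configurable).  Stacks are
called per sample on raw counts; for the processed-mRNA call the per-gene
stack count is averaged across replicates, mirroring the use of
replicate-averaged normalized reads.  Replicate pooling is used only for
plotting exports (stack maps, trimming profiles).

**Normalization.**  Reads per million of each sample's total raw reads.
This is a deliberate simplification of model-based library-size
normalization (e.g. TMM): at the scale of these analyses — ratios of one
gene's reads to a library, thresholds of 10 RPM — composition corrections
are second-order, and RPM keeps every number reproducible by hand.  A
caller may substitute per-sample scaling factors before averaging.

**Composite ranking of processed genes.**  "Top processed" genes are ranked
by the average of the stack-count rank and the expression rank (descending,
average ranks on ties, final ties broken lexicographically), intersected
over the top 50 of the RISC and total small-RNA datasets; genes flagged as
miRNA loci are excluded, as are genes whose top stack holds ≥ 90 % of the
gene's reads ("primarily one location"; the 0.9 is configurable, as no
canonical value exists).

**Differential test.**  Per unique sequence with pooled count ≥ 10, the
split of its counts between conditions is tested with an exact conditional
binomial test against the pooled library-size ratio, followed by
Benjamini–Hochberg adjustment over all tested sequences.  This test is
exact under Poisson counts and slightly anti-conservative under strong
overdispersion; with the replicate-level biological variation typical of
cell-line experiments (NB dispersion ~0.01, see below) the realized
false-positive fraction stays well under the nominal level (measured by the
type-I study, below).  The choice of a self-contained exact test over a
dispersion-modelled GLM is deliberate — results are reproducible without a
fitting engine — and the test is an injection point for alternatives.
Fold changes use a 0.5 pseudocount on mean RPM; "up" means more abundant in
the second condition.

**Seed-viability summaries.**  Viability is "printed once per read": all
summary statistics weight unique sequences by their raw counts.  The
integer histogram rounds half away from zero (37.5 → 38, −2.5 → −3), since
"nearest integer" under banker's rounding would bin x.5 values unevenly.
Weighted medians with even total mass take the mean of the two central
values.  Reads outside 18–25 nt and reads whose seed is absent from the
table (e.g. containing N) are skipped and tallied, never silently dropped.
Seed-shift medians in the differential summary are taken over unique
significant sequences (each differentially loaded species counts once);
the Kruskal–Wallis test compares the up and down viability distributions,
with H = 0, p = 1 by convention when every observation is identical (the
rank statistic is undefined there).

**Adapter trimming.**  Matching is exact with a 6 nt minimum overlap.  The
insert/adapter junction is the leftmost position whose entire remaining
suffix matches the adapter (or a ≥ 6 nt prefix of it at the read's 3' end).
Requiring the match to run to the 3' end prevents an adapter-like hexamer
inside the insert or UMI from being mistaken for the junction.
Error-tolerant trimming is out of scope.  UMI deduplication is off by
default (UMIs are stripped and retained); an on-switch collapses records
identical in sequence and both UMIs.

## The synthetic-data generator

The generator emulates the library design the pipeline consumes, not the
biology that produced it.  A toy transcriptome (uniform-random sequences,
a few hundred to a couple thousand nt) carries *hotspots*: implanted
cleavage sites emitting reads whose 5' starts jitter over −5..+5 (default
mass 0.1/0.8/0.1 on −1/0/+1) and whose lengths follow a unimodal 18–25 nt
distribution peaked at 21 nt.  A miRNA-like background contributes
unmapped species at configurable means.  Counts are negative binomial per
unique read variant (hotspot × jitter × length), so the expected hotspot
total equals its configured mean; the default dispersion is 0.01
(biological coefficient of variation 0.1), the standard magnitude for
replicates of a genetically identical cell line.  *Toxic enrichment*
multiplies the expected count, in the second condition only, of every read
whose seed viability falls below a threshold (default 50 %); enrichment is
applied to the mean rather than to drawn counts so the null case
(enrichment 1) is exactly distribution-identical between conditions.
Emitted FASTQ records are `UMI5 + insert + UMI3 + adapter` with constant
'I' qualities (the pipeline ignores qualities).

Default study design: 2 conditions × 2 replicates; six genes (five
protein-coding with 4/3/3/2/1 hotspots at means 30–60 reads, one lincRNA
with 3 hotspots) so the processed-mRNA definition is exercised on both
sides of every clause; 40 background species at mean 80.  Two variant
designs support the validation studies: a jitter-free design
(`sharp_hotspot_config`, hotspot means 50–80, i.e. at least five times the
stack threshold) in which the planted stack and processed labels are
unambiguous — with spread jitter, satellite 5' starts can legitimately form
extra stacks and exact truth matching would be ill-posed — and a
background-only design for differential calibration, optionally with a
deterministic mix of known-toxic and known-viable seeds at mean 150 reads.

What passing tests on synthetic data do **not** show: robustness to
sequencing error, adapter variants, quality artifacts, multimapping at
genome scale, or real secondary-structure-driven processing preferences.
They do show that every algorithmic step (trimming, collapsing, exact
placement, stack grouping, classification, the seed arithmetic, and the
differential machinery) is correct on inputs whose truth is known.

The bundled seed-viability resources are inputs, not authority: the
packaged CSV fixture carries the three published worked-example entries
(ACTGGG 37.6 %, GACTGG 28 %, ACAAAG 80 %) plus synthetic filler rows
(marked in the file), and `synthetic_viability_table()` builds a
deterministic full 4,096-seed synthetic table (G/C-rich seeds skew toxic)
for simulations.  Real analyses must supply a screen-derived table.

## Validation studies and problem sizes

`riscseed.studies` packages the self-checks; the test suite and
`scripts/acceptance.py` run them at these sizes, chosen to make every
Monte-Carlo margin comfortable at interactive runtimes:

- **Mapper/stack oracle equivalence** — 100 randomized fixtures (1–3
  transcripts of 150–400 nt, 18–25 nt queries on both strands) against
  naive scan-every-offset and group-everything oracles.
- **Recovery** — 100 simulations of the jitter-free design: stack
  precision/recall against planted hotspot positions and exact agreement
  of the processed-mRNA classification with planted truth.
- **Type-I calibration** — 200 background-only null datasets (60 species,
  mean 50, enrichment 1): the fraction of sequences reaching BH-adjusted
  significance must stay below 0.05 plus twice its Monte-Carlo standard
  error.
- **Toxic-shift power** — 100 datasets with 4-fold enrichment of 20 toxic
  species against 20 viable species at mean 150: the seed-shift summary
  must report median(up) < median(down) ("toxic shift") in ≥ 95 runs.

## Known limitations

- Exact matching only: one mismatch (SNP, editing, sequencing error) loses
  a read.  This is by design for targeted ORF analyses.
- Uniqueness is relative to the supplied transcript set.
- The binomial split test ignores replicate-level dispersion beyond what
  pooling absorbs; for strongly overdispersed data, plug in a GLM-based
  test at the documented interface point.
- The generator does not simulate sequencing error or genome-scale
  transcriptomes; runtime scales linearly in transcriptome size × unique
  sequences, which is fine for ORF panels but not for a full genome.
- RNA secondary structure is consumed only as dot-bracket strings
  (RNAfold output); folding itself is out of scope, as are GO enrichment
  and figure rendering (the package exports plot-ready tables).
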