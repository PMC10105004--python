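"""Simulation studies: recovery, calibration and power on ground-truthed data.

Each study runs the full relevant slice of the pipeline on freshly
simulated data many times and measures how well the method recovers the
planted truth: stack recovery precision/recall and processed-mRNA
classification accuracy; the type-I error of the differential test under
the null; and the detection rate of a planted toxic seed-viability shift.
These are the package's self-checks, runnable from both the test suite
and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .differential import seed_shift_summary, test_differential
from .mapping import build_index, map_readset
from .seeds import SeedViabilityTable, synthetic_viability_table
from .stacks import (
    call_stacks,
    classify_processed,
    gene_counts,
    gene_processing_summary,
    normalize_expression,
)
from .synthetic import (
    background_only_config,
    generate_counts,
    generate_transcriptome,
    sharp_hotspot_config,
    toxic_mix_background,
)

#: Multiplier keeping per-run seeds distinct across studies; seeds stay < 2^31
#: for the small base seeds used here.
_SEED_STRIDE = 100_003


def _run_seed(rng_seed: int, i: int) -> int:
    return (rng_seed * _SEED_STRIDE + i) % (2**31 - 1)


def stack_recovery_study(
    n_runs: int = 100,
    rng_seed: int = 0,
    min_stack_reads: int = 10,
    min_stacks: int = 3,
    min_norm_reads: float = 10.0,
) -> dict:
    """Recover implanted hotspots as stacks and genes as processed mRNAs.

    Each run simulates the jitter-free recovery design
    (:func:`riscseed.synthetic.sharp_hotspot_config`, hotspot means 50-80
    reads), maps the reads, calls stacks per sample and classifies
    processed mRNAs from one condition's replicates.  A called stack is a
    true positive when a hotspot was planted at exactly its (gene, start);
    the expected processed label of a gene is ``protein_coding`` with at
    least ``min_stacks`` planted hotspots (normalized reads are far above
    threshold by design).
    """
    tp = fp = fn = 0
    genes_checked = genes_correct = 0
    for i in range(n_runs):
        cfg = sharp_hotspot_config(_run_seed(rng_seed, i))
        transcripts = generate_transcriptome(cfg)
        samples, _ = generate_counts(cfg, transcripts)
        index = build_index(transcripts)
        hits = {s.sample_id: map_readset(s, index) for s in samples}
        stacks_by_sample = {
            sid: call_stacks(h, min_stack_reads) for sid, h in hits.items()
        }
        true_sites = {
            (g, h.start) for g, spots in cfg.hotspots.items() for h in spots
        }
        for stacks in stacks_by_sample.values():
            called = {(s.gene_id, s.start) for s in stacks}
            tp += len(called & true_sites)
            fp += len(called - true_sites)
            fn += len(true_sites - called)

        condition = cfg.conditions[0]
        sids = [s.sample_id for s in samples if s.condition == condition]
        counts = {sid: gene_counts(hits[sid]) for sid in sids}
        totals = {
            sid: next(s for s in samples if s.sample_id == sid).total_raw_reads
            for sid in sids
        }
        rpm = normalize_expression(counts, totals)
        summary = gene_processing_summary(
            {sid: stacks_by_sample[sid] for sid in sids}, rpm, cfg.annotation_frame()
        )
        summary = classify_processed(summary, min_stacks, min_norm_reads)
        biotypes = {t.gene_id: t.biotype for t in cfg.transcripts}
        for row in summary.itertuples():
            expected = (
                biotypes[row.gene_id] == "protein_coding"
                and len(cfg.hotspots.get(row.gene_id, [])) >= min_stacks
            )
            genes_checked += 1
            genes_correct += int(bool(row.processed) == expected)

    return {
        "n_runs": n_runs,
        "precision": tp / (tp + fp) if tp + fp else float("nan"),
        "recall": tp / (tp + fn) if tp + fn else float("nan"),
        "classification_accuracy": genes_correct / genes_checked if genes_checked else float("nan"),
        "n_genes_checked": genes_checked,
    }


def null_differential_study(
    n_runs: int = 200,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Type-I error of the differential test with no planted enrichment.

    Simulates background-only datasets with ``toxic_enrichment = 1`` (both
    conditions drawn from identical distributions) and counts sequences
    reaching BH-adjusted significance.  Returns the rejected fraction and
    the Monte-Carlo bound ``alpha + 2 * sqrt(alpha (1-alpha) / n_tested)``
    it should stay under.
    """
    n_sig = n_tested = 0
    for i in range(n_runs):
        cfg = background_only_config(_run_seed(rng_seed, i), toxic_enrichment=1.0)
        transcripts = generate_transcriptome(cfg)
        samples, _ = generate_counts(cfg, transcripts)
        group_a = [s for s in samples if s.condition == cfg.conditions[0]]
        group_b = [s for s in samples if s.condition == cfg.conditions[1]]
        diff = test_differential(group_a, group_b)
        n_tested += len(diff)
        n_sig += int((diff["adj_p"] < alpha).sum())
    fraction = n_sig / n_tested if n_tested else 0.0
    bound = alpha + 2.0 * float(np.sqrt(alpha * (1 - alpha) / max(n_tested, 1)))
    return {
        "n_runs": n_runs,
        "n_tested": n_tested,
        "fraction_significant": fraction,
        "bound": bound,
    }


def toxic_shift_study(
    n_runs: int = 100,
    rng_seed: int = 0,
    toxic_enrichment: float = 4.0,
    mean_count: float = 150.0,
    table: SeedViabilityTable | None = None,
    alpha: float = 0.05,
) -> dict:
    """Power to detect a planted toxic shift in RISC composition.

    Each run enriches reads with toxic seeds ``toxic_enrichment``-fold in
    condition B over a background of known-toxic and known-viable species
    at ``mean_count`` reads each, then checks that the seed-shift summary
    reports median(up) < median(down) ("toxic shift").
    """
    if table is None:
        table = synthetic_viability_table(rng_seed)
    background = toxic_mix_background(table, mean_count=mean_count)
    detected = 0
    medians_up: list[float] = []
    medians_down: list[float] = []
    for i in range(n_runs):
        cfg = background_only_config(
            _run_seed(rng_seed, i),
            background=background,
            toxic_enrichment=toxic_enrichment,
        )
        transcripts = generate_transcriptome(cfg)
        samples, _ = generate_counts(cfg, transcripts, table)
        group_a = [s for s in samples if s.condition == cfg.conditions[0]]
        group_b = [s for s in samples if s.condition == cfg.conditions[1]]
        diff = test_differential(group_a, group_b)
        shift = seed_shift_summary(diff, table, alpha)
        if shift.label == "toxic shift":
            detected += 1
        if shift.median_up is not None:
            medians_up.append(shift.median_up)
        if shift.median_down is not None:
            medians_down.append(shift.median_down)
    return {
        "n_runs": n_runs,
        "detection_rate": detected / n_runs,
        "mean_median_up": float(np.mean(medians_up)) if medians_up else None,
        "mean_median_down": float(np.mean(medians_down)) if medians_down else None,
    }
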