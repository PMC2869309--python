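"""Reusable benchmark experiments over the synthetic generator.

Each function runs one study — origin recovery, planted-island detection,
divergence recovery, a qPCR reconstruction — at its stated conditions and
returns a plain dict of results.  The analysis drivers, the test suite and
the acceptance script all call these functions rather than re-implementing
the loops.
"""

from __future__ import annotations

import numpy as np

from .islands import evaluate_criteria
from .origin import call_origin, find_dnaa_boxes, gc_skew_profile
from .orthology import best_hits, classify_orthologs, transfer_annotations
from .qpcr import QpcrSample, fold_induction
from .repeats import classify_repeat_context, find_degenerate_palindromes
from .simulate import (
    GenomeConfig,
    IslandSpec,
    derive_sister_genome,
    generate_genome,
)
from .synteny import detect_syntons, nonsyntenic_regions, synton_stats

ORIGIN_WINDOW = 4000  # coarse window for small synthetic replicons


def origin_recovery(
    n_seeds: int = 20,
    seed0: int = 0,
    length: int = 200_000,
    skew_amplitude: float = 0.06,
    window: int = ORIGIN_WINDOW,
) -> dict:
    """Planted-oriC localization error across seeds, in bp and windows."""
    errors = []
    for i in range(n_seeds):
        cfg = GenomeConfig(length=length, n_genes=120,
                           skew_amplitude=skew_amplitude)
        g, t = generate_genome(cfg, seed=seed0 + i)
        call = call_origin(gc_skew_profile(g.record, window))
        L = g.record.length
        err = min((call.oriC - t.oriC) % L, (t.oriC - call.oriC) % L)
        errors.append(err)
    return {
        "errors_bp": errors,
        "max_error_windows": max(errors) / window,
        "mean_error_bp": float(np.mean(errors)),
        "n_seeds": n_seeds,
        "window": window,
    }


def _plain_deletion_runs(genome, truth, rng, n_runs=5, run_len=4):
    """Pick unique-gene runs with no island signal, for precision testing."""
    order = [f.locus_tag for f in genome.cds()]
    island_tags = {tag for isl in truth.islands for tag in isl["genes"]}
    runs = []
    free = [i for i, tag in enumerate(order)
            if tag not in island_tags and 5 < i < len(order) - 10]
    while len(runs) < n_runs and free:
        i = int(rng.choice(free))
        run = order[i : i + run_len]
        if (
            any(tag in island_tags for tag in run)
            or any(set(run) & set(r) for r in runs)
            or len(run) < run_len
        ):
            free.remove(i)
            continue
        runs.append(run)
        free.remove(i)
    return runs


def island_benchmark(
    n_seeds: int = 20,
    seed0: int = 100,
    n_islands: int = 5,
    n_plain: int = 5,
    divergence: float = 0.85,
) -> dict:
    """Planted-island recall/precision at default criteria thresholds.

    Each replicate plants ``n_islands`` islands (full signal set) and
    ``n_plain`` plain unique-gene runs (absence from the comparator only);
    the island caller must separate the two.
    """
    tp = fp = fn = 0
    for i in range(n_seeds):
        cfg = GenomeConfig(
            length=260_000, n_genes=170,
            islands=tuple(IslandSpec(n_genes=6) for _ in range(n_islands)),
        )
        g, t = generate_genome(cfg, seed=seed0 + i)
        rng = np.random.default_rng(seed0 + i)
        plain = _plain_deletion_runs(g, t, rng, n_runs=n_plain)
        deletions = tuple(tag for run in plain for tag in run)
        sister, _ = derive_sister_genome(
            g, t, divergence=divergence, deletions=deletions, seed=seed0 + i + 7
        )
        pairs = classify_orthologs(best_hits(g, sister), best_hits(sister, g))
        regions = nonsyntenic_regions(g, pairs)
        island_sets = {frozenset(isl["genes"]) for isl in t.islands}
        for reg in regions:
            ev = evaluate_criteria(reg, g)
            planted = frozenset(reg.genes) in island_sets
            if ev.is_island and planted:
                tp += 1
            elif ev.is_island and not planted:
                fp += 1
            elif planted and not ev.is_island:
                fn += 1
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "recall": tp / (tp + fn) if tp + fn else 0.0,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "n_seeds": n_seeds,
    }


def divergence_recovery(
    target_identity: float = 0.85, seed: int = 3, length: int = 200_000,
    n_genes: int = 150,
) -> dict:
    """Mean realized alignment identity of BBH pairs vs the planted target."""
    cfg = GenomeConfig(length=length, n_genes=n_genes)
    g, t = generate_genome(cfg, seed=seed)
    sister, st = derive_sister_genome(g, t, divergence=target_identity,
                                      seed=seed + 1)
    pairs = classify_orthologs(best_hits(g, sister), best_hits(sister, g))
    idents = [p.identity for p in pairs]
    return {
        "target_identity_pct": 100 * target_identity,
        "mean_alignment_identity_pct": float(np.mean(idents)),
        "n_pairs": len(pairs),
    }


def qpcr_reconstruction(seed: int = 0, efficiency: float = 2.0) -> dict:
    """Simulate replicate Ct measurements for planted fold inductions and
    recompute them through the delta-delta-Ct pipeline.

    Planted folds mirror a sucrose-induction experiment: a strongly induced
    operon gene, a moderately induced one, and the unchanged reference.
    """
    rng = np.random.default_rng(seed)
    planted = {"budA": 223.0, "budC": 73.5, "scrB": 13.0}
    noise_sd = 0.03
    samples = {}
    ref_base = 18.0
    for cond in ("treatment", "control"):
        samples[("recA", cond)] = QpcrSample(
            gene="recA", condition=cond, timepoint=8.0,
            ct=tuple(ref_base + rng.normal(0, noise_sd, size=3)),
        )
    recovered = {}
    for gene, fold in planted.items():
        ct_ctl = 26.0
        dct = -np.log(fold) / np.log(efficiency)
        t_trt = QpcrSample(
            gene=gene, condition="treatment", timepoint=8.0,
            ct=tuple(ct_ctl + dct + rng.normal(0, noise_sd, size=3)),
        )
        t_ctl = QpcrSample(
            gene=gene, condition="control", timepoint=8.0,
            ct=tuple(ct_ctl + rng.normal(0, noise_sd, size=3)),
        )
        f = fold_induction(t_trt, t_ctl, samples[("recA", "treatment")],
                           samples[("recA", "control")], efficiency=efficiency)
        recovered[gene] = (f.fold, f.sd)
    max_rel_err = max(
        abs(recovered[g][0] - planted[g]) / planted[g] for g in planted
    )
    return {"planted": planted, "recovered": recovered,
            "max_relative_error": max_rel_err}


def end_to_end(seed: int = 1) -> dict:
    """Full pipeline on one generated genome pair; all headline quantities."""
    from .census import census
    from .genome_io import coding_density, gc_content

    cfg = GenomeConfig(
        length=260_000, n_genes=170,
        islands=(IslandSpec(n_genes=8), IslandSpec(n_genes=6),
                 IslandSpec(n_genes=7)),
    )
    g, t = generate_genome(cfg, seed=seed)
    sister, st = derive_sister_genome(g, t, divergence=0.85, seed=seed + 1)

    prof = gc_skew_profile(g.record, ORIGIN_WINDOW)
    call = call_origin(prof)
    L = g.record.length
    ori_err = min((call.oriC - t.oriC) % L, (t.oriC - call.oriC) % L)
    boxes = find_dnaa_boxes(g.record, region=((t.oriC - 2000) % L,
                                              (t.oriC + 4000) % L))

    hits = classify_repeat_context(find_degenerate_palindromes(g.record), g)
    planted_starts = {r["start"] for r in t.repeats}
    recovered_repeats = sum(1 for h in hits if h.start in planted_starts)

    pairs = classify_orthologs(best_hits(g, sister), best_hits(sister, g))
    correct = sum(1 for p in pairs if st.ortholog_map.get(p.a) == p.b)
    syntons = detect_syntons(g, sister, pairs)
    stats = synton_stats(syntons, g)
    regions = nonsyntenic_regions(g, pairs)
    evs = [evaluate_criteria(r, g) for r in regions]
    island_sets = {frozenset(isl["genes"]) for isl in t.islands}
    tp = sum(1 for e in evs if e.is_island and frozenset(e.region.genes) in island_sets)
    fp = sum(1 for e in evs
             if e.is_island and frozenset(e.region.genes) not in island_sets)
    _, n_transferred = transfer_annotations(pairs, source=sister, target=g)

    rep = census(g)
    return {
        "genome_length": L,
        "gc_content_pct": gc_content(g.record),
        "coding_density_pct": coding_density(g),
        "origin_error_bp": ori_err,
        "dnaa_boxes_in_oric_region": len(boxes),
        "dnaa_boxes_planted": len(t.dnaa_boxes),
        "repeats_planted": len(t.repeats),
        "repeats_recovered": recovered_repeats,
        "repeats_found": len(hits),
        "ortholog_pairs": len(pairs),
        "ortholog_pairs_correct": correct,
        "mean_identity_pct": float(np.mean([p.identity for p in pairs])),
        "synton_count": stats["synton_count"],
        "expected_synton_count": len(st.expected_syntons),
        "mean_genes_per_synton": stats["mean_genes_per_synton"],
        "region_count": len(regions),
        "expected_region_count": len(st.expected_regions),
        "islands_called": tp + fp,
        "islands_planted": len(t.islands),
        "islands_correct": tp,
        "annotation_transfers": n_transferred,
        "census_cds": rep.counts["CDS"],
        "census_ta_pairs": rep.counts["TA_pairs"],
    }
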