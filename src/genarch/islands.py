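"""Rule-based genomic-island classification over non-syntenic regions.

Horizontally acquired islands tend to carry a site-specific recombinase at
one extremity, insert at tRNA loci, be flanked by insertion-sequence (IS)
elements, deviate in base/codon composition from the host genome, be
enriched in hypothetical genes, and act as hotspots for mobile genetic
elements (MGEs).  Each candidate region is scored against these criteria
(annotation keywords for the gene-based ones, a codon-usage distance or GC
delta for composition) and called an island when at least ``min_criteria``
of them hold.  Conservation across unrelated hosts needs extra genome
panels and is excluded (NA) unless such panels are supplied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genome_io import AnnotatedGenome, Feature
from .synteny import NonSyntenicRegion

RECOMBINASE_LEXICON = ("integrase", "recombinase", "resolvase")
IS_LEXICON = ("transposase", "insertion sequence", "is element", "transposon")
MGE_LEXICON = RECOMBINASE_LEXICON + IS_LEXICON + ("phage", "mobile element")
HYPOTHETICAL_LEXICON = ("hypothetical", "unknown function", "uncharacterized")

CODONS = tuple(
    "".join(c) for c in itertools.product("TCAG", repeat=3)
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}


@dataclass
class IslandConfig:
    """Tunable thresholds for the criteria."""

    flank_window: int = 500        # bp around boundaries searched for tRNA
    extremity_genes: int = 2       # genes at each end counted as "extremity"
    gc_delta: float = 2.5          # GC percentage-point shift
    codon_threshold: float = 0.35  # Manhattan distance over codon frequencies
    enrich_delta: float = 0.25     # hypothetical-fraction excess
    mge_min_genes: int = 2
    min_criteria: int = 3
    recombinase_lexicon: tuple = RECOMBINASE_LEXICON
    is_lexicon: tuple = IS_LEXICON
    mge_lexicon: tuple = MGE_LEXICON
    hypothetical_lexicon: tuple = HYPOTHETICAL_LEXICON


@dataclass
class IslandEvaluation:
    region: NonSyntenicRegion
    criteria: dict[str, bool | None] = field(default_factory=dict)
    evidence: dict[str, str] = field(default_factory=dict)
    is_island: bool = False

    @property
    def n_met(self) -> int:
        return sum(1 for v in self.criteria.values() if v is True)


def _matches(product: str, lexicon) -> bool:
    p = product.lower()
    return any(term in p for term in lexicon)


def codon_frequencies(cds_seqs: list[str]) -> tuple[np.ndarray, int]:
    """64-codon frequency vector over a set of coding sequences."""
    counts = np.zeros(64, dtype=float)
    total = 0
    for nt in cds_seqs:
        for i in range(0, len(nt) - len(nt) % 3, 3):
            idx = _CODON_INDEX.get(nt[i : i + 3])
            if idx is not None:
                counts[idx] += 1
                total += 1
    if total:
        counts /= total
    return counts, total


def codon_usage_deviation(
    region_cds: list[str],
    genome_cds: list[str],
    threshold: float = 0.35,
    min_codons: int = 100,
) -> tuple[float | None, bool | None]:
    """Manhattan distance between region and genome codon-frequency vectors.

    The statistic ranges over [0, 2].  Below ``min_codons`` region codons the
    estimate is too noisy and (None, None) is returned so the criterion can
    be excluded rather than guessed.
    """
    region_freq, n_region = codon_frequencies(region_cds)
    genome_freq, n_genome = codon_frequencies(genome_cds)
    if n_region < min_codons or n_genome < min_codons:
        return None, None
    stat = float(np.abs(region_freq - genome_freq).sum())
    return stat, stat >= threshold


def _region_features(
    region: NonSyntenicRegion, genome: AnnotatedGenome
) -> list[Feature]:
    return [genome.by_tag(t) for t in region.genes]


def _span_contains(start: int, end: int, pos: int, L: int) -> bool:
    if start <= end:
        return start <= pos < end
    return pos >= start or pos < end  # wraps


def evaluate_criteria(
    region: NonSyntenicRegion,
    genome: AnnotatedGenome,
    prophages: list[tuple[int, int]] | None = None,
    config: IslandConfig | None = None,
) -> IslandEvaluation:
    """Score one candidate region against the island criteria.

    ``prophages`` are externally predicted prophage intervals; overlap with
    the region counts toward the MGE-hotspot criterion.
    """
    cfg = config or IslandConfig()
    prophages = prophages or []
    L = genome.record.length
    ev = IslandEvaluation(region=region)
    feats = _region_features(region, genome)
    cds = [f for f in feats if f.kind == "CDS"]

    # --- recombinase / IS at the extremities (first/last genes +- one flank)
    k = cfg.extremity_genes
    extremity = list(feats[:k]) + list(feats[-k:])
    for flank_tag in (region.flank_left, region.flank_right):
        if flank_tag:
            try:
                extremity.append(genome.by_tag(flank_tag))
            except KeyError:
                pass
    rec_hits = [f.locus_tag for f in extremity
                if _matches(f.product, cfg.recombinase_lexicon)]
    ev.criteria["recombinase_at_extremity"] = bool(rec_hits)
    ev.evidence["recombinase_at_extremity"] = ",".join(sorted(set(rec_hits)))

    is_hits = [f.locus_tag for f in extremity if _matches(f.product, cfg.is_lexicon)]
    ev.criteria["flanking_IS_elements"] = bool(is_hits)
    ev.evidence["flanking_IS_elements"] = ",".join(sorted(set(is_hits)))

    # --- tRNA insertion site near either boundary
    w = cfg.flank_window
    trna_hits = []
    for t in genome.features:
        if t.kind != "tRNA":
            continue
        for boundary in (region.start, region.end):
            if (
                _span_contains((boundary - w) % L, (boundary + w) % L, t.start, L)
                or _span_contains((boundary - w) % L, (boundary + w) % L,
                                  max(t.end - 1, 0), L)
            ):
                trna_hits.append(t.locus_tag or t.product)
                break
    ev.criteria["tRNA_insertion_site"] = bool(trna_hits)
    ev.evidence["tRNA_insertion_site"] = ",".join(sorted(set(trna_hits)))

    # --- composition deviation: codon usage OR GC shift (either suffices)
    region_seqs = [genome.feature_sequence(f) for f in cds]
    genome_seqs = [genome.feature_sequence(f) for f in genome.cds()]
    stat, codon_flag = codon_usage_deviation(
        region_seqs, genome_seqs, threshold=cfg.codon_threshold
    )
    gc_flag = None
    region_nt = "".join(region_seqs)
    if region_nt:
        region_gc = 100.0 * (region_nt.count("G") + region_nt.count("C")) / len(region_nt)
        genome_nt = "".join(genome_seqs)
        genome_gc = 100.0 * (genome_nt.count("G") + genome_nt.count("C")) / len(genome_nt)
        gc_flag = abs(region_gc - genome_gc) >= cfg.gc_delta
    if codon_flag is None and gc_flag is None:
        ev.criteria["composition_deviation"] = None
        ev.evidence["composition_deviation"] = "insufficient coding sequence"
    else:
        ev.criteria["composition_deviation"] = bool(codon_flag) or bool(gc_flag)
        ev.evidence["composition_deviation"] = (
            f"codon_distance={stat:.3f}" if stat is not None else ""
        ) + (f" gc_delta_flag={gc_flag}" if gc_flag is not None else "")

    # --- hypothetical enrichment relative to the whole genome
    if cds:
        genome_cds = genome.cds()
        region_frac = sum(
            _matches(f.product, cfg.hypothetical_lexicon) for f in cds
        ) / len(cds)
        genome_frac = sum(
            _matches(f.product, cfg.hypothetical_lexicon) for f in genome_cds
        ) / len(genome_cds)
        ev.criteria["hypothetical_enrichment"] = (
            region_frac - genome_frac >= cfg.enrich_delta
        )
        ev.evidence["hypothetical_enrichment"] = (
            f"region={region_frac:.2f} genome={genome_frac:.2f}"
        )
    else:
        ev.criteria["hypothetical_enrichment"] = False
        ev.evidence["hypothetical_enrichment"] = "region has no CDS"

    # --- MGE hotspot: MGE-lexicon genes inside, or prophage overlap
    mge_genes = [f.locus_tag for f in feats if _matches(f.product, cfg.mge_lexicon)]
    prophage_overlap = any(
        _span_contains(region.start, region.end, ps, L)
        or _span_contains(ps, pe, region.start, L)
        for ps, pe in prophages
    )
    ev.criteria["MGE_hotspot"] = len(mge_genes) >= cfg.mge_min_genes or prophage_overlap
    ev.evidence["MGE_hotspot"] = ",".join(mge_genes) + (
        " prophage_overlap" if prophage_overlap else ""
    )

    # --- by construction for regions coming out of the synteny stage
    ev.criteria["synteny_absence"] = True
    ev.evidence["synteny_absence"] = "region defined by absence from comparator"

    # --- needs external genome panels; excluded from the count when absent
    ev.criteria["cross_host_conservation"] = None
    ev.evidence["cross_host_conservation"] = "not evaluated (no extra genomes)"

    ev.is_island = ev.n_met >= cfg.min_criteria
    return ev


def classify_islands(
    evaluations: list[IslandEvaluation], min_criteria: int = 3
) -> list[IslandEvaluation]:
    """Apply the >= min_criteria rule and return evaluations with is_island set."""
    for ev in evaluations:
        ev.is_island = ev.n_met >= min_criteria
    return evaluations


def island_summary(evaluations: list[IslandEvaluation]) -> dict:
    return {
        "regions_evaluated": len(evaluations),
        "islands_called": sum(ev.is_island for ev in evaluations),
    }


def evaluation_table(evaluations: list[IslandEvaluation]):
    """One row per region, one column per criterion, plus n_met / is_island."""
    import pandas as pd

    rows = []
    for ev in evaluations:
        row = {"region_id": ev.region.id, "start": ev.region.start,
               "end": ev.region.end, "n_genes": ev.region.n_genes}
        for name, val in ev.criteria.items():
            row[name] = "NA" if val is None else bool(val)
        row["n_met"] = ev.n_met
        row["is_island"] = ev.is_island
        rows.append(row)
    return pd.DataFrame(rows)
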