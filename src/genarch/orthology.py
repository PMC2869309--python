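"""Pairwise protein comparison, bidirectional best hits, and threshold rules
for orthology and annotation transfer.

Protein pairs are scored by Smith-Waterman local alignment (BLOSUM62,
affine gaps: open 11, extend 1).  A pair is an ortholog candidate when each
protein is the other's best hit (BBH).  Annotation transfer follows a
two-tier rule: >= 80% identity on >= 80% of both lengths, or, for genes
inside conserved synteny blocks, >= 70% identity on >= 80% of both lengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import AnnotatedGenome, Feature, PseudogeneWarning, translate_cds

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinHit:
    query: str
    subject: str
    identity: float      # percent over aligned columns
    coverage_q: float    # percent of query length inside the aligned span
    coverage_s: float
    score: float


@dataclass(frozen=True)
class OrthologPair:
    a: str
    b: str
    identity: float
    coverage_a: float
    coverage_b: float
    bidirectional: bool = True
    syntenic: bool = False
    transfer_eligible: bool = False


def _aligner() -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11.0
    aln.extend_gap_score = -1.0
    return aln


def align_proteins(p: str, q: str):
    """Local alignment of two proteins.

    Returns ``(identity_pct, coverage_p_pct, coverage_q_pct, score)`` where
    identity is matches over aligned columns (gap columns inside the local
    alignment count in the denominator) and coverage is the aligned span of
    each sequence over its full length.
    """
    p, q = p.upper(), q.upper()
    if not p or not q:
        raise ValueError("empty protein sequence")
    bad = (set(p) | set(q)) - _AA
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    aln = _aligner()
    alignment = aln.align(p, q)[0]
    score = float(alignment.score)
    counts = alignment.counts()  # gaps, identities, mismatches
    columns = counts.gaps + counts.identities + counts.mismatches
    identity = 100.0 * counts.identities / columns if columns else 0.0
    p_aligned = alignment.aligned[0]
    q_aligned = alignment.aligned[1]
    span_p = int(p_aligned[-1][1] - p_aligned[0][0]) if len(p_aligned) else 0
    span_q = int(q_aligned[-1][1] - q_aligned[0][0]) if len(q_aligned) else 0
    return identity, 100.0 * span_p / len(p), 100.0 * span_q / len(q), score


def proteome(genome: AnnotatedGenome) -> dict[str, str]:
    """locus_tag -> translated protein for every CDS with a translation."""
    prots = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PseudogeneWarning)
        for f in genome.cds():
            if not f.locus_tag:
                continue
            aa = translate_cds(genome, f)
            if aa:
                prots[f.locus_tag] = aa
    return prots


def _kmer_set(p: str, k: int) -> set[str]:
    return {p[i : i + k] for i in range(len(p) - k + 1)}


def best_hits(
    A: AnnotatedGenome,
    B: AnnotatedGenome,
    k: int = 5,
    min_shared_kmers: int = 2,
    prefilter: bool = True,
) -> list[ProteinHit]:
    """Best hit in B for every CDS of A.

    A shared-k-mer prefilter restricts alignment to subjects sharing at least
    ``min_shared_kmers`` k-mers with the query; any pair at >= 70% identity
    over >= 80% coverage shares far more than that, so the filter cannot drop
    a threshold-passing ortholog (checked against the unfiltered scan in the
    test suite).  Ties on score resolve to the lexicographically smallest
    subject tag.
    """
    prot_a = proteome(A)
    prot_b = proteome(B)
    if not prot_a or not prot_b:
        raise ValueError("both genomes need translatable CDS")
    kmers_b: dict[str, set[str]] = {t: _kmer_set(s, k) for t, s in prot_b.items()}
    hits = []
    for qa, pa in sorted(prot_a.items()):
        if prefilter:
            ka = _kmer_set(pa, k)
            cands = [
                t for t, kb in kmers_b.items()
                if len(ka & kb) >= min_shared_kmers
            ]
        else:
            cands = list(prot_b)
        best = None
        for tb in sorted(cands):
            ident, cov_q, cov_s, score = align_proteins(pa, prot_b[tb])
            if best is None or score > best.score:
                best = ProteinHit(qa, tb, ident, cov_q, cov_s, score)
        if best is not None:
            hits.append(best)
    return hits


def classify_orthologs(
    hits_ab: list[ProteinHit],
    hits_ba: list[ProteinHit],
    syntenic_tags: set[str] | None = None,
    identity_strict: float = 80.0,
    identity_syntenic: float = 70.0,
    min_coverage: float = 80.0,
) -> list[OrthologPair]:
    """Bidirectional best hits with the two-tier transfer rule.

    ``syntenic_tags`` holds A-side locus tags inside synteny blocks; the
    relaxed identity tier applies only to those.  Coverage is enforced on
    both proteins (the stricter mutual reading of "80% of their length").
    """
    syntenic_tags = syntenic_tags or set()
    fwd = {h.query: h for h in hits_ab}
    rev = {h.query: h for h in hits_ba}
    pairs = []
    for a, h in sorted(fwd.items()):
        back = rev.get(h.subject)
        if back is None or back.subject != a:
            continue
        syntenic = a in syntenic_tags
        min_cov = min(h.coverage_q, h.coverage_s)
        eligible = (h.identity >= identity_strict and min_cov >= min_coverage) or (
            syntenic and h.identity >= identity_syntenic and min_cov >= min_coverage
        )
        pairs.append(
            OrthologPair(
                a=a, b=h.subject, identity=h.identity,
                coverage_a=h.coverage_q, coverage_b=h.coverage_s,
                bidirectional=True, syntenic=syntenic,
                transfer_eligible=eligible,
            )
        )
    return pairs


def transfer_annotations(
    pairs: list[OrthologPair],
    source: AnnotatedGenome,
    target: AnnotatedGenome,
) -> tuple[AnnotatedGenome, int]:
    """Copy product strings from source to target for transfer-eligible pairs.

    ``pairs`` map target tags (side a) to source tags (side b).  When several
    eligible sources compete for one target the highest identity wins; an
    exact tie transfers nothing for that target.  Returns the rewritten
    genome and the number of transfers; provenance is recorded in a
    ``transferred_from`` qualifier.
    """
    by_target: dict[str, list[OrthologPair]] = {}
    for p in pairs:
        if p.transfer_eligible:
            by_target.setdefault(p.a, []).append(p)
    chosen: dict[str, OrthologPair] = {}
    for tag, plist in by_target.items():
        plist.sort(key=lambda p: (-p.identity, p.b))
        if len(plist) > 1 and plist[0].identity == plist[1].identity:
            continue  # ambiguous; leave target annotation untouched
        chosen[tag] = plist[0]
    source_products = {f.locus_tag: f.product for f in source.cds()}
    new_features = []
    n_transferred = 0
    for f in target.features:
        p = chosen.get(f.locus_tag) if f.kind == "CDS" else None
        if p is not None and p.b in source_products:
            new_features.append(
                replace(
                    f,
                    product=source_products[p.b],
                    qualifiers=f.qualifiers + (("transferred_from", p.b),),
                )
            )
            n_transferred += 1
        else:
            new_features.append(f)
    out = AnnotatedGenome(
        record=target.record, features=new_features, source=target.source
    )
    return out, n_transferred
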