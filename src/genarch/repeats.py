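"""Degenerate palindromic repeat discovery and gene-context classification.

The repeat family of interest is a perfect inverted repeat with a fixed stem
(default CCCTCTCCC) and a free 2-3 nt loop, i.e. ``stem + N{2,3} +
revcomp(stem)``.  Because the pattern is its own reverse complement, a
forward-strand scan enumerates every physical locus exactly once.  Hits
clustered just downstream of gene stops are putative rho-independent
transcription terminators.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .genome_io import AnnotatedGenome, SeqRecord, revcomp

CONTEXT_3PRIME = "three_prime_proximal"
CONTEXT_INTRAGENIC = "intragenic"
CONTEXT_OTHER = "intergenic_other"


@dataclass(frozen=True)
class RepeatHit:
    """One stem-loop locus: ``[start, end)`` spans stem + loop + stem'."""

    start: int
    end: int
    stem: str
    loop: str
    context: str = CONTEXT_OTHER
    nearest_gene: str | None = None
    cluster_id: int | None = None

    def __post_init__(self):
        if self.end - self.start != 2 * len(self.stem) + len(self.loop):
            raise ValueError("hit span inconsistent with stem/loop lengths")


def find_degenerate_palindromes(
    record: SeqRecord,
    stem: str = "CCCTCTCCC",
    loop_min: int = 2,
    loop_max: int = 3,
) -> list[RepeatHit]:
    """Scan the forward strand for ``stem + N{loop_min..loop_max} + revcomp(stem)``.

    At a shared start the shortest qualifying loop wins.  Loop letters are
    restricted to {A,C,G,T}; N never matches.  Circular replicons are scanned
    across the origin, with positions reported modulo the length.
    """
    stem = stem.upper()
    if not stem:
        raise ValueError("empty stem")
    if not (1 <= loop_min <= loop_max):
        raise ValueError("need 1 <= loop_min <= loop_max")
    rc = revcomp(stem)
    L = record.length
    seq = record.sequence
    max_span = 2 * len(stem) + loop_max
    scan = seq + (seq[: max_span - 1] if record.topology == "circular" else "")
    hits: list[RepeatHit] = []
    seen: set[int] = set()
    pos = scan.find(stem)
    while pos != -1:
        start = pos % L
        if start not in seen:
            for ll in range(loop_min, loop_max + 1):
                loop = scan[pos + len(stem) : pos + len(stem) + ll]
                tail = scan[pos + len(stem) + ll : pos + 2 * len(stem) + ll]
                if len(tail) < len(stem):
                    break
                if tail == rc and set(loop) <= set("ACGT"):
                    hits.append(
                        RepeatHit(start=start, end=start + 2 * len(stem) + ll,
                                  stem=stem, loop=loop)
                    )
                    seen.add(start)
                    break
        pos = scan.find(stem, pos + 1)
    hits.sort(key=lambda h: h.start)
    return hits


def find_inverted_repeats(
    record: SeqRecord,
    min_stem: int = 4,
    max_loop: int = 8,
    max_mismatch: int = 0,
    candidate_budget: int = 50_000_000,
) -> list[RepeatHit]:
    """General stem-loop scan: maximal inverted repeats with a bounded loop.

    For every candidate loop placement the stem is extended outward while the
    flanks stay reverse-complementary (allowing up to ``max_mismatch``
    non-complementary pairs).  Shorter-stem hits sharing a center with a
    longer one are suppressed.  Mismatched stems are reported with the
    observed (left-arm) stem string.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    seq = record.sequence
    L = len(seq)
    if L * (max_loop + 1) > candidate_budget:
        raise ValueError(
            "candidate budget exceeded; narrow max_loop or scan a sub-sequence"
        )
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    best_at_center: dict[tuple[int, int], tuple[int, int]] = {}
    for loop_len in range(0, max_loop + 1):
        for loop_start in range(0, L - loop_len):
            left = loop_start - 1
            right = loop_start + loop_len
            stem_len = 0
            mism = 0
            while left >= 0 and right < L:
                a, b = seq[left], seq[right]
                if a in comp and comp[a] == b:
                    pass
                elif mism < max_mismatch and a in comp and b in comp:
                    mism += 1
                else:
                    break
                stem_len += 1
                left -= 1
                right += 1
            if stem_len >= min_stem:
                key = (loop_start, loop_len)
                prev = best_at_center.get(key)
                if prev is None or stem_len > prev[0]:
                    best_at_center[key] = (stem_len, mism)
    hits = []
    for (loop_start, loop_len), (stem_len, mism) in best_at_center.items():
        start = loop_start - stem_len
        end = loop_start + loop_len + stem_len
        hits.append(
            RepeatHit(
                start=start, end=end,
                stem=seq[start : start + stem_len],
                loop=seq[loop_start : loop_start + loop_len],
            )
        )
    # suppress hits fully contained in a longer hit with the same center
    hits.sort(key=lambda h: (h.start, -(h.end - h.start)))
    kept: list[RepeatHit] = []
    for h in sorted(hits, key=lambda x: -(x.end - x.start)):
        if any(k.start <= h.start and h.end <= k.end for k in kept):
            continue
        kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


def classify_repeat_context(
    hits: list[RepeatHit],
    genome: AnnotatedGenome,
    window_3prime: int = 100,
) -> list[RepeatHit]:
    """Label each hit by gene context and cluster 3'-proximal hits.

    A hit is ``three_prime_proximal`` when it lies within ``window_3prime``
    bp downstream of a CDS stop (strand-aware); that label takes precedence
    over ``intragenic``.  Consecutive 3'-proximal hits of the same gene whose
    inter-hit gap is at most ``window_3prime`` share a cluster id.
    """
    L = genome.record.length
    circular = genome.record.topology == "circular"
    genes = genome.cds()

    def downstream_gene(hit: RepeatHit) -> str | None:
        for g in genes:
            if g.strand == 1:
                stop = g.end
                lo, hi = stop, stop + window_3prime
                pos = hit.start
                if lo <= pos < hi:
                    return g.locus_tag
                if circular and hi > L and pos < hi % L:
                    return g.locus_tag
            else:
                stop = g.start
                lo, hi = stop - window_3prime, stop
                pos = hit.end
                if lo < pos <= hi:
                    return g.locus_tag
                if circular and lo < 0 and pos > lo % L:
                    return g.locus_tag
        return None

    def inside_gene(hit: RepeatHit) -> str | None:
        for g in genes:
            if g.wraps:
                if hit.start >= g.start or hit.end <= g.end:
                    return g.locus_tag
            elif g.start <= hit.start and hit.end <= g.end:
                return g.locus_tag
        return None

    labeled = []
    for h in sorted(hits, key=lambda x: x.start):
        tag = downstream_gene(h)
        if tag is not None:
            labeled.append(replace(h, context=CONTEXT_3PRIME, nearest_gene=tag))
            continue
        tag = inside_gene(h)
        if tag is not None:
            labeled.append(replace(h, context=CONTEXT_INTRAGENIC, nearest_gene=tag))
        else:
            labeled.append(replace(h, context=CONTEXT_OTHER, nearest_gene=None))

    # cluster consecutive 3'-proximal hits of the same gene
    out: list[RepeatHit] = []
    cluster_id = -1
    prev = None
    for h in labeled:
        if h.context == CONTEXT_3PRIME:
            if (
                prev is not None
                and prev.context == CONTEXT_3PRIME
                and prev.nearest_gene == h.nearest_gene
                and h.start - prev.end <= window_3prime
            ):
                pass  # same cluster
            else:
                cluster_id += 1
            h = replace(h, cluster_id=cluster_id)
        out.append(h)
        prev = h
    return out


def cluster_sizes(hits: list[RepeatHit]) -> Counter:
    """Sizes of 3'-proximal clusters (singlet / duplicate / triplicate...)."""
    per_cluster = Counter(
        h.cluster_id for h in hits if h.cluster_id is not None
    )
    return Counter(per_cluster.values())


def loop_composition_table(hits: list[RepeatHit]) -> list[tuple[str, int]]:
    """Counts per distinct loop string, most frequent first."""
    counts = Counter(h.loop for h in hits)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
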