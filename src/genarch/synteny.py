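"""Synteny blocks (syntons) and non-syntenic candidate regions.

A synton is a maximal run of at least ``min_genes`` consecutive genes of
genome A whose orthologs are consecutive in genome B, in a consistent
orientation (collinear or inverted).  ``max_gap`` unmatched genes may be
skipped on either side.  Runs are taken non-overlapping in A, longest
first.  The complementary objects are non-syntenic regions: maximal runs of
at least ``min_genes`` consecutive A genes with no ortholog in B at all.
Both respect circular gene order (the first and last genes of a circular
replicon are neighbors).
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import AnnotatedGenome
from .orthology import OrthologPair


@dataclass(frozen=True)
class Synton:
    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    orientation: str  # "collinear" or "inverted"

    @property
    def size(self) -> int:
        return len(self.genes_a)


@dataclass(frozen=True)
class NonSyntenicRegion:
    id: int
    start: int
    end: int  # may be < start when the region wraps the origin
    genes: tuple[str, ...]
    flank_left: str | None
    flank_right: str | None

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _gene_order(genome: AnnotatedGenome) -> list[str]:
    return [f.locus_tag for f in genome.cds() if f.locus_tag]


def _circ_step(i: int, j: int, n: int) -> int:
    """Signed shortest circular step from i to j on a ring of n."""
    d = (j - i) % n
    return d if d <= n // 2 else d - n


def detect_syntons(
    A: AnnotatedGenome,
    B: AnnotatedGenome,
    pairs: list[OrthologPair],
    min_genes: int = 3,
    max_gap: int = 0,
) -> list[Synton]:
    """Maximal consistent runs of BBH orthologs, non-overlapping in A.

    Consecutive matched A genes may be separated by up to ``max_gap``
    unmatched A genes, and their B partners must advance by a step of
    magnitude ``<= max_gap + 1`` in the run's direction.
    """
    order_a = _gene_order(A)
    order_b = _gene_order(B)
    pos_b = {t: i for i, t in enumerate(order_b)}
    amap = {p.a: p.b for p in pairs}
    circ_a = A.record.topology == "circular"
    circ_b = B.record.topology == "circular"
    nB = len(order_b)

    matched = [
        (ia, pos_b[amap[t]], t)
        for ia, t in enumerate(order_a)
        if t in amap and amap[t] in pos_b
    ]
    M = len(matched)
    if M == 0:
        return []

    def compatible(prev, cur, direction):
        ia0, ib0, _ = prev
        ia1, ib1, _ = cur
        a_gap = ia1 - ia0 - 1
        if a_gap < 0:  # wrapped past the origin of A
            if not circ_a:
                return False
            a_gap = (ia1 - ia0 - 1) % len(order_a)
        if a_gap > max_gap:
            return False
        if circ_b:
            step = _circ_step(ib0, ib1, nB)
        else:
            step = ib1 - ib0
        if direction * step < 1 or abs(step) > max_gap + 1:
            return False
        return True

    # enumerate maximal runs starting at every matched index, both directions
    runs = []  # (indices into matched, direction)
    for s in range(M):
        for direction in (+1, -1):
            idxs = [s]
            j = s
            while len(idxs) < M:
                nxt = (j + 1) % M
                if nxt == s:
                    break
                if (nxt < j) and not circ_a:
                    break
                if compatible(matched[j], matched[nxt], direction):
                    idxs.append(nxt)
                    j = nxt
                else:
                    break
            if len(idxs) >= max(min_genes, 2):
                runs.append((idxs, direction))

    # drop runs contained in a longer run with the same direction
    runs.sort(key=lambda r: (-len(r[0]), r[0][0], r[1]))
    selected: list[tuple[list[int], int]] = []
    used: set[int] = set()
    for idxs, direction in runs:
        # drop already-used indices, keeping the first surviving contiguous run
        contiguous: list[int] = []
        for i in idxs:
            if i in used:
                if contiguous:
                    break
                continue
            contiguous.append(i)
        if len(contiguous) >= min_genes:
            selected.append((contiguous, direction))
            used.update(contiguous)

    syntons = []
    for idxs, direction in selected:
        genes_a = tuple(matched[i][2] for i in idxs)
        genes_b = tuple(amap[t] for t in genes_a)
        syntons.append(
            Synton(
                genes_a=genes_a,
                genes_b=genes_b,
                orientation="collinear" if direction == 1 else "inverted",
            )
        )
    syntons.sort(key=lambda s: order_a.index(s.genes_a[0]))
    return syntons


def synton_stats(syntons: list[Synton], A: AnnotatedGenome) -> dict:
    """Count, mean genes per synton and the fraction of A's CDS in syntons."""
    n_cds = len(A.cds())
    n_in = sum(s.size for s in syntons)
    return {
        "synton_count": len(syntons),
        "mean_genes_per_synton": (n_in / len(syntons)) if syntons else 0.0,
        "fraction_cds_syntenic": (n_in / n_cds) if n_cds else 0.0,
    }


def nonsyntenic_regions(
    A: AnnotatedGenome,
    pairs: list[OrthologPair],
    min_genes: int = 3,
) -> list[NonSyntenicRegion]:
    """Maximal runs of >= min_genes consecutive A genes with no ortholog."""
    order_a = _gene_order(A)
    n = len(order_a)
    if n == 0:
        return []
    matched_tags = {p.a for p in pairs}
    unmatched = [t not in matched_tags for t in order_a]
    feats = {f.locus_tag: f for f in A.cds()}
    circ = A.record.topology == "circular"

    if all(unmatched):
        runs = [list(range(n))]
    else:
        # rotate so index 0 is matched; runs then never split across the seam
        if circ:
            first_matched = unmatched.index(False)
        else:
            first_matched = 0
        runs = []
        cur: list[int] = []
        for k in range(n):
            i = (first_matched + k) % n if circ else k
            if unmatched[i]:
                cur.append(i)
            else:
                if cur:
                    runs.append(cur)
                cur = []
        if cur:
            runs.append(cur)

    regions = []
    for run in runs:
        if len(run) < min_genes:
            continue
        genes = tuple(order_a[i] for i in run)
        start = feats[genes[0]].start
        end = feats[genes[-1]].end
        left = order_a[(run[0] - 1) % n] if (circ or run[0] > 0) else None
        right = order_a[(run[-1] + 1) % n] if (circ or run[-1] < n - 1) else None
        if left in genes:
            left = None
        if right in genes:
            right = None
        regions.append((start, end, genes, left, right))
    regions.sort(key=lambda r: r[0])
    return [
        NonSyntenicRegion(
            id=i + 1, start=s, end=e, genes=g, flank_left=l, flank_right=r
        )
        for i, (s, e, g, l, r) in enumerate(regions)
    ]


def region_table(regions: list[NonSyntenicRegion], A: AnnotatedGenome):
    """Region summary as a DataFrame (id, flanks, coordinates, size, genes)."""
    import pandas as pd

    L = A.record.length
    rows = []
    for reg in regions:
        size = (reg.end - reg.start) % L if reg.end < reg.start else reg.end - reg.start
        rows.append(
            {
                "region_id": reg.id,
                "flank_left": reg.flank_left or "",
                "flank_right": reg.flank_right or "",
                "start": reg.start,
                "end": reg.end,
                "size_bp": size,
                "gene_count": reg.n_genes,
                "genes": ",".join(reg.genes),
            }
        )
    return pd.DataFrame(rows)
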