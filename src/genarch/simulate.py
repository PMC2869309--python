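"""Synthetic annotated genomes with machine-readable planted ground truth.

The generator emulates the structures the analysis pipeline looks for on a
real enterobacterial replicon:

* a circular chromosome whose leading/lagging strands carry opposite G-vs-C
  bias switching at a planted oriC and terminus (genes are sampled codon-wise
  from a codon model whose marginal base composition matches the local
  replichore, so windowed skew is coherent across coding and intergenic DNA);
* DnaA boxes clustered in an intergenic zone at oriC;
* stem-loop (palindromic) repeats planted singly or in small clusters just
  downstream of gene stops;
* genomic islands: contiguous gene blocks with shifted GC/codon usage,
  an integrase at one extremity, an IS-element gene at the other, a tRNA at
  the insertion boundary, and an excess of hypothetical products;
* a diverged sister genome with a known ortholog map, known deletions
  (islands and plain unique runs) and hence known synteny blocks.

Every planted fact is recorded in a :class:`GroundTruth` manifest, and
:func:`audit_truth` re-verifies the manifest against the emitted sequence
and features.  Generation is fully deterministic under (config, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import AnnotatedGenome, Feature, SeqRecord, revcomp

BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE = [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3))
          if c not in _STOPS]

ASSIGNED_PRODUCTS = (
    "ABC transporter ATP-binding protein",
    "ABC transporter permease",
    "MFS transporter",
    "PTS system sucrose-specific EIIBC component",
    "RND efflux transporter",
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L2",
    "acetolactate synthase",
    "acetoin reductase",
    "sucrose-6-phosphate hydrolase",
    "two-component system response regulator",
    "outer membrane porin",
    "glutathione S-transferase",
    "enterobactin synthase component F",
    "flagellar biosynthesis protein",
    "pilus assembly chaperone",
    "pectate lyase",
    "superoxide dismutase",
    "catalase",
    "aromatic amino acid aminotransferase",
)
ISLAND_HYPOTHETICAL = "hypothetical protein"
INTEGRASE_PRODUCT = "site-specific integrase"
IS_PRODUCT = "IS481 family transposase"
TOXIN_PRODUCT = "RelE family toxin"
ANTITOXIN_PRODUCT = "RelB family antitoxin"
TRNA_PRODUCTS = ("tRNA-Gly", "tRNA-Ser", "tRNA-Leu", "tRNA-Met", "tRNA-Arg")
DNAA_BOX = "TTATCCACA"


@dataclass(frozen=True)
class IslandSpec:
    """One planted genomic island."""

    n_genes: int = 8
    gc_shift: float = 0.08
    codon_bias: float = 2.0          # sharpening exponent on codon weights
    flank_integrase: bool = True
    flank_is_element: bool = True
    trna_site: bool = True
    hypothetical_fraction: float = 0.8


@dataclass(frozen=True)
class GenomeConfig:
    """Study conditions for one synthetic replicon."""

    length: int = 300_000
    gc: float = 0.53
    skew_amplitude: float = 0.06
    oriC: int | None = None          # default 0.75 * length
    terminus: int | None = None      # default 0.25 * length
    n_genes: int = 220
    gene_len_codons: tuple[int, int] = (120, 380)
    n_trna: int = 6
    n_dnaa_boxes: int = 3
    n_repeat_clusters: int = 6       # 3'-proximal stem-loop clusters
    repeat_cluster_sizes: tuple[int, ...] = (1, 2, 3)
    repeat_stem: str = "CCCTCTCCC"
    repeat_loops: tuple[str, ...] = ("TGT", "ACA", "AC", "TG", "GT", "TGA")
    n_ta_pairs: int = 2
    hypothetical_fraction: float = 0.2
    islands: tuple[IslandSpec, ...] = ()
    exclusive_motifs: bool = True    # scrub accidental stem/DnaA occurrences
    id: str = "synthetic"


@dataclass
class GroundTruth:
    """Everything the generator planted, for recovery tests."""

    length: int
    oriC: int
    terminus: int
    gc: float
    skew_amplitude: float
    dnaa_boxes: list[int] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)   # start, loop, gene
    islands: list[dict] = field(default_factory=list)   # genes, start, end
    ta_pairs: list[tuple[str, str]] = field(default_factory=list)
    gene_coords: dict[str, tuple[int, int, int]] = field(default_factory=dict)
    products: dict[str, str] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    trna_positions: list[int] = field(default_factory=list)
    # sister-genome bookkeeping (filled by derive_sister_genome on the pair)
    ortholog_map: dict[str, str] = field(default_factory=dict)
    target_identity: dict[str, float] = field(default_factory=dict)
    realized_identity: dict[str, float] = field(default_factory=dict)
    deleted_genes: list[str] = field(default_factory=list)
    expected_regions: list[tuple[str, ...]] = field(default_factory=list)
    expected_syntons: list[tuple[str, ...]] = field(default_factory=list)


class OverPackedError(ValueError):
    """The requested features do not fit in the requested length."""


# ---------------------------------------------------------------------------
# composition models


def _base_probs(gc: float, skew: float) -> np.ndarray:
    """P(A), P(C), P(G), P(T) with GC split (1 +- skew)/2 between G and C."""
    at = (1.0 - gc) / 2.0
    return np.array([at, gc / 2 * (1 - skew), gc / 2 * (1 + skew), at])


def _codon_weights(gc: float, skew: float, bias: float = 1.0) -> np.ndarray:
    """Sense-codon weights whose marginal base usage follows the base model.

    ``bias > 1`` sharpens the distribution (raises weights to a power and
    renormalizes), emulating the distinct codon-preference matrix of
    horizontally acquired DNA.
    """
    p = _base_probs(gc, skew)
    idx = {b: i for i, b in enumerate("ACGT")}
    w = np.array([p[idx[c[0]]] * p[idx[c[1]]] * p[idx[c[2]]] for c in _SENSE])
    w = w ** bias
    return w / w.sum()


def _sample_gene(rng, n_codons: int, gc: float, skew: float, bias: float) -> str:
    w = _codon_weights(gc, skew, bias)
    body = rng.choice(len(_SENSE), size=n_codons - 2, p=w)
    return "ATG" + "".join(_SENSE[i] for i in body) + "TAA"


def _region_skew(pos: int, oriC: int, terminus: int, length: int, amp: float) -> float:
    """Forward-strand G-vs-C bias at a coordinate: +amp on the leading
    replichore [oriC, terminus) walking forward, -amp elsewhere."""
    if oriC <= terminus:
        leading = oriC <= pos < terminus
    else:
        leading = pos >= oriC or pos < terminus
    return amp if leading else -amp


# ---------------------------------------------------------------------------
# genome generation


def _plan_genes(cfg: GenomeConfig, rng) -> list[dict]:
    """Ordered gene plan: regular genes, TA couples, island blocks."""
    plan = []
    for _ in range(cfg.n_genes):
        hyp = rng.random() < cfg.hypothetical_fraction
        product = (
            ISLAND_HYPOTHETICAL if hyp
            else ASSIGNED_PRODUCTS[rng.integers(len(ASSIGNED_PRODUCTS))]
        )
        plan.append(
            {
                "n_codons": int(rng.integers(*cfg.gene_len_codons)),
                "strand": 1 if rng.random() < 0.6 else -1,
                "product": product,
                "island": None,
                "ta_role": None,
                "repeat_cluster": None,
            }
        )
    # TA couples: rewrite two adjacent regular genes, same strand, short gap
    if cfg.n_ta_pairs > 0 and len(plan) >= 2 * cfg.n_ta_pairs:
        slots = rng.choice(len(plan) - 1, size=min(cfg.n_ta_pairs * 4,
                                                   len(plan) - 1), replace=False)
    else:
        slots = np.array([], dtype=int)
    planted_ta = 0
    used: set[int] = set()
    for s in slots:
        if planted_ta >= cfg.n_ta_pairs:
            break
        if s in used or s + 1 in used:
            continue
        plan[s]["product"] = TOXIN_PRODUCT
        plan[s]["ta_role"] = "toxin"
        plan[s]["strand"] = 1
        plan[s]["n_codons"] = 100
        plan[s + 1]["product"] = ANTITOXIN_PRODUCT
        plan[s + 1]["ta_role"] = "antitoxin"
        plan[s + 1]["strand"] = 1
        used.update((s, s + 1))
        planted_ta += 1
    # repeat clusters: mark + strand regular genes (well away from TA edits)
    candidates = [
        i for i, g in enumerate(plan)
        if g["strand"] == 1 and g["ta_role"] is None
    ]
    rng.shuffle(candidates)
    for ci in range(cfg.n_repeat_clusters):
        if not candidates:
            break
        gi = candidates.pop()
        size = int(
            cfg.repeat_cluster_sizes[rng.integers(len(cfg.repeat_cluster_sizes))]
        )
        plan[gi]["repeat_cluster"] = size
    # island blocks inserted at interior ordinal positions
    if cfg.islands:
        positions = sorted(
            rng.choice(
                np.arange(10, len(plan) - 10), size=len(cfg.islands), replace=False
            ),
            reverse=True,
        )
        for spec, pos in zip(cfg.islands, positions):
            while plan[pos]["ta_role"] == "antitoxin":  # never split a TA couple
                pos += 1
            block = []
            for j in range(spec.n_genes):
                if j == 0 and spec.flank_integrase:
                    product = INTEGRASE_PRODUCT
                elif j == spec.n_genes - 1 and spec.flank_is_element:
                    product = IS_PRODUCT
                elif rng.random() < spec.hypothetical_fraction:
                    product = ISLAND_HYPOTHETICAL
                else:
                    product = ASSIGNED_PRODUCTS[rng.integers(len(ASSIGNED_PRODUCTS))]
                block.append(
                    {
                        "n_codons": int(rng.integers(*cfg.gene_len_codons)),
                        "strand": 1 if rng.random() < 0.6 else -1,
                        "product": product,
                        "island": spec,
                        "ta_role": None,
                        "repeat_cluster": None,
                    }
                )
            plan[pos:pos] = block
    return plan


def generate_genome(
    cfg: GenomeConfig, seed: int = 0
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Emit a synthetic annotated replicon and its ground-truth manifest."""
    rng = np.random.default_rng(seed)
    L = cfg.length
    oriC = cfg.oriC if cfg.oriC is not None else int(0.75 * L)
    terminus = cfg.terminus if cfg.terminus is not None else int(0.25 * L)
    if oriC == terminus:
        raise ValueError("oriC and terminus must differ")
    truth = GroundTruth(
        length=L, oriC=oriC, terminus=terminus,
        gc=cfg.gc, skew_amplitude=cfg.skew_amplitude,
    )
    plan = _plan_genes(cfg, rng)

    # ---- background sequence, skewed per replichore
    seq = np.empty(L, dtype="<U1")
    if oriC <= terminus:
        segments = [(oriC, terminus, +1), (terminus, L, -1), (0, oriC, -1)]
    else:
        segments = [(oriC, L, +1), (0, terminus, +1), (terminus, oriC, -1)]
    for s0, s1, sign in segments:
        if s1 > s0:
            p = _base_probs(cfg.gc, sign * cfg.skew_amplitude)
            seq[s0:s1] = rng.choice(BASES, size=s1 - s0, p=p)

    # ---- oriC zone: keep ~1.5 kb gene-free for the DnaA boxes
    zone = (oriC, min(oriC + 1500, L))

    # ---- walk the replicon laying down genes and companion elements
    features: list[Feature] = []
    stem = cfg.repeat_stem
    rc_stem = revcomp(stem)
    pending_repeats: list[tuple[int, str, int]] = []  # (start, loop, gene_index)
    pos = int(rng.integers(100, 300))
    gene_records = []  # (start, end, strand, plan entry)
    prev_island = None
    for entry in plan:
        gap = int(rng.integers(40, 200))
        if entry["ta_role"] == "antitoxin":
            gap = int(rng.integers(5, 60))  # keep the couple tight
        pos += gap
        # tRNA marks an island insertion boundary
        if entry["island"] is not None and entry["island"] is not prev_island:
            if entry["island"].trna_site:
                trna_start = pos
                features.append(
                    Feature(
                        start=trna_start, end=trna_start + 76, kind="tRNA",
                        strand=1, locus_tag="", product=str(
                            TRNA_PRODUCTS[rng.integers(len(TRNA_PRODUCTS))]
                        ),
                    )
                )
                truth.trna_positions.append(trna_start)
                pos = trna_start + 76 + int(rng.integers(20, 120))
        prev_island = entry["island"]
        footprint = 3 * entry["n_codons"] + 80
        if entry["repeat_cluster"]:
            footprint += entry["repeat_cluster"] * 45 + 60
        if pos < zone[1] and pos + footprint > zone[0]:
            pos = zone[1] + int(rng.integers(40, 120))
        glen = 3 * entry["n_codons"]
        if pos + glen > L - 2500:
            raise OverPackedError(
                f"gene layout exceeds length {L}; reduce n_genes or lengthen"
            )
        spec = entry["island"]
        gc = cfg.gc + (spec.gc_shift if spec else 0.0)
        bias = spec.codon_bias if spec else 1.0
        fwd_skew = _region_skew(pos, oriC, terminus, L, cfg.skew_amplitude)
        model_skew = fwd_skew if entry["strand"] == 1 else -fwd_skew
        if spec:  # islands: alien composition, no host replichore signature
            model_skew = 0.0
        nt = _sample_gene(rng, entry["n_codons"], gc, model_skew, bias)
        placed = nt if entry["strand"] == 1 else revcomp(nt)
        seq[pos : pos + glen] = list(placed)
        gene_records.append((pos, pos + glen, entry["strand"], entry))
        if entry["repeat_cluster"]:
            rpos = pos + glen + int(rng.integers(8, 30))
            for _ in range(entry["repeat_cluster"]):
                loop = str(cfg.repeat_loops[rng.integers(len(cfg.repeat_loops))])
                unit = stem + loop + rc_stem
                pending_repeats.append((rpos, loop, len(gene_records) - 1))
                seq[rpos : rpos + len(unit)] = list(unit)
                rpos += len(unit) + int(rng.integers(5, 20))
            pos = rpos + int(rng.integers(10, 40))
        else:
            pos = pos + glen

    # remaining stand-alone tRNAs scattered in the tail intergenic space
    n_extra_trna = max(cfg.n_trna - len(truth.trna_positions), 0)
    tail_lo = pos + 100
    for i in range(n_extra_trna):
        tpos = tail_lo + i * 200
        if tpos + 76 > L:
            break
        if zone[0] <= tpos < zone[1]:
            continue
        features.append(
            Feature(start=tpos, end=tpos + 76, kind="tRNA", strand=1,
                    locus_tag="", product=str(TRNA_PRODUCTS[i % len(TRNA_PRODUCTS)]))
        )
        truth.trna_positions.append(tpos)

    # ---- DnaA boxes inside the reserved oriC zone
    for i in range(cfg.n_dnaa_boxes):
        bpos = zone[0] + 120 + 180 * i
        if bpos + len(DNAA_BOX) > zone[1]:
            break
        seq[bpos : bpos + len(DNAA_BOX)] = list(DNAA_BOX)
        truth.dnaa_boxes.append(bpos)

    # ---- locus tags in coordinate order
    gene_records.sort(key=lambda r: r[0])
    island_specs = {id(s): [] for s in cfg.islands}
    cds_features = []
    for i, (start, end, strand, entry) in enumerate(gene_records):
        tag = f"GA_{i + 1:04d}"
        cds_features.append(
            Feature(start=start, end=end, kind="CDS", strand=strand,
                    locus_tag=tag, product=entry["product"])
        )
        truth.gene_coords[tag] = (start, end, strand)
        truth.products[tag] = entry["product"]
        entry["tag"] = tag
        if entry["island"] is not None:
            island_specs[id(entry["island"])].append((start, end, tag))
        if entry["ta_role"] == "toxin":
            truth.ta_pairs.append((tag, ""))
    # complete TA pair partners (antitoxin directly follows its toxin)
    completed = []
    for tox, _ in truth.ta_pairs:
        tox_idx = next(i for i, f in enumerate(cds_features) if f.locus_tag == tox)
        if tox_idx + 1 < len(cds_features):
            completed.append((tox, cds_features[tox_idx + 1].locus_tag))
    truth.ta_pairs = completed

    for spec in cfg.islands:
        members = island_specs[id(spec)]
        if members:
            truth.islands.append(
                {
                    "genes": tuple(tag for _, _, tag in members),
                    "start": members[0][0],
                    "end": members[-1][1],
                    "gc_shift": spec.gc_shift,
                }
            )
    for rpos, loop, gi in pending_repeats:
        truth.repeats.append(
            {"start": rpos, "loop": loop, "gene": gene_records[gi][3]["tag"]}
        )

    features.extend(cds_features)
    sequence = "".join(seq)

    # ---- scrub accidental motif occurrences outside planted loci
    if cfg.exclusive_motifs:
        sequence = _scrub_motifs(sequence, cfg, truth, cds_features)

    record = SeqRecord(id=cfg.id, sequence=sequence, topology="circular")
    genome = AnnotatedGenome(record=record, features=features, source="generated")

    # manifest proteins from the final sequence (after any scrubbing)
    from .genome_io import translate_cds  # local import avoids cycle at load

    for f in genome.cds():
        truth.proteins[f.locus_tag] = translate_cds(genome, f)
    return genome, truth


def _scrub_motifs(sequence: str, cfg: GenomeConfig, truth: GroundTruth,
                  cds_features: list[Feature]) -> str:
    """Mutate accidental occurrences of the repeat stem and the DnaA box so
    planted counts are exact; substitutions inside CDS avoid creating stops."""
    seq = list(sequence)
    L = len(seq)
    planted_spans = []
    unit_len = 2 * len(cfg.repeat_stem) + max(len(l) for l in cfg.repeat_loops)
    for r in truth.repeats:
        planted_spans.append((r["start"], r["start"] + unit_len))
    for b in truth.dnaa_boxes:
        planted_spans.append((b, b + len(DNAA_BOX)))

    def in_planted(lo: int, hi: int) -> bool:
        return any(lo < pe and hi > ps for ps, pe in planted_spans)

    cds_sorted = sorted(cds_features, key=lambda f: f.start)

    def containing_cds(pos: int) -> Feature | None:
        for f in cds_sorted:
            if f.start <= pos < f.end:
                return f
            if f.start > pos:
                return None
        return None

    def safe_substitute(pos: int):
        f = containing_cds(pos)
        for b in "ACGT":
            if b == seq[pos]:
                continue
            if f is None:
                seq[pos] = b
                return
            old = seq[pos]
            seq[pos] = b
            off = (pos - f.start) // 3
            c0 = f.start + 3 * off
            codon = "".join(seq[c0 : c0 + 3])
            if f.strand == -1:
                codon = revcomp(codon)
            if codon not in _STOPS and codon != "ATG":
                return
            seq[pos] = old
        # all four bases problematic: give up on this position (harmless)

    motifs = {cfg.repeat_stem, revcomp(cfg.repeat_stem), DNAA_BOX, revcomp(DNAA_BOX)}
    for _ in range(6):  # a substitution can create a new occurrence; iterate
        text = "".join(seq)
        doubled = text + text[:20]
        dirty = False
        for m in motifs:
            start = doubled.find(m)
            while start != -1:
                lo = start % L
                hi = lo + len(m)
                if not in_planted(lo, hi):
                    safe_substitute(lo + len(m) // 2)
                    dirty = True
                start = doubled.find(m, start + 1)
        if not dirty:
            break
    return "".join(seq)


# ---------------------------------------------------------------------------
# sister-genome derivation


def _mutate_protein(rng, protein: str, target_identity: float) -> tuple[str, float]:
    n = len(protein)
    n_sub = int(round((1.0 - target_identity) * n))
    n_sub = min(n_sub, n - 1)
    if n_sub == 0:
        return protein, 1.0
    positions = rng.choice(np.arange(1, n), size=min(n_sub, n - 1), replace=False)
    aa = list(protein)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for p in positions:
        choices = [c for c in alphabet if c != aa[p]]
        aa[p] = choices[rng.integers(len(choices))]
    return "".join(aa), 1.0 - len(positions) / n


_CODONS_BY_AA: dict[str, list[str]] = {}


def _codon_table():
    if not _CODONS_BY_AA:
        from Bio.Seq import Seq

        for c in _SENSE:
            aa = str(Seq(c).translate(table=11))
            _CODONS_BY_AA.setdefault(aa, []).append(c)
    return _CODONS_BY_AA


def _encode_protein(rng, protein: str, gc: float) -> str:
    """Back-translate with synonymous codons drawn from a GC-matched model."""
    table = _codon_table()
    w_all = _codon_weights(gc, 0.0)
    w_by_codon = dict(zip(_SENSE, w_all))
    out = []
    for aa in protein:
        codons = table[aa]
        w = np.array([w_by_codon[c] for c in codons])
        w /= w.sum()
        out.append(codons[rng.choice(len(codons), p=w)])
    return "".join(out) + "TAA"


def derive_sister_genome(
    base: AnnotatedGenome,
    truth: GroundTruth,
    divergence: float | dict[str, float] = 0.85,
    drop_islands: bool = True,
    deletions: tuple[str, ...] = (),
    inversion_spans: tuple[tuple[int, int], ...] = (),
    seed: int = 1,
    id: str = "sister",
    gc: float | None = None,
) -> tuple[AnnotatedGenome, GroundTruth]:
    """Derive a diverged comparator genome with a known ortholog map.

    ``divergence`` is the per-gene target amino-acid identity (global float
    or per-tag map).  Island genes (when ``drop_islands``) and ``deletions``
    are omitted from the sister, becoming ground-truth unique regions of the
    base genome.  ``inversion_spans`` are (start, end) ordinal ranges, in the
    sister's retained gene order, whose gene order and strands are reversed.
    The sister truth records the ortholog map, realized identities, and the
    expected synteny blocks (runs of retained genes split at deletions and
    inversion boundaries).
    """
    rng = np.random.default_rng(seed)
    island_tags = {t for isl in truth.islands for t in isl["genes"]} if drop_islands else set()
    dropped = island_tags | set(deletions)
    order_a = [f.locus_tag for f in base.cds()]
    retained = [t for t in order_a if t not in dropped]
    if not retained:
        raise ValueError("every gene was deleted; nothing to derive")

    # expected synteny blocks: split retained runs at each deletion gap
    blocks: list[list[str]] = []
    cur: list[str] = []
    retained_set = set(retained)
    for t in order_a:
        if t in retained_set:
            cur.append(t)
        else:
            if cur:
                blocks.append(cur)
            cur = []
    if cur:
        blocks.append(cur)
    # circular: the genome start may split a run in two
    if (
        len(blocks) > 1
        and order_a[0] in retained_set
        and order_a[-1] in retained_set
        and base.record.topology == "circular"
    ):
        blocks[0] = blocks[-1] + blocks[0]
        blocks.pop()

    # apply inversions on the retained order
    b_order = list(retained)
    inversion_tag_spans = []
    for lo, hi in inversion_spans:
        b_order[lo:hi] = b_order[lo:hi][::-1]
        inversion_tag_spans.append(tuple(retained[lo:hi]))

    gc_b = gc if gc is not None else truth.gc
    div_of = (
        (lambda t: divergence[t]) if isinstance(divergence, dict)
        else (lambda t: float(divergence))
    )
    strand_of = {f.locus_tag: f.strand for f in base.cds()}
    inverted_tags = {t for span in inversion_tag_spans for t in span}

    sister_truth = GroundTruth(
        length=0, oriC=truth.oriC, terminus=truth.terminus,
        gc=gc_b, skew_amplitude=0.0,
    )
    pos = 200
    feats = []
    proteins_b = {}
    for i, a_tag in enumerate(b_order):
        b_tag = f"GB_{i + 1:04d}"
        target = div_of(a_tag)
        if not 0 < target <= 1:
            raise ValueError("divergence targets must be in (0, 1]")
        mutated, realized = _mutate_protein(rng, truth.proteins[a_tag], target)
        nt_len = 3 * len(mutated) + 3  # body codons + stop
        strand = strand_of[a_tag] * (-1 if a_tag in inverted_tags else 1)
        feats.append(
            Feature(start=pos, end=pos + nt_len, kind="CDS", strand=strand,
                    locus_tag=b_tag, product=truth.products[a_tag])
        )
        sister_truth.gene_coords[b_tag] = (pos, pos + nt_len, strand)
        sister_truth.products[b_tag] = truth.products[a_tag]
        proteins_b[b_tag] = mutated
        sister_truth.ortholog_map[a_tag] = b_tag
        sister_truth.target_identity[a_tag] = target
        sister_truth.realized_identity[a_tag] = realized
        pos += nt_len + int(rng.integers(40, 200))
    L_b = pos + 200

    seq = rng.choice(BASES, size=L_b, p=_base_probs(gc_b, 0.0))
    for f in feats:
        nt = _encode_protein(rng, proteins_b[f.locus_tag], gc_b)
        placed = nt if f.strand == 1 else revcomp(nt)
        seq[f.start : f.end] = list(placed)

    record = SeqRecord(id=id, sequence="".join(seq), topology="circular")
    sister = AnnotatedGenome(record=record, features=feats, source="derived")
    sister_truth.length = L_b
    # the sister carries no planted replichore structure; keep the manifest
    # coordinates inside the replicon
    sister_truth.oriC = 0
    sister_truth.terminus = L_b // 2
    sister_truth.proteins = proteins_b
    sister_truth.deleted_genes = sorted(dropped)
    sister_truth.expected_regions = _deleted_runs(order_a, dropped,
                                                  base.record.topology == "circular")
    sister_truth.expected_syntons = [tuple(b) for b in blocks]
    return sister, sister_truth


def _deleted_runs(order_a: list[str], dropped: set[str], circular: bool):
    runs = []
    cur: list[str] = []
    for t in order_a:
        if t in dropped:
            cur.append(t)
        else:
            if cur:
                runs.append(tuple(cur))
            cur = []
    if cur:
        runs.append(tuple(cur))
    if (
        circular and len(runs) > 1
        and order_a[0] in dropped and order_a[-1] in dropped
    ):
        runs[0] = runs[-1] + runs[0]
        runs.pop()
    return runs


# ---------------------------------------------------------------------------
# manifest (de)serialization


def truth_to_json(truth: GroundTruth, path) -> None:
    """Write the ground-truth manifest as JSON."""
    import dataclasses
    import json

    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1)


def truth_from_json(path) -> GroundTruth:
    import json

    with open(path) as fh:
        d = json.load(fh)
    d["gene_coords"] = {k: tuple(v) for k, v in d["gene_coords"].items()}
    d["ta_pairs"] = [tuple(p) for p in d["ta_pairs"]]
    d["islands"] = [
        {**isl, "genes": tuple(isl["genes"])} for isl in d["islands"]
    ]
    d["expected_regions"] = [tuple(r) for r in d["expected_regions"]]
    d["expected_syntons"] = [tuple(s) for s in d["expected_syntons"]]
    return GroundTruth(**d)


# ---------------------------------------------------------------------------
# self-audit


def audit_truth(genome: AnnotatedGenome, truth: GroundTruth) -> list[str]:
    """Verify every manifest fact against the emitted genome.

    Returns a list of human-readable discrepancies; empty means the manifest
    and the artifact agree.
    """
    problems = []
    seq = genome.record.sequence
    L = genome.record.length
    if truth.length and truth.length != L:
        problems.append(f"length mismatch: manifest {truth.length}, genome {L}")
    feats = {f.locus_tag: f for f in genome.features if f.locus_tag}
    for tag, (start, end, strand) in truth.gene_coords.items():
        f = feats.get(tag)
        if f is None:
            problems.append(f"gene {tag} missing from features")
        elif (f.start, f.end, f.strand) != (start, end, strand):
            problems.append(
                f"gene {tag} at {(f.start, f.end, f.strand)}, "
                f"manifest says {(start, end, strand)}"
            )
    for tag, product in truth.products.items():
        f = feats.get(tag)
        if f is not None and f.product != product:
            problems.append(f"gene {tag} product {f.product!r} != {product!r}")
    stem = "CCCTCTCCC"
    for r in truth.repeats:
        loop = r["loop"]
        unit = stem + loop + revcomp(stem)
        found = seq[r["start"] : r["start"] + len(unit)]
        if found != unit:
            problems.append(
                f"repeat at {r['start']} reads {found!r}, expected {unit!r}"
            )
    for b in truth.dnaa_boxes:
        if seq[b : b + len(DNAA_BOX)] != DNAA_BOX:
            problems.append(f"DnaA box missing at {b}")
    for isl in truth.islands:
        for tag in isl["genes"]:
            if tag not in feats:
                problems.append(f"island gene {tag} missing")
    for tox, anti in truth.ta_pairs:
        for tag in (tox, anti):
            if tag not in feats:
                problems.append(f"TA gene {tag} missing")
    if not 0 <= truth.oriC < max(L, 1):
        problems.append("oriC outside replicon")
    return problems
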