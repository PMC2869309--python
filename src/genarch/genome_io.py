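"""Annotated-genome input/output and coordinate conventions.

All internal coordinates are 0-based, half-open ``[start, end)``.  GenBank
and GFF3, which are 1-based inclusive, are converted exactly once, here.
Features that span the origin of a circular replicon are kept as a single
:class:`Feature` with ``wraps=True`` and ``end`` reduced modulo the replicon
length (so ``end < start`` for wrapping features, and only for them).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

_VALID_KINDS = ("CDS", "tRNA", "rRNA", "repeat_region", "mobile_element", "misc")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed genome input."""


@dataclass(frozen=True)
class SeqRecord:
    """A replicon: identifier, sequence and topology."""

    id: str
    sequence: str
    topology: str = "circular"  # or "linear"

    def __post_init__(self):
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise GenomeIOError(f"invalid characters in sequence: {sorted(bad)}")
        if self.topology not in ("circular", "linear"):
            raise GenomeIOError(f"unknown topology {self.topology!r}")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Sub-sequence with circular wrap-around when end > length."""
        L = self.length
        start %= L
        if end <= L and end >= start:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise GenomeIOError("coordinates beyond the end of a linear replicon")
        span = end - start
        doubled = self.sequence[start:] + self.sequence
        return doubled[:span]


@dataclass(frozen=True, order=True)
class Feature:
    """One annotated feature in internal 0-based half-open coordinates."""

    start: int
    end: int
    kind: str = "misc"
    strand: int = 1  # +1 or -1
    locus_tag: str = ""
    product: str = ""
    qualifiers: tuple = field(default_factory=tuple, compare=False)
    wraps: bool = False

    def __post_init__(self):
        if self.kind not in _VALID_KINDS:
            raise GenomeIOError(f"unknown feature kind {self.kind!r}")
        if self.strand not in (1, -1):
            raise GenomeIOError("strand must be +1 or -1")
        if not self.wraps and not 0 <= self.start < self.end:
            raise GenomeIOError(f"bad interval [{self.start}, {self.end})")

    def length(self, replicon_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start
        if replicon_length is None:
            raise GenomeIOError("replicon length required for a wrapping feature")
        return replicon_length - self.start + self.end

    def qualifier(self, key: str, default: str = "") -> str:
        for k, v in self.qualifiers:
            if k == key:
                return v
        return default


@dataclass
class AnnotatedGenome:
    """A replicon plus its ordered feature list."""

    record: SeqRecord
    features: list[Feature]
    source: str = ""

    def __post_init__(self):
        self.features = sorted(
            self.features, key=lambda f: (f.start, f.end, f.locus_tag)
        )
        tags = [f.locus_tag for f in self.features if f.locus_tag]
        if len(tags) != len(set(tags)):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise GenomeIOError(f"duplicate locus_tags: {dup[:5]}")

    def cds(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "CDS"]

    def by_tag(self, tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == tag:
                return f
        raise KeyError(tag)

    def feature_sequence(self, feature: Feature) -> str:
        """Spliced, strand-resolved nucleotide sequence of a feature."""
        L = self.record.length
        end = feature.end + L if feature.wraps else feature.end
        seq = self.record.fetch(feature.start, end)
        return seq if feature.strand == 1 else revcomp(seq)


# ---------------------------------------------------------------------------
# GenBank / FASTA reading


def _classify_kind(bio_type: str) -> str:
    if bio_type in ("CDS", "tRNA", "rRNA", "repeat_region"):
        return bio_type
    if bio_type in ("mobile_element", "mobile_element_type", "IS"):
        return "mobile_element"
    return "misc"


def _feature_from_bio(bf: SeqFeature, length: int) -> Feature | None:
    kind = _classify_kind(bf.type)
    if bf.type in ("source", "gene"):
        return None
    quals = []
    for key, vals in bf.qualifiers.items():
        for v in vals:
            quals.append((key, str(v)))
    locus = bf.qualifiers.get("locus_tag", [""])[0]
    product = bf.qualifiers.get("product", [""])[0]
    strand = -1 if bf.location.strand == -1 else 1
    start = int(bf.location.start)
    end = int(bf.location.end)
    wraps = False
    if isinstance(bf.location, CompoundLocation):
        parts = sorted(bf.location.parts, key=lambda p: int(p.start))
        # origin-spanning join(x..L, 1..y): last part ends at L, first begins at 0
        if int(parts[-1].end) == length and int(parts[0].start) == 0:
            start = int(parts[-1].start)
            end = int(parts[0].end) % length
            wraps = True
    return Feature(
        start=start, end=end, kind=kind, strand=strand,
        locus_tag=locus, product=product, qualifiers=tuple(quals), wraps=wraps,
    )


def read_genbank(path) -> AnnotatedGenome:
    """Read a single-record GenBank flat file into an :class:`AnnotatedGenome`.

    GenBank's 1-based inclusive spans become 0-based half-open; compound
    (join) locations that span the origin of a circular replicon collapse to
    one wrapping feature.
    """
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise GenomeIOError(f"malformed GenBank record in {path}: {exc}") from exc
    if not records:
        raise GenomeIOError(f"no GenBank record found in {path}")
    if len(records) > 1:
        raise GenomeIOError(
            f"{path} holds {len(records)} records; process one replicon at a time"
        )
    rec = records[0]
    topology = rec.annotations.get("topology", "linear")
    sr = SeqRecord(id=rec.id, sequence=str(rec.seq), topology=topology)
    feats = []
    for bf in rec.features:
        f = _feature_from_bio(bf, sr.length)
        if f is not None:
            feats.append(f)
    return AnnotatedGenome(record=sr, features=feats, source=str(path))


def read_fasta(path, topology: str = "circular") -> AnnotatedGenome:
    """Read a plain FASTA replicon (no features)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise GenomeIOError(f"expected one FASTA record in {path}")
    rec = records[0]
    sr = SeqRecord(id=rec.id, sequence=str(rec.seq), topology=topology)
    return AnnotatedGenome(record=sr, features=[], source=str(path))


def write_genbank(genome: AnnotatedGenome, path) -> None:
    """Emit the genome as a GenBank flat file (inverse of :func:`read_genbank`)."""
    rec = _BioSeqRecord(
        Seq(genome.record.sequence),
        id=genome.record.id,
        name=genome.record.id[:16].replace(".", "_"),
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": genome.record.topology,
        },
    )
    L = genome.record.length
    for f in genome.features:
        if f.wraps:
            loc = CompoundLocation(
                [SimpleLocation(f.start, L, f.strand), SimpleLocation(0, f.end, f.strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, f.strand)
        quals: dict[str, list[str]] = {}
        if f.locus_tag:
            quals["locus_tag"] = [f.locus_tag]
        if f.product:
            quals["product"] = [f.product]
        for k, v in f.qualifiers:
            if k in ("locus_tag", "product"):
                continue
            quals.setdefault(k, []).append(v)
        bio_type = f.kind if f.kind != "misc" else "misc_feature"
        rec.features.append(SeqFeature(loc, type=bio_type, qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


# ---------------------------------------------------------------------------
# Derived quantities


class PseudogeneWarning(UserWarning):
    """A CDS translation hit an internal stop codon."""


def translate_cds(genome: AnnotatedGenome, feature: Feature) -> str:
    """Translate a CDS with the bacterial code (NCBI table 11).

    Strand is resolved first; the trailing stop is removed.  An internal stop
    raises a :class:`PseudogeneWarning` and truncates the translation there.
    """
    if feature.kind != "CDS":
        raise GenomeIOError("translate_cds requires a CDS feature")
    nt = genome.feature_sequence(feature)
    if len(nt) % 3 != 0:
        raise GenomeIOError(
            f"CDS {feature.locus_tag or feature.start} length {len(nt)} "
            "is not divisible by 3"
        )
    aa = str(Seq(nt).translate(table=11))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        warnings.warn(
            f"internal stop in CDS {feature.locus_tag or feature.start}; "
            "translation truncated (putative pseudogene)",
            PseudogeneWarning,
            stacklevel=2,
        )
        aa = aa.split("*")[0]
    return aa


def coding_density(genome: AnnotatedGenome) -> float:
    """Percent of the replicon covered by the union of CDS intervals."""
    L = genome.record.length
    if L == 0:
        raise GenomeIOError("empty replicon")
    intervals = []
    for f in genome.cds():
        if f.wraps:
            intervals.append((f.start, L))
            intervals.append((0, f.end))
        else:
            intervals.append((f.start, f.end))
    if not intervals:
        return 0.0
    intervals.sort()
    covered = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s > cur_e:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    covered += cur_e - cur_s
    return 100.0 * covered / L


def gc_content(record: SeqRecord) -> float:
    """G+C percent over unambiguous bases; N is excluded entirely."""
    seq = record.sequence
    gc = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise GenomeIOError("GC content undefined for an all-N sequence")
    return 100.0 * gc / denom


# ---------------------------------------------------------------------------
# Feature-table export


def write_features(genome: AnnotatedGenome, fmt: str, path) -> None:
    """Write the feature table as GFF3 (1-based inclusive), BED (0-based
    half-open) or TSV, rows ordered by start."""
    fmt = fmt.upper()
    if fmt not in ("GFF3", "BED", "TSV"):
        raise GenomeIOError(f"unknown feature format {fmt!r}")
    rows = []
    rid = genome.record.id
    for f in genome.features:
        strand = "+" if f.strand == 1 else "-"
        if fmt == "GFF3":
            attrs = []
            if f.locus_tag:
                attrs.append(f"ID={f.locus_tag};locus_tag={f.locus_tag}")
            if f.product:
                attrs.append(f"product={f.product}")
            rows.append(
                "\t".join(
                    [
                        rid, "genarch", f.kind, str(f.start + 1), str(f.end),
                        ".", strand, ".", ";".join(attrs) or ".",
                    ]
                )
            )
        elif fmt == "BED":
            rows.append(
                "\t".join(
                    [rid, str(f.start), str(f.end), f.locus_tag or f.kind, "0", strand]
                )
            )
        else:
            rows.append(
                "\t".join(
                    [rid, f.kind, str(f.start), str(f.end), strand,
                     f.locus_tag, f.product]
                )
            )
    header = {
        "GFF3": "##gff-version 3\n",
        "BED": "",
        "TSV": "replicon\tkind\tstart\tend\tstrand\tlocus_tag\tproduct\n",
    }[fmt]
    with open(path, "w") as fh:
        fh.write(header)
        fh.write("\n".join(rows))
        if rows:
            fh.write("\n")


def read_gff3(path, genome: AnnotatedGenome) -> AnnotatedGenome:
    """Re-read a GFF3 written by :func:`write_features` onto a sequence."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            feats.append(
                Feature(
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    kind=cols[2],
                    strand=1 if cols[6] == "+" else -1,
                    locus_tag=attrs.get("locus_tag", ""),
                    product=attrs.get("product", ""),
                )
            )
    return AnnotatedGenome(record=genome.record, features=feats, source=str(path))
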