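"""Annotation-based feature census: per-replicon tallies of CDS classes,
RNA genes, transporter families, mobile elements and toxin/antitoxin pairs.

All gene-class tallies are deterministic keyword matches against product
strings (case-insensitive substring), with the counted locus tags kept in an
audit map so every number can be traced back to its genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import AnnotatedGenome, Feature

TRANSPORTER_LEXICONS = {
    "ABC": ("abc transporter", "abc-type transporter"),
    "MFS": ("mfs transporter", "major facilitator"),
    "PTS": ("pts transporter", "phosphotransferase system", "pts system"),
    "RND": ("rnd transporter", "rnd efflux", "nodulation and cell division"),
}
HYPOTHETICAL_LEXICON = ("hypothetical", "unknown function", "uncharacterized")
INTEGRASE_LEXICON = ("integrase", "recombinase")
IS_LEXICON = ("transposase", "insertion sequence", "is element")

TOXIN_LEXICON = ("rele", "hipa", "pare ", "chpa", "yeev", "toxin")
ANTITOXIN_LEXICON = ("relb", "hipb", "pard", "chpr", "yeeu", "antitoxin")


@dataclass
class CensusReport:
    replicon: str
    counts: dict[str, int] = field(default_factory=dict)
    audit: dict[str, list[str]] = field(default_factory=dict)
    ta_pairs: list[tuple[str, str]] = field(default_factory=list)


def _matches(product: str, lexicon) -> bool:
    p = product.lower()
    return any(term in p for term in lexicon)


def _is_toxin(product: str) -> bool:
    # "antitoxin" contains "toxin": the antitoxin lexicon takes precedence
    return not _matches(product, ANTITOXIN_LEXICON) and _matches(product, TOXIN_LEXICON)


def _is_antitoxin(product: str) -> bool:
    return _matches(product, ANTITOXIN_LEXICON)


def find_ta_pairs(
    genome: AnnotatedGenome,
    toxin_lexicon=TOXIN_LEXICON,
    antitoxin_lexicon=ANTITOXIN_LEXICON,
    max_gap: int = 200,
) -> list[tuple[str, str]]:
    """Adjacent same-strand toxin/antitoxin couples with gap <= max_gap bp.

    Each returned pair is ``(toxin_tag, antitoxin_tag)``; either order along
    the replicon qualifies.
    """

    def is_tox(f: Feature) -> bool:
        return not _matches(f.product, antitoxin_lexicon) and _matches(
            f.product, toxin_lexicon
        )

    def is_anti(f: Feature) -> bool:
        return _matches(f.product, antitoxin_lexicon)

    cds = genome.cds()
    pairs = []
    for f1, f2 in zip(cds, cds[1:]):
        if f1.strand != f2.strand:
            continue
        if f2.start - f1.end > max_gap:
            continue
        if is_tox(f1) and is_anti(f2):
            pairs.append((f1.locus_tag, f2.locus_tag))
        elif is_anti(f1) and is_tox(f2):
            pairs.append((f2.locus_tag, f1.locus_tag))
    return pairs


def census(genome: AnnotatedGenome, lexicons: dict | None = None) -> CensusReport:
    """Tally the annotation classes of one replicon.

    ``lexicons`` may override any of the default keyword lists (keys:
    transporter family names, "hypothetical", "integrase", "IS").
    """
    lex = {
        "hypothetical": HYPOTHETICAL_LEXICON,
        "integrase": INTEGRASE_LEXICON,
        "IS": IS_LEXICON,
        **TRANSPORTER_LEXICONS,
    }
    if lexicons:
        lex.update(lexicons)

    report = CensusReport(replicon=genome.record.id)
    cds = genome.cds()
    report.counts["CDS"] = len(cds)
    report.counts["tRNA"] = sum(1 for f in genome.features if f.kind == "tRNA")
    rrna = [f for f in genome.features if f.kind == "rRNA"]
    report.counts["rRNA"] = len(rrna)
    for sub in ("5S", "16S", "23S"):
        report.counts[f"rRNA_{sub}"] = sum(1 for f in rrna if sub in f.product)

    def tally(name: str, predicate):
        tags = [f.locus_tag for f in cds if predicate(f)]
        report.counts[name] = len(tags)
        report.audit[name] = tags

    tally("hypothetical_CDS", lambda f: _matches(f.product, lex["hypothetical"]))
    report.counts["assigned_function_CDS"] = (
        report.counts["CDS"] - report.counts["hypothetical_CDS"]
    )
    for fam in TRANSPORTER_LEXICONS:
        tally(f"transporter_{fam}", lambda f, fam=fam: _matches(f.product, lex[fam]))
    report.counts["transporters_total"] = sum(
        report.counts[f"transporter_{fam}"] for fam in TRANSPORTER_LEXICONS
    )
    tally("integrases", lambda f: _matches(f.product, lex["integrase"]))
    tally("IS_elements", lambda f: _matches(f.product, lex["IS"]))

    report.ta_pairs = find_ta_pairs(genome)
    report.counts["TA_pairs"] = len(report.ta_pairs)
    return report
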