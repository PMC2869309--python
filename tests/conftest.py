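"""Shared fixtures: a synthetic genome pair with ground truth, and a tiny
hand-written GenBank record for coordinate-convention checks."""

import pytest

from genarch.genome_io import AnnotatedGenome, Feature, SeqRecord
from genarch.orthology import best_hits, classify_orthologs
from genarch.simulate import (
    GenomeConfig,
    IslandSpec,
    derive_sister_genome,
    generate_genome,
)

PAIR_SEED = 11


@pytest.fixture(scope="session")
def pair_config():
    return GenomeConfig(
        length=200_000,
        n_genes=150,
        islands=(IslandSpec(n_genes=8), IslandSpec(n_genes=6)),
    )


@pytest.fixture(scope="session")
def genome_truth(pair_config):
    return generate_genome(pair_config, seed=PAIR_SEED)


@pytest.fixture(scope="session")
def genome(genome_truth):
    return genome_truth[0]


@pytest.fixture(scope="session")
def truth(genome_truth):
    return genome_truth[1]


@pytest.fixture(scope="session")
def sister_pair(genome_truth):
    genome, truth = genome_truth
    return derive_sister_genome(genome, truth, divergence=0.85, seed=PAIR_SEED + 1)


@pytest.fixture(scope="session")
def ortholog_pairs(genome_truth, sister_pair):
    genome, _ = genome_truth
    sister, _ = sister_pair
    ab = best_hits(genome, sister)
    ba = best_hits(sister, genome)
    return classify_orthologs(ab, ba)


MINI_GENBANK = """\
LOCUS       MINI                    1000 bp    DNA     circular BCT 01-JAN-2000
DEFINITION  Hand-written miniature replicon.
ACCESSION   MINI
VERSION     MINI.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
FEATURES             Location/Qualifiers
     source          1..1000
                     /organism="synthetic construct"
     CDS             101..160
                     /locus_tag="MINI_0001"
                     /product="demo protein"
     CDS             complement(201..260)
                     /locus_tag="MINI_0002"
                     /product="reverse demo protein"
     tRNA            300..375
                     /product="tRNA-Gly"
     CDS             join(951..1000,1..40)
                     /locus_tag="MINI_0003"
                     /product="origin-spanning protein"
ORIGIN
"""


def _mini_sequence():
    # deterministic filler with an ATG...stop open frame under each CDS
    seq = list("ACGT" * 250)
    seq[100:160] = list("ATG" + "GCT" * 18 + "TAA")          # MINI_0001 (+)
    # MINI_0002 on - strand: forward spelling is revcomp(ATG GCA... TAA)
    core = "ATG" + "GCA" * 18 + "TAA"
    comp = core.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    seq[200:260] = list(comp)
    seq[950:1000] = list("ATG" + "GAT" * 15 + "GA")          # wraps: 50 bp here
    seq[0:40] = list("T" + "GAA" * 12 + "TAA")               # ...40 bp after wrap
    return "".join(seq)


@pytest.fixture()
def mini_genbank(tmp_path):
    seq = _mini_sequence()
    lines = []
    for i in range(0, 1000, 60):
        chunk = seq[i : i + 60]
        blocks = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {blocks}")
    text = MINI_GENBANK + "\n".join(lines) + "\n//\n"
    path = tmp_path / "mini.gbk"
    path.write_text(text)
    return path


def toy_genome(tags, length_per_gene=90, topology="circular", products=None):
    """Minimal annotated genome from an ordered locus-tag list (for synteny)."""
    products = products or {}
    feats = []
    pos = 10
    for tag in tags:
        feats.append(
            Feature(
                start=pos, end=pos + length_per_gene, kind="CDS", strand=1,
                locus_tag=tag, product=products.get(tag, "protein"),
            )
        )
        pos += length_per_gene + 10
    record = SeqRecord(id="toy", sequence="A" * (pos + 10), topology=topology)
    return AnnotatedGenome(record=record, features=feats)
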