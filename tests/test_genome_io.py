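"""Coordinate conventions, translation, coding density and GC content."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genarch import genome_io as gio
from genarch.genome_io import (
    AnnotatedGenome,
    Feature,
    GenomeIOError,
    SeqRecord,
    coding_density,
    gc_content,
    read_genbank,
    translate_cds,
    write_features,
    write_genbank,
)

# independent translation oracle: the standard code laid out in TCAG order
_TCAG = "TCAG"
_AA_ORDER = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
CODON_ORACLE = {
    a + b + c: _AA_ORDER[16 * i + 4 * j + k]
    for i, a in enumerate(_TCAG)
    for j, b in enumerate(_TCAG)
    for k, c in enumerate(_TCAG)
}


def _oracle_translate(nt: str) -> str:
    aa = "".join(CODON_ORACLE[nt[i : i + 3]] for i in range(0, len(nt), 3))
    return aa[:-1] if aa.endswith("*") else aa


class TestReadGenBank:
    def test_one_based_inclusive_converts_to_half_open(self, mini_genbank):
        g = read_genbank(mini_genbank)
        f = g.by_tag("MINI_0001")
        assert (f.start, f.end, f.strand) == (100, 160, 1)

    def test_minus_strand_and_kinds(self, mini_genbank):
        g = read_genbank(mini_genbank)
        assert g.by_tag("MINI_0002").strand == -1
        assert [f.kind for f in g.features].count("tRNA") == 1
        assert g.record.topology == "circular"
        assert g.record.length == 1000

    def test_origin_spanning_join_collapses_to_wrap(self, mini_genbank):
        g = read_genbank(mini_genbank)
        f = g.by_tag("MINI_0003")
        assert f.wraps and (f.start, f.end) == (950, 40)
        assert f.length(g.record.length) == 90

    def test_genbank_round_trip_preserves_features(self, mini_genbank, tmp_path):
        g = read_genbank(mini_genbank)
        out = tmp_path / "rt.gbk"
        write_genbank(g, out)
        g2 = read_genbank(out)
        assert g2.record.sequence == g.record.sequence
        assert [
            (f.start, f.end, f.strand, f.kind, f.locus_tag) for f in g2.features
        ] == [(f.start, f.end, f.strand, f.kind, f.locus_tag) for f in g.features]

    def test_generator_output_round_trips(self, genome, tmp_path):
        out = tmp_path / "syn.gbk"
        write_genbank(genome, out)
        g2 = read_genbank(out)
        assert g2.record.sequence == genome.record.sequence
        assert [(f.start, f.end, f.kind) for f in g2.features] == [
            (f.start, f.end, f.kind) for f in genome.features
        ]

    def test_multi_record_file_rejected(self, mini_genbank, tmp_path):
        text = mini_genbank.read_text()
        two = tmp_path / "two.gbk"
        two.write_text(text + text)
        with pytest.raises(GenomeIOError, match="one replicon at a time"):
            read_genbank(two)


class TestTranslateCds:
    def test_plus_strand_standard_code(self):
        rec = SeqRecord(id="x", sequence="ATGGCTTAA", topology="linear")
        g = AnnotatedGenome(record=rec, features=[])
        f = Feature(start=0, end=9, kind="CDS", strand=1, locus_tag="t")
        assert translate_cds(g, f) == "MA"

    def test_minus_strand_is_revcomp_of_plus(self):
        from genarch.genome_io import revcomp

        rec = SeqRecord(id="x", sequence=revcomp("ATGGCTTAA"), topology="linear")
        g = AnnotatedGenome(record=rec, features=[])
        f = Feature(start=0, end=9, kind="CDS", strand=-1, locus_tag="t")
        assert translate_cds(g, f) == "MA"

    def test_internal_stop_warns_and_truncates(self):
        rec = SeqRecord(id="x", sequence="ATGTAAGCTTAA", topology="linear")
        g = AnnotatedGenome(record=rec, features=[])
        f = Feature(start=0, end=12, kind="CDS", strand=1, locus_tag="t")
        with pytest.warns(gio.PseudogeneWarning):
            assert translate_cds(g, f) == "M"

    def test_non_triplet_length_rejected(self):
        rec = SeqRecord(id="x", sequence="ATGGCTTAAC", topology="linear")
        g = AnnotatedGenome(record=rec, features=[])
        f = Feature(start=0, end=10, kind="CDS", strand=1, locus_tag="t")
        with pytest.raises(GenomeIOError, match="divisible by 3"):
            translate_cds(g, f)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.sampled_from(sorted(CODON_ORACLE)), min_size=2, max_size=60),
           st.sampled_from([1, -1]))
    def test_random_cds_matches_codon_table_oracle(self, codons, strand):
        from genarch.genome_io import revcomp

        nt = "ATG" + "".join(c for c in codons if CODON_ORACLE[c] != "*") + "TAA"
        rec = SeqRecord(
            id="x", sequence=nt if strand == 1 else revcomp(nt), topology="linear"
        )
        g = AnnotatedGenome(record=rec, features=[])
        f = Feature(start=0, end=len(nt), kind="CDS", strand=strand, locus_tag="t")
        assert translate_cds(g, f) == _oracle_translate(nt)


class TestCodingDensity:
    def test_overlapping_cds_counted_once(self):
        rec = SeqRecord(id="x", sequence="A" * 1000, topology="circular")
        feats = [
            Feature(start=0, end=400, kind="CDS", strand=1, locus_tag="a"),
            Feature(start=300, end=600, kind="CDS", strand=1, locus_tag="b"),
        ]
        g = AnnotatedGenome(record=rec, features=feats)
        assert coding_density(g) == pytest.approx(60.0)

    def test_no_cds_gives_zero(self):
        rec = SeqRecord(id="x", sequence="A" * 100, topology="circular")
        assert coding_density(AnnotatedGenome(record=rec, features=[])) == 0.0

    def test_wrapping_cds_counted_once(self):
        rec = SeqRecord(id="x", sequence="A" * 1000, topology="circular")
        f = Feature(start=900, end=100, kind="CDS", strand=1, locus_tag="w",
                    wraps=True)
        g = AnnotatedGenome(record=rec, features=[f])
        assert coding_density(g) == pytest.approx(20.0)

    def test_invariant_under_rotation_of_coordinates(self, genome):
        # rotate every (non-wrapping) feature by a constant offset mod L
        L = genome.record.length
        shift = 12_345
        seq = genome.record.sequence
        rec = SeqRecord(id="r", sequence=seq[shift:] + seq[:shift],
                        topology="circular")
        feats = []
        for f in genome.cds():
            s, e = (f.start - shift) % L, (f.end - shift) % L
            if s < e:
                feats.append(Feature(start=s, end=e, kind="CDS", strand=f.strand,
                                     locus_tag=f.locus_tag))
            else:
                feats.append(Feature(start=s, end=e, kind="CDS", strand=f.strand,
                                     locus_tag=f.locus_tag, wraps=True))
        rotated = AnnotatedGenome(record=rec, features=feats)
        assert coding_density(rotated) == pytest.approx(coding_density(genome))


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 0.0), ("GCGC", 100.0), ("ACGT", 50.0),
                         ("ACGTNNNN", 50.0)]
    )
    def test_basic_values_and_n_exclusion(self, seq, expected):
        assert gc_content(SeqRecord(id="x", sequence=seq, topology="linear")) == expected

    def test_all_n_is_an_error(self):
        with pytest.raises(GenomeIOError):
            gc_content(SeqRecord(id="x", sequence="NNNN", topology="linear"))


class TestWriteFeatures:
    def test_gff3_is_one_based_inclusive(self, tmp_path):
        rec = SeqRecord(id="x", sequence="A" * 200, topology="linear")
        f = Feature(start=100, end=160, kind="CDS", strand=1, locus_tag="t1")
        g = AnnotatedGenome(record=rec, features=[f])
        out = tmp_path / "f.gff3"
        write_features(g, "GFF3", out)
        cols = out.read_text().splitlines()[1].split("\t")
        assert (cols[3], cols[4]) == ("101", "160")

    def test_bed_is_zero_based_half_open(self, tmp_path):
        rec = SeqRecord(id="x", sequence="A" * 200, topology="linear")
        f = Feature(start=100, end=160, kind="CDS", strand=1, locus_tag="t1")
        g = AnnotatedGenome(record=rec, features=[f])
        out = tmp_path / "f.bed"
        write_features(g, "BED", out)
        cols = out.read_text().splitlines()[0].split("\t")
        assert (cols[1], cols[2]) == ("100", "160")

    def test_gff3_read_write_round_trip_is_byte_identical(self, genome, tmp_path):
        out1 = tmp_path / "a.gff3"
        write_features(genome, "GFF3", out1)
        g2 = gio.read_gff3(out1, genome)
        out2 = tmp_path / "b.gff3"
        write_features(g2, "GFF3", out2)
        assert out1.read_bytes() == out2.read_bytes()

    def test_unknown_format_rejected(self, genome, tmp_path):
        with pytest.raises(GenomeIOError, match="unknown feature format"):
            write_features(genome, "XLSX", tmp_path / "x")
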