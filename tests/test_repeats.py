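"""Palindromic-repeat scanning, the general inverted-repeat scanner, and
gene-context classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genarch.genome_io import AnnotatedGenome, Feature, SeqRecord, revcomp
from genarch.repeats import (
    RepeatHit,
    classify_repeat_context,
    cluster_sizes,
    find_degenerate_palindromes,
    find_inverted_repeats,
    loop_composition_table,
)

STEM = "CCCTCTCCC"
RC = revcomp(STEM)


def _brute_palindromes(seq, stem=STEM, loop_min=2, loop_max=3, circular=True):
    """Enumerate every qualifying substring directly."""
    L = len(seq)
    scan = seq + (seq[: 2 * len(stem) + loop_max - 1] if circular else "")
    rc = revcomp(stem)
    found = {}
    for i in range(L):
        for ll in range(loop_min, loop_max + 1):
            s = scan[i : i + len(stem)]
            loop = scan[i + len(stem) : i + len(stem) + ll]
            t = scan[i + len(stem) + ll : i + 2 * len(stem) + ll]
            if s == stem and t == rc and len(t) == len(stem) and set(loop) <= set("ACGT"):
                if i not in found:
                    found[i] = loop
                break
    return sorted(found.items())


class TestDegeneratePalindromes:
    def test_planted_instances_found_exactly(self):
        rng = np.random.default_rng(7)
        seq = list("".join(rng.choice(list("AT"), size=5000)))
        planted = {100: "TG", 2000: "ACA", 4000: "AC"}
        for pos, loop in planted.items():
            unit = STEM + loop + RC
            seq[pos : pos + len(unit)] = list(unit)
        r = SeqRecord(id="x", sequence="".join(seq), topology="circular")
        hits = find_degenerate_palindromes(r)
        assert {(h.start, h.loop) for h in hits} == set(planted.items())

    def test_no_stem_no_hits(self):
        r = SeqRecord(id="x", sequence="AT" * 500, topology="circular")
        assert find_degenerate_palindromes(r) == []

    def test_shortest_loop_wins_at_shared_start(self):
        # CCCTCTCCC + TG + GGGAGAGGG... a 3-loop "TGG" also matches at the
        # same start when the tail still spells the reverse-complement stem
        seq = "A" * 20 + STEM + "TG" + RC + "GGA" + "A" * 20
        r = SeqRecord(id="x", sequence=seq, topology="linear")
        hits = find_degenerate_palindromes(r)
        assert len(hits) == 1 and hits[0].loop == "TG"

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.integers(0, 3))
    def test_equals_exhaustive_enumeration(self, seed, n_plant):
        rng = np.random.default_rng(seed)
        seq = list("".join(rng.choice(list("ACGT"), size=3000)))
        for k in range(n_plant):
            pos = 30 + 700 * k + int(rng.integers(0, 300))
            loop = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 4))))
            unit = STEM + loop + RC
            seq[pos : pos + len(unit)] = list(unit)
        s = "".join(seq)
        r = SeqRecord(id="x", sequence=s, topology="circular")
        got = [(h.start, h.loop) for h in find_degenerate_palindromes(r)]
        assert got == _brute_palindromes(s)

    def test_hit_count_invariant_under_reverse_complement(self, genome):
        fwd = find_degenerate_palindromes(genome.record)
        rc_rec = SeqRecord(id="rc", sequence=revcomp(genome.record.sequence),
                           topology="circular")
        rev = find_degenerate_palindromes(rc_rec)
        assert len(fwd) == len(rev)

    def test_finds_all_planted_generator_repeats(self, genome, truth):
        hits = find_degenerate_palindromes(genome.record)
        assert {h.start for h in hits} == {r["start"] for r in truth.repeats}
        by_start = {h.start: h.loop for h in hits}
        for r in truth.repeats:
            assert by_start[r["start"]] == r["loop"]


class TestInvertedRepeats:
    def test_direct_repeat_is_not_an_inverted_repeat(self):
        # two identical (not reverse-complementary) arms must not qualify
        seq = "AAAA" + "GCATCA" + "TTT" + "GCATCA" + "AAAA"
        r = SeqRecord(id="x", sequence=seq, topology="linear")
        hits = find_inverted_repeats(r, min_stem=6, max_loop=4)
        assert hits == []

    def test_planted_perfect_hairpin(self):
        stem = "AGGCTGCA"
        seq = "T" * 40 + stem + "AAAA" + revcomp(stem) + "T" * 40
        r = SeqRecord(id="x", sequence=seq, topology="linear")
        hits = find_inverted_repeats(r, min_stem=8, max_loop=4)
        spans = {(h.start, h.end) for h in hits}
        assert (40, 40 + 2 * len(stem) + 4) in spans

    def test_every_hit_is_definitionally_palindromic(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        r = SeqRecord(id="x", sequence=seq, topology="linear")
        for h in find_inverted_repeats(r, min_stem=5, max_loop=6):
            left = seq[h.start : h.start + len(h.stem)]
            right = seq[h.end - len(h.stem) : h.end]
            assert revcomp(left) == right

    def test_budget_guard(self):
        r = SeqRecord(id="x", sequence="ACGT" * 300, topology="linear")
        with pytest.raises(ValueError, match="budget"):
            find_inverted_repeats(r, min_stem=4, max_loop=8, candidate_budget=10)


def _hit(start, loop="TG"):
    return RepeatHit(start=start, end=start + 18 + len(loop), stem=STEM, loop=loop)


class TestContextClassification:
    def _genome(self, feats, length=3000):
        rec = SeqRecord(id="x", sequence="A" * length, topology="linear")
        return AnnotatedGenome(record=rec, features=feats)

    def test_downstream_cluster_of_two(self):
        g = self._genome(
            [Feature(start=400, end=1000, kind="CDS", strand=1, locus_tag="g1")]
        )
        hits = classify_repeat_context([_hit(1010), _hit(1040)], g)
        assert all(h.context == "three_prime_proximal" for h in hits)
        assert hits[0].cluster_id == hits[1].cluster_id
        assert cluster_sizes(hits) == {2: 1}

    def test_no_features_everything_intergenic(self):
        g = self._genome([])
        hits = classify_repeat_context([_hit(100), _hit(500)], g)
        assert all(h.context == "intergenic_other" for h in hits)
        assert all(h.cluster_id is None for h in hits)

    def test_minus_strand_three_prime_side(self):
        # - strand gene: its 3' end is the feature start; upstream window below it
        g = self._genome(
            [Feature(start=1000, end=1600, kind="CDS", strand=-1, locus_tag="g1")]
        )
        (h,) = classify_repeat_context([_hit(950)], g)
        assert h.context == "three_prime_proximal" and h.nearest_gene == "g1"

    def test_three_prime_takes_precedence_over_intragenic(self):
        # hit inside g2 but also within g1's 3' window: 3'-proximal wins
        g = self._genome(
            [
                Feature(start=100, end=1000, kind="CDS", strand=1, locus_tag="g1"),
                Feature(start=1005, end=1600, kind="CDS", strand=-1, locus_tag="g2"),
            ]
        )
        (h,) = classify_repeat_context([_hit(1010)], g)
        assert h.context == "three_prime_proximal" and h.nearest_gene == "g1"

    def test_intragenic_label(self):
        g = self._genome(
            [Feature(start=100, end=1000, kind="CDS", strand=1, locus_tag="g1")]
        )
        (h,) = classify_repeat_context([_hit(500)], g)
        assert h.context == "intragenic"

    def test_cluster_members_mutually_within_gap(self, genome):
        from genarch.repeats import find_degenerate_palindromes

        hits = classify_repeat_context(
            find_degenerate_palindromes(genome.record), genome
        )
        by_cluster = {}
        for h in hits:
            if h.cluster_id is not None:
                by_cluster.setdefault(h.cluster_id, []).append(h)
        for members in by_cluster.values():
            members.sort(key=lambda h: h.start)
            for a, b in zip(members, members[1:]):
                assert b.start - a.end <= 100

    def test_generator_repeats_are_three_prime_proximal(self, genome, truth):
        from genarch.repeats import find_degenerate_palindromes

        hits = classify_repeat_context(
            find_degenerate_palindromes(genome.record), genome
        )
        frac = np.mean([h.context == "three_prime_proximal" for h in hits])
        assert frac == 1.0


class TestLoopTable:
    def test_counts_and_order(self):
        hits = [_hit(0, "TG"), _hit(50, "TG"), _hit(100, "ACA")]
        assert loop_composition_table(hits) == [("TG", 2), ("ACA", 1)]

    def test_empty(self):
        assert loop_composition_table([]) == []
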