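"""Synton detection, synteny statistics and non-syntenic region extraction."""

import itertools

import numpy as np
import pytest

from genarch.orthology import OrthologPair
from genarch.synteny import (
    detect_syntons,
    nonsyntenic_regions,
    region_table,
    synton_stats,
)

from conftest import toy_genome


def _pairs(mapping):
    return [
        OrthologPair(a=a, b=b, identity=90.0, coverage_a=90.0, coverage_b=90.0)
        for a, b in mapping.items()
    ]


def _brute_runs(order_a, order_b, mapping, min_genes, circular=True):
    """Exhaustive enumeration oracle: every (start, length, direction) run is
    checked directly against the definition (max_gap = 0)."""
    nA, nB = len(order_a), len(order_b)
    pos_b = {t: i for i, t in enumerate(order_b)}
    valid = []
    for start, length, d in itertools.product(range(nA), range(min_genes, nA + 1),
                                              (1, -1)):
        idxs = [(start + k) % nA if circular else start + k for k in range(length)]
        if not circular and idxs[-1] >= nA:
            continue
        tags = [order_a[i] for i in idxs]
        if any(t not in mapping or mapping[t] not in pos_b for t in tags):
            continue
        bs = [pos_b[mapping[t]] for t in tags]
        ok = all((bs[k + 1] - bs[k]) % nB == d % nB for k in range(length - 1))
        if ok:
            valid.append((tuple(tags), d))
    # keep only maximal runs (not a sub-run of a longer valid run, same dir)
    maximal = []
    for tags, d in valid:
        if not any(
            d == d2 and len(tags) < len(t2)
            and any(t2[i : i + len(tags)] == tags for i in range(len(t2) - len(tags) + 1))
            for t2, d2 in valid
        ):
            maximal.append((tags, d))
    return maximal


class TestDetectSyntons:
    def test_identity_gives_one_whole_genome_synton(self):
        tags = [f"g{i}" for i in range(8)]
        A = toy_genome(tags)
        B = toy_genome(tags)
        syntons = detect_syntons(A, B, _pairs({t: t for t in tags}))
        assert len(syntons) == 1
        assert syntons[0].size == 8
        assert syntons[0].orientation == "collinear"

    def test_two_genes_below_minimum_is_no_synton(self):
        A = toy_genome(["a1", "a2", "a3", "a4", "a5", "a6"])
        B = toy_genome(["b1", "b2", "bx", "by", "bz", "bw"])
        # only a1,a2 have orthologs, adjacent in both genomes
        syntons = detect_syntons(A, B, _pairs({"a1": "b1", "a2": "b2"}))
        assert syntons == []

    def test_planted_block_in_permuted_toy_matches_oracle(self):
        rng = np.random.default_rng(5)
        tags_a = [f"a{i}" for i in range(12)]
        A = toy_genome(tags_a)
        # B carries orthologs of a3..a6 consecutively; the rest scattered
        # as non-orthologs
        tags_b = ["x0", "b3", "b4", "b5", "b6", "x1", "x2", "x3", "x4"]
        B = toy_genome(tags_b)
        mapping = {"a3": "b3", "a4": "b4", "a5": "b5", "a6": "b6"}
        syntons = detect_syntons(A, B, _pairs(mapping), min_genes=3)
        assert len(syntons) == 1
        assert syntons[0].genes_a == ("a3", "a4", "a5", "a6")
        oracle = _brute_runs(tags_a, tags_b, mapping, 3)
        best = max(oracle, key=lambda r: len(r[0]))
        assert syntons[0].genes_a == best[0]

    def test_inverted_block_detected(self):
        tags_a = [f"a{i}" for i in range(8)]
        A = toy_genome(tags_a)
        tags_b = ["b5", "b4", "b3", "y0", "y1", "y2", "y3", "y4"]
        B = toy_genome(tags_b)
        mapping = {"a3": "b3", "a4": "b4", "a5": "b5"}
        syntons = detect_syntons(A, B, _pairs(mapping), min_genes=3)
        assert len(syntons) == 1 and syntons[0].orientation == "inverted"

    @pytest.mark.parametrize("seed", range(6))
    def test_random_toys_match_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        tags_a = [f"a{i}" for i in range(n)]
        tags_b = [f"b{i}" for i in range(n)]
        perm = rng.permutation(n)
        mapping = {tags_a[i]: tags_b[perm[i]] for i in range(n)
                   if rng.random() < 0.8}
        A, B = toy_genome(tags_a), toy_genome(tags_b)
        syntons = detect_syntons(A, B, _pairs(mapping), min_genes=3)
        oracle = _brute_runs(tags_a, tags_b, mapping, 3)
        oracle_tags = {tags for tags, _ in oracle}
        # every detected synton must be a maximal valid run (or a truncation
        # forced by the non-overlap rule)
        for s in syntons:
            assert any(
                any(t2[i : i + s.size] == s.genes_a
                    for i in range(len(t2) - s.size + 1))
                for t2 in oracle_tags
            )
        # and when the oracle finds nothing, detection must agree
        if not oracle:
            assert syntons == []

    def test_recovers_expected_blocks_on_generated_pair(
        self, genome, sister_pair, ortholog_pairs
    ):
        sister, struth = sister_pair
        syntons = detect_syntons(genome, sister, ortholog_pairs)
        got = sorted(s.genes_a for s in syntons)
        expected = sorted(tuple(b) for b in struth.expected_syntons)
        assert got == expected

    def test_raising_min_genes_never_increases_count(self, genome, sister_pair,
                                                     ortholog_pairs):
        sister, _ = sister_pair
        counts = [
            len(detect_syntons(genome, sister, ortholog_pairs, min_genes=m))
            for m in (3, 5, 8, 15)
        ]
        assert counts == sorted(counts, reverse=True)


class TestSyntonStats:
    def test_small_example(self):
        tags = [f"g{i}" for i in range(16)]
        A = toy_genome(tags)
        from genarch.synteny import Synton

        syntons = [
            Synton(genes_a=tuple(tags[:3]), genes_b=("x",) * 3,
                   orientation="collinear"),
            Synton(genes_a=tuple(tags[5:10]), genes_b=("y",) * 5,
                   orientation="collinear"),
        ]
        stats = synton_stats(syntons, A)
        assert stats["synton_count"] == 2
        assert stats["mean_genes_per_synton"] == pytest.approx(4.0)
        assert stats["fraction_cds_syntenic"] == pytest.approx(0.5)

    def test_empty_is_all_zero(self):
        A = toy_genome(["g0", "g1"])
        stats = synton_stats([], A)
        assert stats == {
            "synton_count": 0,
            "mean_genes_per_synton": 0.0,
            "fraction_cds_syntenic": 0.0,
        }


class TestNonSyntenicRegions:
    def test_all_orthologous_gives_no_region(self):
        tags = [f"g{i}" for i in range(6)]
        A = toy_genome(tags)
        assert nonsyntenic_regions(A, _pairs({t: t for t in tags})) == []

    def test_planted_unique_run_found_exactly(self):
        tags = [f"g{i}" for i in range(10)]
        A = toy_genome(tags)
        mapping = {t: t for t in tags if t not in ("g4", "g5", "g6", "g7")}
        regions = nonsyntenic_regions(A, _pairs(mapping))
        assert len(regions) == 1
        assert regions[0].genes == ("g4", "g5", "g6", "g7")
        assert (regions[0].flank_left, regions[0].flank_right) == ("g3", "g8")

    def test_short_runs_below_minimum_skipped(self):
        tags = [f"g{i}" for i in range(8)]
        A = toy_genome(tags)
        mapping = {t: t for t in tags if t not in ("g2", "g3")}
        assert nonsyntenic_regions(A, _pairs(mapping), min_genes=3) == []

    def test_circular_run_joins_across_seam(self):
        tags = [f"g{i}" for i in range(10)]
        A = toy_genome(tags, topology="circular")
        mapping = {t: t for t in tags if t not in ("g9", "g0", "g1")}
        regions = nonsyntenic_regions(A, _pairs(mapping))
        assert len(regions) == 1
        assert set(regions[0].genes) == {"g9", "g0", "g1"}

    def test_matches_generator_manifest(self, genome, sister_pair, ortholog_pairs):
        _, struth = sister_pair
        regions = nonsyntenic_regions(genome, ortholog_pairs)
        got = sorted(r.genes for r in regions)
        expected = sorted(struth.expected_regions)
        assert got == expected

    def test_partition_consistency_with_syntons(self, genome, sister_pair,
                                                ortholog_pairs):
        sister, _ = sister_pair
        syntons = detect_syntons(genome, sister, ortholog_pairs)
        regions = nonsyntenic_regions(genome, ortholog_pairs)
        in_syntons = {t for s in syntons for t in s.genes_a}
        in_regions = {t for r in regions for t in r.genes}
        assert in_syntons & in_regions == set()

    def test_region_table_columns(self, genome, ortholog_pairs):
        df = region_table(nonsyntenic_regions(genome, ortholog_pairs), genome)
        assert list(df.columns) == [
            "region_id", "flank_left", "flank_right", "start", "end",
            "size_bp", "gene_count", "genes",
        ]
        assert (df["gene_count"] >= 3).all()
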