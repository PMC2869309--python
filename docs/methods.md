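# Methods

This note documents the models and procedures implemented in `genarch`,
the parameters that matter, the calibration of the one statistic that
needed calibrating, and what the synthetic benchmarks do and do not show.

## Coordinates and conventions

All internal coordinates are 0-based half-open; GenBank and GFF3 (1-based
inclusive) are converted at exactly one point each (`genome_io`). Features
spanning the origin of a circular replicon are stored once, with a wrap
flag and `end` reduced modulo the replicon length. Window scans and motif
scans treat circular sequences as logically doubled, reporting positions
modulo the length. The ambiguity code N is tolerated in sequence, excluded
from GC computations, and never matches in motif scans — a deliberately
conservative choice.

Coding density is the union of CDS intervals over the replicon length
(overlapping genes counted once, wrapping genes once). The alternative
sum-of-lengths convention differs by the amount of gene overlap, which is
why checks against published densities carry a ±0.5-point tolerance.

## Replication-origin calling

GC skew is (G−C)/(G+C) per window (windows with no G or C score 0); GC
deviation is window GC% minus replicon GC%. The skew statistic is
implemented in its standard bounded form; a printed form like "G+C/G−C" is
unbounded and undefined at G=C and is read as a typographical inversion of
the same statistic.

oriC is called at the global minimum of the cumulative skew curve and the
terminus at its maximum, reported at window midpoints. This argmin is the
maximum-likelihood changepoint for a two-level mean shift with equal
variances, so no fancier estimator was layered on top. A near-flat
cumulative curve (range below `flat_tolerance`, default 1.0 summed-skew
units) or a linear replicon yields an explicit "no transition" result.

Window size trades resolution against localization noise. Per-window skew
noise is ≈ 1/√(window·GC), so at 1000 bp windows and a ±0.04 strand bias
the argmin lands outside ±2 windows a non-negligible fraction of the time
on a 200 kb replicon. The origin benchmarks on small synthetic replicons
therefore use 4000 bp windows (~50–65 windows per replicon), where ±2
windows (±8 kb) localization is reliable down to amplitude 0.04; 1000 bp
remains the default for Mb-scale genomes, matching the usual figure-track
resolution. DnaA boxes are found by a vectorized Hamming scan of both
strands; upstream distance to a gene's start codon is measured on the
circle, in the gene's own upstream direction (start coordinate for +
genes, end for − genes, first base of the motif).

## Repeat discovery

The degenerate palindrome family is `stem + N{loop_min..loop_max} +
revcomp(stem)` with stem `CCCTCTCCC` and loops of 2–3 nt. Because the
pattern equals its own reverse complement, a forward-strand scan
enumerates every physical locus once. At a shared start the shortest
qualifying loop wins (determinism for counting); the loop alphabet is
unconstrained over {A,C,G,T}. The general inverted-repeat scanner expands
stems outward from every candidate loop placement, keeps maximal stems of
≥ `min_stem`, suppresses hits contained in longer hits, and refuses
parameter combinations whose candidate count exceeds a budget.

Context classification labels a hit 3′-proximal when it lies within
`window_3prime` (default 100 bp — the literature says "at the 3′ end of
genes" without a number; the choice is configurable and recorded in the
output metadata) downstream of a CDS stop, strand-aware; that label takes
precedence over intragenic. Consecutive 3′-proximal hits of the same gene
within the same window form clusters (singlet/duplicate/triplicate), the
pattern expected of tandem rho-independent terminators.

## Orthology, synteny, annotation transfer

Proteins are compared by local alignment with BLOSUM62 and affine gaps
(open 11, extend 1) — the classical BLASTP regime. Identity is matches
over aligned columns (gap columns in the local span count in the
denominator); coverage is the aligned span over each protein's full
length, enforced on **both** partners (the stricter reading of "80% of
their length", which suppresses short-fragment false orthologs). Exact
reproduction of any particular BLAST implementation's numbers is not
attempted; the threshold semantics are what is reproduced.

`best_hits` prunes the all-vs-all scan with a shared-5-mer prefilter
(candidates need ≥2 shared 5-mers). A pair at ≥70% identity over ≥80%
coverage of a ~100+ aa protein shares dozens of 5-mers in expectation, so
the filter cannot drop a threshold-passing ortholog; the test suite checks
the prefiltered result against the unfiltered scan. Ties resolve to the
lexicographically smallest tag everywhere, making the whole comparative
layer deterministic.

Orthologs are bidirectional best hits. Transfer eligibility is two-tier:
identity ≥80 and mutual coverage ≥80, or (gene inside a synton) identity
≥70 and mutual coverage ≥80. The synteny flag is applied in a single pass
(BBH → syntons → relaxed rule), not iterated. On transfer, conflicting
eligible sources resolve to the highest identity; exact ties transfer
nothing.

Syntons are maximal runs of consecutive genes of A whose partners advance
by consecutive steps in B, in one direction (collinear or inverted), with
up to `max_gap` skipped genes (default 0: "consecutive" read literally;
the gap is exposed because annotation platforms tolerate small gaps).
First/last genes of circular replicons are neighbors. Runs shorter than
`min_genes` (default 3) are dropped, and overlapping runs are resolved
longest-first in A. Non-syntenic regions are the complement: maximal runs
of ≥3 consecutive A genes with no ortholog at all, with flanking matched
genes recorded. By construction no gene is in both a synton and a region.

## Genomic-island criteria

Gene-based criteria use case-insensitive keyword lexicons over product
strings (integrase/recombinase/resolvase; transposase/insertion
sequence/IS; a wider MGE list; hypothetical/uncharacterized), all
config-editable — these signals live in annotation text, so the lexicons
are data, not code. Extremity means the first/last two region genes plus
the flanking matched gene. tRNA insertion requires a tRNA feature within
`flank_window` (500 bp) of either boundary. Composition deviation holds if
either the codon-usage statistic fires or the region GC differs from the
genome by ≥2.5 points ("base composition and/or phylogeny" read as
either-suffices). Hypothetical enrichment requires the region's
hypothetical fraction to exceed the genome's by ≥0.25. MGE hotspot needs
≥2 MGE-lexicon genes inside the region or overlap with an externally
supplied prophage interval (prophage prediction itself is out of scope —
intervals are consumed as input). Cross-host conservation needs external
genome panels and is NA (excluded from the count) unless they are given.
A region is an island when ≥3 criteria hold.

The codon-usage statistic is the Manhattan distance between the region's
and the genome's 64-codon frequency vectors (range [0, 2]); regions with
fewer than 100 codons return NA rather than a noisy guess. The threshold
0.35 was calibrated on the generator's null: windows of five consecutive
genes drawn from the host codon model have a sampling-noise distance of
~0.15–0.25, and the shipped calibration test verifies a false-positive
rate <5% over 200 such windows, while a +0.08 GC shift with a sharpened
codon preference (the island model) sits well above 0.35. The statistic
and threshold are this package's own; published island counts obtained
with other platforms' statistics are therefore comparable only softly.

## qPCR fold induction

Comparative-Ct with a reference gene: per replicate r, ΔΔCt_r =
(Ct_tgt,trt − Ct_ref,trt)_r − (Ct_tgt,ctl − Ct_ref,ctl)_r and fold_r =
E^(−ΔΔCt_r). Replicates are paired by index and must agree in count.
Amplification efficiency defaults to E = 2.0 (perfect doubling) and is
overridable per run. Mean ± SD is computed over the per-replicate folds
(sample SD, n−1), matching the usual "mean ± SD (N = 3)" presentation;
the reference gene against itself gives exactly 1. The computation is
invariant under adding any constant to all Ct values (plate offset).

## Synthetic data: what it emulates

The generator builds a circular replicon from a per-base model with P(G),
P(C) split (1±s)/2 at the given GC, where s = +`skew_amplitude` on the
leading replichore [oriC, terminus) and −s elsewhere. Genes are sampled
codon-wise from sense-codon weights whose marginal base usage matches the
local replichore model (− strand genes use the mirrored model), so coding
and intergenic DNA carry a coherent skew and the codon-deviation statistic
has a well-defined null. Defaults: 260 kb, GC 0.53, amplitude 0.06 —
enterobacterial GC at a skew strong enough to be unambiguous at the
benchmark replicon sizes, which are kept two orders of magnitude below a
real chromosome so that a full pairwise-proteome study runs in seconds.

Planted structure: DnaA boxes in a reserved intergenic zone at oriC;
stem-loop repeats 8–30 bp downstream of + strand gene stops, in clusters
of 1–3; adjacent same-strand toxin/antitoxin couples; islands as
contiguous gene blocks with +0.08 GC shift and sharpened codon preference,
an integrase first gene, an IS-element last gene, a tRNA at the insertion
boundary and 80% hypothetical products. With `exclusive_motifs` (default)
accidental occurrences of the repeat stem and the DnaA box are scrubbed by
single-base substitutions that avoid creating stop codons, so planted
counts are exact. A self-audit (`audit_truth`) re-verifies every manifest
fact against the emitted sequence and features, and manifest proteins are
taken from the final sequence.

The sister genome keeps the retained genes in order, mutates each protein
to a target identity (substitutions uniform over the other 19 residues,
never the initial Met), re-encodes through a GC-matched synonymous codon
model, and records the exact ortholog map, realized identities, expected
synteny blocks (retained runs split at deletions) and expected unique
regions (deletion runs, including islands). There are no indels, no rate
heterogeneity and no gene family structure — realized alignment identity
therefore tracks the target within rounding, which is exactly what the
±3-point parameter-recovery check exercises. Passing these benchmarks
shows the pipeline's logic and thresholds are correct; it does not show
robustness to real-world complications (paralogs, domain shuffling,
pseudogenes, contaminated annotation text), which the thresholds inherit
from decades of comparative-genomics practice rather than from these
tests.

## Problem sizes and determinism

Benchmarks run at: origin recovery, 20 seeds × 200 kb; island
recall/precision, 20 seeds × 260 kb with 5 planted islands and 5 plain
unique-gene runs each (recall ≥0.9, precision ≥0.8 at default criteria);
divergence recovery on a 150-gene pair; brute-force oracle equivalence for
the motif scans at 50 kb and synton enumeration at ≤30 genes. Everything
is deterministic given (config, seed): numpy `default_rng` throughout,
lexicographic tie-breaks in alignment/greedy steps, and re-running any
driver with the same seed reproduces byte-identical artifacts.

## Known limitations

* The origin caller assumes a single oriC/terminus pair; multi-replicon or
  skew-less (e.g. some plasmid) topologies return "no transition" rather
  than a guess.
* The island rule is annotation-driven; unannotated or poorly annotated
  genomes lose the gene-based criteria and fall back on composition alone.
* The 70/80 synteny-relaxed transfer tier is applied once, not iterated to
  a fixed point; iterating changes few calls but would make the output
  depend on iteration order.
* Census tallies are keyword matches and inherit the annotation's
  vocabulary; published manually curated tallies will differ where the
  curators used information beyond product strings.
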