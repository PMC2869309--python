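#!/usr/bin/env python
"""Orthology and synteny between genome A and the comparator genome B.

Computes bidirectional best hits, applies the two-tier transfer rule
(80%/80%, or 70%/80% inside synteny blocks), detects syntons and
non-syntenic candidate regions, and transfers annotations.  Writes the
ortholog table, synton table and region table (TSV) plus a summary JSON.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from genarch.genome_io import read_genbank
from genarch.orthology import best_hits, classify_orthologs, transfer_annotations
from genarch.synteny import (
    detect_syntons,
    nonsyntenic_regions,
    region_table,
    synton_stats,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--min-genes", type=int, default=3)
    ap.add_argument("--max-gap", type=int, default=0)
    args = ap.parse_args()

    A = read_genbank(args.outdir / "genome_a.gbk")
    B = read_genbank(args.outdir / "genome_b.gbk")
    ab = best_hits(A, B)
    ba = best_hits(B, A)
    pairs = classify_orthologs(ab, ba)
    syntons = detect_syntons(A, B, pairs, min_genes=args.min_genes,
                             max_gap=args.max_gap)
    syntenic_tags = {t for s in syntons for t in s.genes_a}
    # one relaxation pass: genes inside syntons get the 70%/80% tier
    pairs = classify_orthologs(ab, ba, syntenic_tags=syntenic_tags)
    regions = nonsyntenic_regions(A, pairs, min_genes=args.min_genes)
    _, n_transferred = transfer_annotations(pairs, source=B, target=A)

    pd.DataFrame([p.__dict__ for p in pairs]).to_csv(
        args.outdir / "orthologs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"synton_id": i + 1, "size": s.size, "orientation": s.orientation,
          "genes_a": ",".join(s.genes_a), "genes_b": ",".join(s.genes_b)}
         for i, s in enumerate(syntons)]
    ).to_csv(args.outdir / "syntons.tsv", sep="\t", index=False)
    region_table(regions, A).to_csv(args.outdir / "regions.tsv", sep="\t",
                                    index=False)

    stats = synton_stats(syntons, A)
    summary = {
        **stats,
        "ortholog_pairs": len(pairs),
        "transfer_eligible": sum(p.transfer_eligible for p in pairs),
        "annotation_transfers": n_transferred,
        "region_count": len(regions),
        "min_genes": args.min_genes,
        "max_gap": args.max_gap,
    }
    (args.outdir / "synteny_summary.json").write_text(json.dumps(summary, indent=1))
    print(f"{len(pairs)} BBH ortholog pairs; {stats['synton_count']} syntons "
          f"(mean {stats['mean_genes_per_synton']:.1f} genes, "
          f"{100 * stats['fraction_cds_syntenic']:.1f}% of CDS syntenic); "
          f"{len(regions)} non-syntenic regions; "
          f"{n_transferred} annotations transferred")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
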