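#!/usr/bin/env python
"""Checks against the deposited Enterobacter sp. 638 genome records.

Requires local GenBank flat files under data/records/ (CP000653.gbk for the
chromosome, CP000654.gbk for plasmid pENT638-1); run with --fetch-help for
download instructions.  Recomputes replicon lengths, GC content, feature
counts, coding densities, the 100-member palindromic-repeat family, the
GC-skew origin call and the DnaA-box distance to dnaA.  With --comparator, a
comparator proteome (e.g. E. coli K12 MG1655) enables the synteny survey,
sweeping the gap tolerance over 0..5 (slow: all-vs-all protein comparison).
"""

import argparse
import json
from pathlib import Path

FETCH_HELP = """\
Fetch the deposited records once (any of the usual routes works), e.g.:

  efetch -db nuccore -id CP000653.1 -format gbwithparts > data/records/CP000653.gbk
  efetch -db nuccore -id CP000654.1 -format gbwithparts > data/records/CP000654.gbk

or download the GenBank (full) flat files from the NCBI web pages for
accessions CP000653 / CP000654 and save them under data/records/.
"""


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--records", type=Path,
                    default=Path(__file__).resolve().parent.parent
                    / "data" / "records")
    ap.add_argument("--comparator", type=Path, default=None,
                    help="GenBank file of a comparator genome (optional)")
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--fetch-help", action="store_true")
    args = ap.parse_args()
    if args.fetch_help:
        print(FETCH_HELP)
        return 0

    chrom_path = args.records / "CP000653.gbk"
    plasmid_path = args.records / "CP000654.gbk"
    if not chrom_path.exists() or not plasmid_path.exists():
        print("deposited records not found under", args.records)
        print(FETCH_HELP)
        return 1

    from genarch.census import census
    from genarch.genome_io import coding_density, gc_content, read_genbank
    from genarch.origin import (
        call_origin, distance_upstream, find_dnaa_boxes, gc_skew_profile,
    )
    from genarch.repeats import (
        classify_repeat_context, find_degenerate_palindromes,
        loop_composition_table,
    )

    out = {}
    chrom = read_genbank(chrom_path)
    plasmid = read_genbank(plasmid_path)
    for name, g in (("chromosome", chrom), ("plasmid", plasmid)):
        out[name] = {
            "length_bp": g.record.length,
            "gc_pct": round(gc_content(g.record), 2),
            "cds": len(g.cds()),
            "trna": sum(1 for f in g.features if f.kind == "tRNA"),
            "coding_density_pct": round(coding_density(g), 2),
        }
    hits = classify_repeat_context(
        find_degenerate_palindromes(chrom.record), chrom)
    out["chromosome"]["palindromic_repeats"] = len(hits)
    out["chromosome"]["repeat_loops_top"] = loop_composition_table(hits)[:4]
    call = call_origin(gc_skew_profile(chrom.record, 1000))
    out["chromosome"]["oriC_called"] = call.oriC
    out["chromosome"]["terminus_called"] = call.terminus
    L = chrom.record.length
    if call.found:
        boxes = find_dnaa_boxes(
            chrom.record,
            region=((call.oriC - 50_000) % L, (call.oriC + 50_000) % L))
        dnaa = next(
            (f for f in chrom.cds()
             if "dnaA" in f.qualifier("gene")
             or "chromosomal replication init" in f.product.lower()), None)
        if dnaa and boxes:
            out["chromosome"]["dnaa_box_distances_bp"] = sorted(
                distance_upstream(b, dnaa, L) for b, _, _ in boxes)
    out["chromosome"]["census"] = census(chrom).counts
    out["plasmid"]["census"] = census(plasmid).counts

    if args.comparator is not None:
        from genarch.orthology import best_hits, classify_orthologs
        from genarch.synteny import (
            detect_syntons, nonsyntenic_regions, synton_stats,
        )

        comp = read_genbank(args.comparator)
        ab = best_hits(chrom, comp)
        ba = best_hits(comp, chrom)
        pairs = classify_orthologs(ab, ba)
        sweep = {}
        for gap in range(6):
            syntons = detect_syntons(chrom, comp, pairs, max_gap=gap)
            sweep[gap] = synton_stats(syntons, chrom)
        out["synteny_gap_sweep"] = sweep
        out["nonsyntenic_region_count"] = len(nonsyntenic_regions(chrom, pairs))

    args.outdir.mkdir(parents=True, exist_ok=True)
    (args.outdir / "deposited_record_checks.json").write_text(
        json.dumps(out, indent=1))
    print(json.dumps(out, indent=1))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
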