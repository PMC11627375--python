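#!/usr/bin/env python
"""Annotate variants against gene models and score thresholds.

Classifies every variant (exonic / promoter / intronic / intergenic, with
TSS +/- 2 kb promoters), joins the score table, and prints the location
breakdown and how many variants pass the splice and regulatory filters.
Writes results/annotated.tsv.
"""

import argparse
from collections import Counter
from pathlib import Path

from pleiogene.genome_core import read_chrom_sizes, read_genes_gff3, read_variants
from pleiogene.variant_annotation import (
    GeneIndex,
    classify_location,
    is_regulatory,
    is_splice_altering,
    read_scores,
    summary_location,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    args = parser.parse_args()

    assembly = read_chrom_sizes(args.simdir / "chrom.sizes")
    variants = read_variants(args.simdir / "variants.tsv", assembly)
    index = GeneIndex(read_genes_gff3(args.simdir / "genes.gff3"))
    records = read_scores(args.simdir / "scores.tsv")

    tally = Counter()
    n_splice = n_reg = 0
    out = ROOT / "results" / "annotated.tsv"
    with open(out, "w") as fh:
        fh.write("variant_id\tcancer\tsummary_class\tsplice_altering\tregulatory\n")
        for v in variants:
            loc = classify_location(v, index)
            rec = records[v.id]
            rec.location_class = loc
            summary = summary_location(loc)
            tally[summary] += 1
            splice = summary == "intronic" and is_splice_altering(rec)
            reg = is_regulatory(rec)
            n_splice += splice
            n_reg += reg
            fh.write(f"{v.id}\t{v.cancer}\t{summary}\t{int(splice)}\t{int(reg)}\n")

    total = sum(tally.values())
    for cls in ("exonic", "promoter", "intronic", "intergenic"):
        print(f"  {cls:11s} {tally[cls]:4d} ({100 * tally[cls] / total:.1f}%)")
    print(f"  {n_splice} potential splice-altering intronic variants")
    print(f"  {n_reg} variants pass the regulatory probability filter (> 0.55)")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
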