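#!/usr/bin/env python
"""Construct multi-cancer risk regions.

Extends each cancer's index variants by 0.5 Mb, merges, and keeps maximal
segments covered by at least two cancers. Writes results/regions.bed and a
per-region summary (cancer set, independent signal counts), and prints the
combination histogram.
"""

import argparse
from pathlib import Path

from pleiogene.genome_core import read_chrom_sizes, read_variants, write_bed
from pleiogene.region_builder import (
    build_cancer_regions,
    build_mhdcr_regions,
    combination_summary,
    count_signals,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    parser.add_argument("--flank", type=int, default=500_000)
    args = parser.parse_args()

    assembly = read_chrom_sizes(args.simdir / "chrom.sizes")
    variants = [
        v for v in read_variants(args.simdir / "variants.tsv", assembly) if v.is_index
    ]
    regions = build_mhdcr_regions(
        build_cancer_regions(variants, assembly, flank=args.flank)
    )
    count_signals(regions, variants)
    write_bed(
        ROOT / "results" / "regions.bed",
        [(r.interval, str(r.region_id)) for r in regions],
    )
    with open(ROOT / "results" / "regions_summary.tsv", "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tcancers\tsignal_counts\n")
        for r in regions:
            counts = ";".join(f"{c}:{n}" for c, n in sorted(r.signal_counts.items()))
            fh.write(
                f"{r.region_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{','.join(sorted(r.cancers))}\t{counts}\n"
            )
    summary = combination_summary(regions)
    print(f"{summary['n_regions']} multi-cancer regions")
    for k in sorted(summary["by_cardinality"]):
        print(f"  {summary['by_cardinality'][k]} regions shared by {k} cancers")
    print("wrote results/regions.bed, results/regions_summary.tsv")


if __name__ == "__main__":
    main()
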