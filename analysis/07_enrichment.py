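#!/usr/bin/env python
"""Test candidate genes for COSMIC and drug-target enrichment.

Fisher's exact test (one-sided) against the background of all
protein-coding genes at the multi-cancer regions, plus the matched
region-resampling null for a z-scaled effect. Writes
results/enrichment.json.
"""

import argparse
import csv
import json
from pathlib import Path

from pleiogene.genome_core import read_bed, read_genes_gff3
from pleiogene.integration_enrichment import (
    CandidateGene,
    fisher_enrichment,
    genes_at_regions,
    matched_permutation_z,
)
from pleiogene.region_builder import MHDCRRegion

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=11)
    parser.add_argument("--n-perms", type=int, default=10_000)
    parser.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    args = parser.parse_args()

    genes = [
        g
        for g in read_genes_gff3(args.simdir / "genes.gff3")
        if g.biotype == "protein_coding"
    ]
    regions = [
        MHDCRRegion(int(name), iv, frozenset({"_a", "_b"}))
        for iv, name in read_bed(ROOT / "results" / "regions.bed")
    ]
    gene_regions = genes_at_regions(genes, regions)
    background = set(gene_regions)
    pools: dict[int, list[str]] = {}
    for gid, rids in gene_regions.items():
        for rid in rids:
            pools.setdefault(rid, []).append(gid)

    candidates = []
    with open(ROOT / "results" / "candidates.tsv") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            evidence = {
                cancer: set(row[cancer].split("|"))
                for cancer in ("breast", "endometrial", "ovarian", "prostate")
                if row.get(cancer)
            }
            candidates.append(
                CandidateGene(
                    gene_id=row["gene_id"],
                    name=row["name"],
                    biotype=row["biotype"],
                    region_ids=tuple(int(r) for r in row["regions"].split(",")),
                    evidence=evidence,
                )
            )

    out = {}
    for name in ("cosmic", "drug_target"):
        with open(args.simdir / f"{name}_genes.txt") as fh:
            members = {line.strip() for line in fh if line.strip()}
        res = fisher_enrichment({c.gene_id for c in candidates}, members, background)
        z, z_def, _ = matched_permutation_z(
            candidates, members, pools, n_perms=args.n_perms, rng_seed=args.seed
        )
        res.z_matched = z if z_def else None
        res.z_defined = z_def
        res.n_perms = args.n_perms
        res.seed = args.seed
        out[name] = res.to_dict()
        or_text = f"{res.odds_ratio:.2f}" if res.odds_ratio_defined else "undefined"
        z_text = f"{z:.2f}" if z_def else "undefined"
        print(
            f"{name}: {res.table[0][0]}/{len(candidates)} candidates in category; "
            f"OR = {or_text}, Fisher P = {res.p_fisher:.3g}, matched z = {z_text}"
        )
    (ROOT / "results" / "enrichment.json").write_text(json.dumps(out, indent=2))
    print("wrote results/enrichment.json")


if __name__ == "__main__":
    main()
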