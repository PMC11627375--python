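#!/usr/bin/env python
"""Call candidate multi-cancer genes and lncRNAs from all evidence channels.

Combines exonic/promoter/splicing evidence, intronic regulatory variants
and within-TAD distal links; emits genes with qualifying evidence from at
least two cancers, and scores recovery against the planted truth table.
Writes results/candidates.tsv and results/lncrnas.tsv.
"""

import argparse
import csv
from pathlib import Path

from pleiogene.chromatin_linking import DistalLink
from pleiogene.genome_core import read_bed, read_chrom_sizes, read_genes_gff3, read_variants
from pleiogene.integration_enrichment import call_candidate_genes, call_candidate_lncrnas
from pleiogene.pipeline import write_candidates_tsv
from pleiogene.region_builder import MHDCRRegion
from pleiogene.synthetic_data import PlantedGene, evaluate_recovery
from pleiogene.variant_annotation import read_scores

ROOT = Path(__file__).resolve().parents[1]


def read_links(path):
    links = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            links.append(
                DistalLink(
                    variant_id=row["variant_id"],
                    gene_id=row["gene_id"],
                    cell_lines=frozenset(row["cell_lines"].split(",")),
                    within_tad=row["within_tad"] == "1",
                    cancer=row["cancer"],
                )
            )
    return links


def read_gene_list(path):
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--simdir", type=Path, default=ROOT / "results" / "sim")
    args = parser.parse_args()

    assembly = read_chrom_sizes(args.simdir / "chrom.sizes")
    variants = read_variants(args.simdir / "variants.tsv", assembly)
    genes = read_genes_gff3(args.simdir / "genes.gff3")
    records = read_scores(args.simdir / "scores.tsv")
    regions = [
        MHDCRRegion(int(name), iv, frozenset({"_a", "_b"}))
        for iv, name in read_bed(ROOT / "results" / "regions.bed")
    ]
    links = read_links(ROOT / "results" / "links.tsv")
    category_lists = {
        "cosmic": read_gene_list(args.simdir / "cosmic_genes.txt"),
        "drug_target": read_gene_list(args.simdir / "drug_target_genes.txt"),
    }

    candidates = call_candidate_genes(
        regions, variants, records, links, genes, category_lists=category_lists
    )
    coding_only = call_candidate_genes(
        regions, variants, records, links, genes, coding_only=True
    )
    lncrnas = call_candidate_lncrnas(
        regions, variants, records, links, genes, category_lists=category_lists
    )
    write_candidates_tsv(ROOT / "results" / "candidates.tsv", candidates)
    write_candidates_tsv(ROOT / "results" / "lncrnas.tsv", lncrnas)

    print(f"{len(coding_only)} candidates from coding/promoter/splicing evidence alone")
    print(f"{len(candidates)} candidates with regulatory and distal channels added")
    print(f"{len(lncrnas)} candidate lncRNAs")

    truth_path = args.simdir / "truth.tsv"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = [
                PlantedGene(row["gene_id"], tuple(row["cancers"].split(",")), ())
                for row in csv.DictReader(fh, delimiter="\t")
            ]
        rec = evaluate_recovery({c.gene_id for c in candidates}, truth)
        print(
            f"planted-truth recovery: {rec['n_recovered']}/{rec['n_true']} "
            f"(precision {rec['precision']:.2f}, recall {rec['recall']:.2f})"
        )
    print("wrote results/candidates.tsv, results/lncrnas.tsv")


if __name__ == "__main__":
    main()
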