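# pleiogene

Mapping **pleiotropic cancer risk genes** shared by the four hormone-dependent
cancers (HDCs: breast, endometrial, ovarian and prostate). GWAS have mapped
hundreds of risk loci for each of these cancers separately; loci for different
HDCs often sit close together on the genome, suggesting shared regulatory
elements and common target genes. `pleiogene` implements the computational
pipeline for finding them, end to end, over standard text formats — plus a
seedable synthetic-data generator so every stage is testable without any
external downloads.

It is written for statistical geneticists and regulatory genomicists who want
to run, extend, or stress-test this kind of multi-trait integration:

1. **Clustering test** — are risk variants of different cancers co-located
   more than chance? Variants are clustered per chromosome by single linkage
   with a 100 kb maximum gap (`bedtools cluster -d` semantics). The statistic
   is the number of clusters containing ≥ 2 cancers,
   `T = #{clusters : |{cancers in cluster}| ≥ 2}`,
   compared against a chromosome-preserving null in which every variant is
   re-placed uniformly on its own chromosome;
   `p = #{T_null ≥ T_obs} / N_perm` (one-sided) and
   `z = (T_obs − mean(T_null)) / sd(T_null)`.
2. **Region construction** — each cancer's index variants are extended ±0.5 Mb
   and merged into cancer-specific risk regions; maximal segments covered by
   ≥ 2 cancers' regions become numbered multi-cancer risk regions, with
   per-region counts of independent GWAS signals.
3. **Variant annotation** — per-gene location classes (exon > promoter
   [TSS ± 2 kb] > intron, else intergenic) plus thresholded score filters on
   externally computed annotations: VEP coding classes
   (frameshift/missense/synonymous/5′UTR/3′UTR), SpliceAI Δ ≥ 0.2 or
   |MaxEntScan| > 0 for splice-altering intronic variants, and RegulomeDB
   probability > 0.55 for regulatory variants, with ChromHMM active-state
   support per biosample.
4. **PCHiC linking** — promoter capture Hi-C interactions (CHiCAGO score ≥ 5)
   connect intergenic regulatory variants to target gene promoters; links are
   prioritised when both restriction-fragment midpoints fall inside one TAD,
   and TAD/interaction concordance is tested by a circularised permutation
   that rotates each region's TADs by a random offset, wrapping past the
   region end (TAD sizes conserved exactly).
5. **Gene calling & enrichment** — a gene becomes a candidate when it has
   qualifying evidence from ≥ 2 cancers; candidates are tested for COSMIC
   Cancer Gene Census and drug-target enrichment with one-sided Fisher's
   exact tests and a region-matched resampling null (z-scaled).

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
world with 12 planted pleiotropic target genes and the four cancers' real
index-variant counts (196 / 17 / 60 / 258):

```bash
python analysis/01_simulate_inputs.py      # writes results/sim/
python analysis/02_cluster_test.py
python analysis/03_build_regions.py
python analysis/04_annotate_variants.py
python analysis/05_link_distal_variants.py
python analysis/06_call_candidate_genes.py
python analysis/07_enrichment.py
```

With the default seed (11) this prints, among other things:

```
74 multi-cancer clusters observed; null mean 37.3; z = 7.2, P < 0.0001 (10000 permutations)
136 multi-cancer regions
795/1004 interactions pass CHiCAGO >= 5
138 interactions within TADs inside regions; z = 2.7, P 0.0035
8 candidates from coding/promoter/splicing evidence alone
12 candidates with regulatory and distal channels added
planted-truth recovery: 12/12 (precision 1.00, recall 1.00)
drug_target: 4/12 candidates in category; OR = 5.94, Fisher P = 0.0219, matched z = 1.99
```

Reading: cross-cancer co-location is highly non-random (z = 7.2); the
extended risk intervals fuse into 136 regions shared by ≥ 2 cancers;
interactions respect TAD boundaries more than rotated TADs would predict
(P ≈ 0.004); and adding the regulatory/distal evidence channels grows the
candidate set from 8 to 12 genes, recovering all 12 planted targets with no
false positives. The candidate table (`results/candidates.tsv`) lists each
gene's per-cancer evidence categories, ChromHMM support and category flags.

The same stages are available as a CLI (`pleiogene simulate | cluster-test |
build-regions | annotate | link | tad-test | call-genes | enrich | run-all`)
driven by flags or a flat YAML config in which every threshold
(100 kb, 0.5 Mb, ±2 kb, 0.2, 0.55, 5, permutation counts) is overridable.

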