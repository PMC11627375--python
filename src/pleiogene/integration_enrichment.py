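"""Candidate multi-cancer gene calling and gene-category enrichment.

A gene becomes a candidate when it accumulates qualifying variant evidence
from at least two distinct cancers. Evidence categories per (gene, cancer):

* coding (frameshift / missense / synonymous / 5'UTR / 3'UTR) from exonic
  variants' VEP classes;
* ``promoter`` from variants in the TSS +/- 2 kb window;
* ``splicing`` from intronic variants passing the SpliceAI/MaxEntScan rule;
* ``intronic_regulatory`` from intronic variants passing the RegulomeDB rule;
* ``distal_reg_within_tad`` from intergenic regulatory variants linked to
  the gene's promoter by a within-TAD PCHiC interaction.

lncRNA calling applies identical rules with biotype lncRNA and the coding
channel collapsed to a single ``exon`` category. Presence/absence only — a
gene counts toward a cancer through any one qualifying variant.

Enrichment of candidates for a gene category (COSMIC census membership,
drug-target status) uses a one-sided Fisher's exact test against the
background of all genes at the multi-cancer regions, plus a matched
resampling null (per region, draw as many genes as the region contributed
candidates) for a z-scaled effect display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .genome_core import GeneModel, Variant
from .region_builder import MHDCRRegion
from .chromatin_linking import DistalLink
from .variant_annotation import (
    AnnotationRecord,
    GeneIndex,
    chromhmm_support,
    classify_location,
    coding_evidence,
    is_regulatory,
    is_splice_altering,
)

__all__ = [
    "CandidateGene",
    "EnrichmentResult",
    "call_candidate_genes",
    "call_candidate_lncrnas",
    "fisher_enrichment",
    "matched_permutation_z",
    "label_permutation_z",
    "genes_at_regions",
]

CODING_ONLY_CATEGORIES = frozenset(
    {"frameshift", "missense", "synonymous", "utr5", "utr3", "exon", "promoter", "splicing"}
)


@dataclass
class CandidateGene:
    """A gene with qualifying evidence from >= 2 cancers, plus annotations."""

    gene_id: str
    name: str
    biotype: str
    region_ids: tuple[int, ...]
    evidence: dict[str, set[str]]  # cancer -> categories
    audit: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    # (cancer, category) -> supporting variant ids
    chromhmm_support: bool = False
    cosmic: bool = False
    drug_target: bool = False

    def __post_init__(self) -> None:
        cancers = {c for c, cats in self.evidence.items() if cats}
        if len(cancers) < 2:
            raise ValueError(f"{self.gene_id}: evidence from < 2 cancers")


def genes_at_regions(
    genes: Sequence[GeneModel], regions: Sequence[MHDCRRegion]
) -> dict[str, tuple[int, ...]]:
    """gene_id -> region ids whose interval the gene footprint overlaps."""
    out: dict[str, tuple[int, ...]] = {}
    for g in genes:
        span = g.span
        prom = g.promoter
        hits = tuple(
            r.region_id
            for r in regions
            if r.interval.overlaps(span) or r.interval.overlaps(prom)
        )
        if hits:
            out[g.gene_id] = hits
    return out


def _variants_in_regions(
    variants: Sequence[Variant], regions: Sequence[MHDCRRegion]
) -> list[Variant]:
    return [
        v
        for v in variants
        if any(r.interval.contains(v.chrom, v.pos) for r in regions)
    ]


def _call(
    regions: Sequence[MHDCRRegion],
    variants: Sequence[Variant],
    annotations: Mapping[str, AnnotationRecord],
    distal_links: Sequence[DistalLink],
    genes: Sequence[GeneModel],
    biotype_filter: str,
    exon_category_from_vep: bool,
    channels: frozenset | None,
    category_lists: Mapping[str, set] | None,
    relevant_biosamples: Mapping[str, set] | None,
    min_cancers: int = 2,
) -> list[CandidateGene]:
    selected = [g for g in genes if g.biotype == biotype_filter]
    gene_region = genes_at_regions(selected, regions)
    index = GeneIndex(selected)
    by_id = {g.gene_id: g for g in selected}
    in_regions = _variants_in_regions(variants, regions)
    variant_by_id = {v.id: v for v in variants}

    # (gene, cancer) -> category -> variant ids
    evidence: dict[str, dict[str, dict[str, set[str]]]] = {}
    support_variants: dict[str, set[str]] = {}

    def add(gid: str, cancer: str, category: str, vid: str) -> None:
        if channels is not None and category not in channels:
            return
        if gid not in gene_region:
            return
        evidence.setdefault(gid, {}).setdefault(cancer, {}).setdefault(category, set()).add(vid)
        support_variants.setdefault(gid, set()).add(vid)

    for v in in_regions:
        rec = annotations.get(v.id)
        if rec is None:
            continue
        loc = rec.location_class or classify_location(v, index)
        for gid, cls in loc.items():
            if gid not in by_id:
                continue
            if cls == "exonic":
                if exon_category_from_vep:
                    cat = coding_evidence(rec)
                    if cat is not None:
                        add(gid, v.cancer, cat, v.id)
                else:
                    add(gid, v.cancer, "exon", v.id)
            elif cls == "promoter":
                add(gid, v.cancer, "promoter", v.id)
            elif cls == "intronic":
                if is_splice_altering(rec):
                    add(gid, v.cancer, "splicing", v.id)
                if is_regulatory(rec):
                    add(gid, v.cancer, "intronic_regulatory", v.id)

    for link in distal_links:
        if not link.within_tad:
            continue
        if link.gene_id not in by_id:
            if link.gene_id not in {g.gene_id for g in genes}:
                raise ValueError(f"distal link to unknown gene {link.gene_id}")
            continue
        v = variant_by_id.get(link.variant_id)
        cancer = link.cancer or (v.cancer if v else "")
        if v is not None and not any(
            r.interval.contains(v.chrom, v.pos) for r in regions
        ):
            continue
        add(link.gene_id, cancer, "distal_reg_within_tad", link.variant_id)

    candidates = []
    for gid, per_cancer in evidence.items():
        cancers_with = {c for c, cats in per_cancer.items() if cats}
        if len(cancers_with) < min_cancers:
            continue
        g = by_id[gid]
        hmm = any(
            chromhmm_support(
                annotations[vid],
                None
                if relevant_biosamples is None
                else set().union(
                    *(relevant_biosamples.get(c, set()) for c in cancers_with)
                ),
            )
            for vid in support_variants.get(gid, ())
            if vid in annotations
        )
        cats = category_lists or {}
        candidates.append(
            CandidateGene(
                gene_id=gid,
                name=g.name,
                biotype=g.biotype,
                region_ids=gene_region[gid],
                evidence={c: set(catmap) for c, catmap in per_cancer.items()},
                audit={
                    (c, cat): set(vids)
                    for c, catmap in per_cancer.items()
                    for cat, vids in catmap.items()
                },
                chromhmm_support=hmm,
                cosmic=gid in cats.get("cosmic", set()),
                drug_target=gid in cats.get("drug_target", set()),
            )
        )
    candidates.sort(key=lambda c: (c.region_ids, c.gene_id))
    return candidates


def call_candidate_genes(
    regions: Sequence[MHDCRRegion],
    variants: Sequence[Variant],
    annotations: Mapping[str, AnnotationRecord],
    distal_links: Sequence[DistalLink],
    genes: Sequence[GeneModel],
    biotype_filter: str = "protein_coding",
    coding_only: bool = False,
    category_lists: Mapping[str, set] | None = None,
    relevant_biosamples: Mapping[str, set] | None = None,
) -> list[CandidateGene]:
    """Call candidate multi-cancer genes from all evidence channels.

    ``coding_only=True`` restricts to the exonic/promoter/splicing channels
    (the initial-call mode, a strict subset of the full call).
    """
    return _call(
        regions,
        variants,
        annotations,
        distal_links,
        genes,
        biotype_filter=biotype_filter,
        exon_category_from_vep=True,
        channels=CODING_ONLY_CATEGORIES if coding_only else None,
        category_lists=category_lists,
        relevant_biosamples=relevant_biosamples,
    )


def call_candidate_lncrnas(
    regions: Sequence[MHDCRRegion],
    variants: Sequence[Variant],
    annotations: Mapping[str, AnnotationRecord],
    distal_links: Sequence[DistalLink],
    genes: Sequence[GeneModel],
    category_lists: Mapping[str, set] | None = None,
    relevant_biosamples: Mapping[str, set] | None = None,
) -> list[CandidateGene]:
    """lncRNA candidates: exon / promoter / intronic_regulatory / distal."""
    return _call(
        regions,
        variants,
        annotations,
        distal_links,
        genes,
        biotype_filter="lncRNA",
        exon_category_from_vep=False,
        channels=None,
        category_lists=category_lists,
        relevant_biosamples=relevant_biosamples,
    )


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    odds_ratio_defined: bool
    conditional_odds_ratio: float
    p_fisher: float
    z_matched: float | None = None
    z_defined: bool | None = None
    n_perms: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "table": [list(self.table[0]), list(self.table[1])],
            "odds_ratio": self.odds_ratio if self.odds_ratio_defined else None,
            "odds_ratio_defined": self.odds_ratio_defined,
            "conditional_odds_ratio": self.conditional_odds_ratio,
            "p_fisher": self.p_fisher,
            "z_matched": self.z_matched,
            "z_defined": self.z_defined,
            "n_perms": self.n_perms,
            "seed": self.seed,
        }


def fisher_enrichment(
    candidates: set[str],
    category_members: set[str],
    background: set[str],
) -> EnrichmentResult:
    """One-sided (greater) Fisher's exact test for category enrichment.

    The 2x2 table is [[candidate&cat, candidate-not-cat],
    [rest&cat, rest-not-cat]] over ``background`` (all genes at the
    multi-cancer regions). The sample odds ratio (a*d)/(b*c) is reported
    (NaN with flag when b*c == 0); the conditional-MLE odds ratio is also
    computed.
    """
    if not background:
        raise ValueError("background gene set is empty")
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    rest = background - candidates
    a = len(candidates & category_members)
    b = len(candidates - category_members)
    c = len(rest & category_members)
    d = len(rest - category_members)
    table = ((a, b), (c, d))
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])
    if b * c == 0:
        sample_or, defined = float("nan"), False
    else:
        sample_or, defined = (a * d) / (b * c), True
    cond = float(stats.contingency.odds_ratio([[a, b], [c, d]]).statistic)
    return EnrichmentResult(
        table=table,
        odds_ratio=sample_or,
        odds_ratio_defined=defined,
        conditional_odds_ratio=cond,
        p_fisher=p,
    )


def matched_permutation_z(
    candidates: Sequence[CandidateGene],
    category_members: set[str],
    region_gene_pools: Mapping[int, Sequence[str]],
    n_perms: int = 10_000,
    rng_seed: int = 0,
) -> tuple[float, bool, np.ndarray]:
    """Matched resampling null for category overlap, z-scaled.

    Per iteration, from each region's gene pool draw (without replacement)
    as many genes as the region contributed candidates, and count draws in
    the category. Candidates spanning several regions are attributed to
    their first region id. Returns (z, z_defined, null_counts).
    """
    rng = np.random.default_rng(rng_seed)
    per_region: dict[int, int] = {}
    for cand in candidates:
        rid = cand.region_ids[0]
        per_region[rid] = per_region.get(rid, 0) + 1
    pools = {}
    for rid, k in per_region.items():
        pool = list(region_gene_pools.get(rid, ()))
        if len(pool) < k:
            raise ValueError(
                f"region {rid}: pool of {len(pool)} genes < {k} candidates"
            )
        pools[rid] = (np.array(pool, dtype=object), k)
    observed = sum(1 for c in candidates if c.gene_id in category_members)
    null = np.zeros(n_perms, dtype=np.int64)
    for i in range(n_perms):
        total = 0
        for pool, k in pools.values():
            draw = rng.choice(pool, size=k, replace=False)
            total += sum(1 for g in draw if g in category_members)
        null[i] = total
    sd = float(null.std())
    if sd == 0.0:
        return float("nan"), False, null
    return float((observed - null.mean()) / sd), True, null


def label_permutation_z(
    candidates: Sequence[CandidateGene],
    category_members: set[str],
    background: set[str],
    n_perms: int = 10_000,
    rng_seed: int = 0,
) -> tuple[float, bool, np.ndarray]:
    """Alternative null: permute category labels over the background genes
    and recount labelled candidates."""
    rng = np.random.default_rng(rng_seed)
    bg = np.array(sorted(background), dtype=object)
    n_labels = len(category_members & background)
    cand_ids = {c.gene_id for c in candidates}
    observed = len(cand_ids & category_members)
    null = np.zeros(n_perms, dtype=np.int64)
    for i in range(n_perms):
        labelled = rng.choice(bg, size=n_labels, replace=False)
        null[i] = sum(1 for g in labelled if g in cand_ids)
    sd = float(null.std())
    if sd == 0.0:
        return float("nan"), False, null
    return float((observed - null.mean()) / sd), True, null
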