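"""Candidate calling rules on constructed fixtures; Fisher test against an
exact hypergeometric-sum oracle; matched resampling null properties."""

import math

import numpy as np
import pytest
from scipy import stats

from pleiogene.chromatin_linking import DistalLink
from pleiogene.genome_core import GenomicInterval
from pleiogene.integration_enrichment import (
    CandidateGene,
    call_candidate_genes,
    call_candidate_lncrnas,
    fisher_enrichment,
    genes_at_regions,
    label_permutation_z,
    matched_permutation_z,
)
from pleiogene.region_builder import MHDCRRegion
from pleiogene.variant_annotation import AnnotationRecord
from .conftest import make_gene, make_variant


def ann(vid, **kwargs):
    return AnnotationRecord(variant_id=vid, **kwargs)


@pytest.fixture
def calling_fixture():
    """One region; gene G with a breast promoter variant and a prostate
    distal within-TAD link; gene H with breast-only evidence."""
    region = MHDCRRegion(
        1, GenomicInterval("chr1", 0, 60_000), frozenset({"breast", "prostate"})
    )
    g = make_gene("G", exon_coords=((10_000, 10_500), (14_000, 14_600)))
    h = make_gene("H", exon_coords=((30_000, 30_400), (33_000, 33_500)))
    variants = [
        make_variant("rsProm", pos=9_000, cancer="breast"),       # promoter of G
        make_variant("rsDist", pos=50_000, cancer="prostate"),    # intergenic
        make_variant("rsHexon", pos=30_100, cancer="breast"),     # exon of H
    ]
    annotations = {
        "rsProm": ann("rsProm", chromhmm_states={"breast_epithelium": "TssA"}),
        "rsDist": ann("rsDist", regulome_probability=0.9),
        "rsHexon": ann("rsHexon", vep_class="missense"),
    }
    links = [
        DistalLink("rsDist", "G", frozenset({"LNCAP"}), within_tad=True, cancer="prostate")
    ]
    return [region], variants, annotations, links, [g, h]


def test_candidate_called_from_two_cancers(calling_fixture):
    regions, variants, annotations, links, genes = calling_fixture
    candidates = call_candidate_genes(regions, variants, annotations, links, genes)
    assert [c.gene_id for c in candidates] == ["G"]
    cand = candidates[0]
    assert cand.evidence == {
        "breast": {"promoter"},
        "prostate": {"distal_reg_within_tad"},
    }
    assert cand.audit[("breast", "promoter")] == {"rsProm"}
    assert cand.audit[("prostate", "distal_reg_within_tad")] == {"rsDist"}
    assert cand.chromhmm_support  # promoter variant carries a TssA state
    assert cand.region_ids == (1,)


def test_single_cancer_gene_not_emitted(calling_fixture):
    regions, variants, annotations, links, genes = calling_fixture
    candidates = call_candidate_genes(regions, variants, annotations, [], genes)
    # without the distal link, G has breast-only evidence; H breast-only too
    assert candidates == []


def test_coding_only_mode_is_subset(calling_fixture):
    regions, variants, annotations, links, genes = calling_fixture
    full = {c.gene_id for c in call_candidate_genes(regions, variants, annotations, links, genes)}
    coding = {
        c.gene_id
        for c in call_candidate_genes(
            regions, variants, annotations, links, genes, coding_only=True
        )
    }
    assert coding <= full
    assert "G" not in coding  # the prostate evidence is distal-only


def test_distal_link_without_tad_gives_no_evidence(calling_fixture):
    regions, variants, annotations, _links, genes = calling_fixture
    outside = [
        DistalLink("rsDist", "G", frozenset({"LNCAP"}), within_tad=False, cancer="prostate")
    ]
    assert call_candidate_genes(regions, variants, annotations, outside, genes) == []


def test_link_to_unknown_gene_raises(calling_fixture):
    regions, variants, annotations, _links, genes = calling_fixture
    bad = [DistalLink("rsDist", "NOPE", frozenset(), within_tad=True, cancer="prostate")]
    with pytest.raises(ValueError, match="NOPE"):
        call_candidate_genes(regions, variants, annotations, bad, genes)


def test_lncrna_calling_uses_exon_category():
    region = MHDCRRegion(
        1, GenomicInterval("chr1", 0, 40_000), frozenset({"ovarian", "prostate"})
    )
    lnc = make_gene("L", biotype="lncRNA", exon_coords=((10_000, 11_000), (14_000, 15_000)))
    variants = [
        make_variant("rsE", pos=10_200, cancer="ovarian"),
        make_variant("rsP", pos=8_500, cancer="prostate"),
    ]
    annotations = {"rsE": ann("rsE"), "rsP": ann("rsP")}
    out = call_candidate_lncrnas([region], variants, annotations, [], [lnc])
    assert len(out) == 1
    assert out[0].evidence == {"ovarian": {"exon"}, "prostate": {"promoter"}}
    # non-qualifying evidence (intronic without scores) emits nothing
    dull = [
        make_variant("rsI1", pos=12_500, cancer="ovarian"),
        make_variant("rsI2", pos=12_600, cancer="prostate"),
    ]
    dull_ann = {v.id: ann(v.id) for v in dull}
    assert call_candidate_lncrnas([region], dull, dull_ann, [], [lnc]) == []


def test_candidate_requires_two_cancers_invariant():
    with pytest.raises(ValueError):
        CandidateGene(
            gene_id="G",
            name="G",
            biotype="protein_coding",
            region_ids=(1,),
            evidence={"breast": {"promoter"}},
        )


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) by explicit hypergeometric summation."""
    n_cat = a + c
    n_cand = a + b
    total = a + b + c + d
    return sum(
        math.comb(n_cat, k) * math.comb(total - n_cat, n_cand - k) / math.comb(total, n_cand)
        for k in range(a, min(n_cat, n_cand) + 1)
    )


def test_fisher_worked_example():
    candidates = {f"c{i}" for i in range(10)}
    rest = {f"r{i}" for i in range(90)}
    category = {f"c{i}" for i in range(4)} | {f"r{i}" for i in range(10)}
    res = fisher_enrichment(candidates, category, candidates | rest)
    assert res.table == ((4, 6), (10, 80))
    assert res.odds_ratio == pytest.approx(16 / 3)
    assert res.p_fisher == pytest.approx(hypergeom_tail_oracle(4, 6, 10, 80))


def test_fisher_matches_oracle_on_small_margins(rng):
    for _ in range(30):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        if a + b == 0 or c + d == 0:
            continue
        candidates = {f"c{i}" for i in range(a + b)}
        rest = {f"r{i}" for i in range(c + d)}
        category = {f"c{i}" for i in range(a)} | {f"r{i}" for i in range(c)}
        res = fisher_enrichment(candidates, category, candidates | rest)
        assert res.p_fisher == pytest.approx(hypergeom_tail_oracle(a, b, c, d), rel=1e-9)


def test_fisher_disjoint_category():
    res = fisher_enrichment({"a"}, {"zzz"}, {"a", "b", "c"})
    assert not res.odds_ratio_defined
    assert res.p_fisher == 1.0


def test_fisher_empty_background_raises():
    with pytest.raises(ValueError):
        fisher_enrichment(set(), {"x"}, set())


# ---------------------------------------------------------------------------
# Matched resampling null
# ---------------------------------------------------------------------------

def cands(n, region_id=1, category_prefix="g"):
    return [
        CandidateGene(
            gene_id=f"{category_prefix}{i}",
            name=f"{category_prefix}{i}",
            biotype="protein_coding",
            region_ids=(region_id,),
            evidence={"breast": {"promoter"}, "ovarian": {"exon"}},
        )
        for i in range(n)
    ]


def test_matched_z_degenerate_category_everywhere():
    pool = [f"g{i}" for i in range(5)]
    z, defined, null = matched_permutation_z(
        cands(2), set(pool), {1: pool}, n_perms=100, rng_seed=0
    )
    assert not defined
    assert set(null) == {2}


def test_matched_z_empty_category():
    pool = [f"g{i}" for i in range(5)]
    z, defined, null = matched_permutation_z(
        cands(2), set(), {1: pool}, n_perms=50, rng_seed=0
    )
    assert not defined
    assert set(null) == {0}


def test_matched_z_pool_too_small():
    with pytest.raises(ValueError, match="region 1"):
        matched_permutation_z(cands(3), set(), {1: ["g0"]}, n_perms=10, rng_seed=0)


def test_matched_null_mean_matches_hypergeometric_expectation():
    """Sampling k of n genes with m in-category: E[hits] = k*m/n."""
    pool = [f"g{i}" for i in range(20)]
    category = set(pool[:6])
    candidates = cands(5)
    _z, defined, null = matched_permutation_z(
        candidates, category, {1: pool}, n_perms=10_000, rng_seed=1
    )
    expectation = 5 * 6 / 20
    se = null.std() / np.sqrt(len(null))
    assert abs(null.mean() - expectation) < 3 * se + 1e-9


def test_matched_z_detects_planted_enrichment():
    """Five regions whose candidates are all in-category against pools that
    are mostly out-of-category."""
    candidates = []
    pools = {}
    category = set()
    for rid in range(1, 6):
        gid = f"hit{rid}"
        category.add(gid)
        candidates.append(
            CandidateGene(
                gene_id=gid,
                name=gid,
                biotype="protein_coding",
                region_ids=(rid,),
                evidence={"breast": {"promoter"}, "prostate": {"missense"}},
            )
        )
        pools[rid] = [gid] + [f"bg{rid}_{i}" for i in range(9)]
    z, defined, _ = matched_permutation_z(candidates, category, pools, n_perms=5_000, rng_seed=2)
    assert defined
    assert z > 2


def test_label_permutation_mode():
    candidates = cands(5)
    background = {f"g{i}" for i in range(5)} | {f"bg{i}" for i in range(45)}
    category = {f"g{i}" for i in range(4)} | {"bg0"}
    z, defined, _ = label_permutation_z(candidates, category, background, n_perms=2_000, rng_seed=3)
    assert defined
    assert z > 2


def test_genes_at_regions_overlap():
    regions = [
        MHDCRRegion(1, GenomicInterval("chr1", 0, 20_000), frozenset({"A", "B"})),
        MHDCRRegion(2, GenomicInterval("chr1", 40_000, 60_000), frozenset({"A", "B"})),
    ]
    inside = make_gene("IN", exon_coords=((10_000, 10_500), (12_000, 12_400)))
    outside = make_gene("OUT", exon_coords=((25_000, 25_500), (27_000, 27_400)))
    spanning = make_gene("SPAN", exon_coords=((15_000, 15_500), (45_000, 45_400)))
    got = genes_at_regions([inside, outside, spanning], regions)
    assert got == {"IN": (1,), "SPAN": (1, 2)}
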