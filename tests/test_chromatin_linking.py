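"""Interaction filtering, replicate concordance vs a definitional oracle,
distal assignment on hand-built fixtures, and the TAD permutation test."""

import numpy as np
import pytest
from scipy import stats

from pleiogene.chromatin_linking import (
    CHICAGO_THRESHOLD,
    ConcordanceResult,
    Fragment,
    FragmentMap,
    Interaction,
    TAD,
    assign_distal,
    filter_interactions,
    replicate_concordance,
    tad_enrichment,
    within_tad_count,
)
from pleiogene.genome_core import GenomicInterval
from pleiogene.region_builder import MHDCRRegion
from pleiogene.variant_annotation import AnnotationRecord
from .conftest import make_gene, make_variant


def tile_fragments(chrom="chr1", size=2_000, n=250) -> FragmentMap:
    return FragmentMap(
        [
            Fragment(i, GenomicInterval(chrom, i * size, (i + 1) * size))
            for i in range(n)
        ]
    )


def interaction(bait, other, score=6.0, cell_line="MCF7", **kw):
    return Interaction(bait=bait, other_end=other, cell_line=cell_line, score=score, **kw)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def test_score_threshold_boundary():
    xs = [interaction(0, 1, 5.0), interaction(0, 2, 4.99), interaction(0, 3, 12.0)]
    kept = filter_interactions(xs)
    assert [x.score for x in kept] == [5.0, 12.0]
    assert filter_interactions(kept) == kept  # idempotent
    assert filter_interactions([]) == []


def test_self_interaction_rejected():
    with pytest.raises(ValueError):
        interaction(3, 3)


# ---------------------------------------------------------------------------
# Replicate concordance
# ---------------------------------------------------------------------------

def test_concordance_perfect_and_reversed():
    keys = [(0, i) for i in range(1, 11)]
    counts = {k: i for i, k in enumerate(keys, 1)}
    assert replicate_concordance(counts, counts).rho == pytest.approx(1.0)
    reversed_counts = {k: 11 - v for k, v in counts.items()}
    assert replicate_concordance(counts, reversed_counts).rho == pytest.approx(-1.0)


def test_concordance_undefined_with_few_shared_keys():
    res = replicate_concordance({(0, 1): 5, (0, 2): 3}, {(0, 3): 2})
    assert not res.defined
    assert np.isnan(res.rho)


def test_concordance_matches_rank_then_pearson_oracle(rng):
    keys = [(0, i) for i in range(1, 51)]
    rep1 = {k: int(rng.integers(0, 100)) for k in keys}
    rep2 = {k: int(rng.integers(0, 100)) for k in keys[:40]}  # partial overlap
    res = replicate_concordance(rep1, rep2)
    union = sorted(set(rep1) | set(rep2))
    x = stats.rankdata([rep1.get(k, 0) for k in union])
    y = stats.rankdata([rep2.get(k, 0) for k in union])
    oracle = np.corrcoef(x, y)[0, 1]
    assert res.rho == pytest.approx(oracle)


# ---------------------------------------------------------------------------
# Distal assignment
# ---------------------------------------------------------------------------

@pytest.fixture
def distal_fixture():
    fragmap = tile_fragments()
    # gene G with TSS at 5_000 (fragment 2 holds the promoter centre)
    gene = make_gene("G", exon_coords=((5_000, 5_400), (8_000, 8_500)))
    variant = make_variant("rsX", pos=15_100, cancer="ovarian")  # fragment 7
    annotations = {
        "rsX": AnnotationRecord(variant_id="rsX", regulome_probability=0.9)
    }
    interactions = [
        interaction(2, 7, 6.0, "MCF7"),
        interaction(2, 7, 8.0, "LNCAP"),
    ]
    tads = [TAD(GenomicInterval("chr1", 0, 500_000))]
    return fragmap, gene, variant, annotations, interactions, tads


def test_distal_link_found(distal_fixture):
    fragmap, gene, variant, annotations, interactions, tads = distal_fixture
    links = assign_distal([variant], fragmap, interactions, [gene], annotations, tads)
    assert len(links) == 1
    link = links[0]
    assert (link.variant_id, link.gene_id) == ("rsX", "G")
    assert link.cell_lines == frozenset({"MCF7", "LNCAP"})
    assert link.within_tad
    assert link.cancer == "ovarian"
    # exhaustive check: no other fragment pair produces a link
    all_pairs = {
        (x.bait, x.other_end) for x in interactions
    }
    assert all_pairs == {(2, 7)}


def test_distal_requires_regulatory_score(distal_fixture):
    fragmap, gene, variant, annotations, interactions, tads = distal_fixture
    annotations["rsX"].regulome_probability = 0.40
    assert (
        assign_distal([variant], fragmap, interactions, [gene], annotations, tads)
        == []
    )


def test_distal_outside_tads_flagged(distal_fixture):
    fragmap, gene, variant, annotations, interactions, _ = distal_fixture
    tads = [TAD(GenomicInterval("chr1", 300_000, 400_000))]  # elsewhere
    links = assign_distal([variant], fragmap, interactions, [gene], annotations, tads)
    assert len(links) == 1
    assert not links[0].within_tad


def test_distal_skips_non_intergenic(distal_fixture):
    fragmap, gene, _variant, annotations, _interactions, tads = distal_fixture
    # an intronic variant (fragment 3) looping to the promoter fragment
    intronic = make_variant("rsX", pos=7_500, cancer="ovarian")
    loop = [interaction(2, 3, 6.0)]
    # does not qualify in default (intergenic-only) mode
    assert assign_distal([intronic], fragmap, loop, [gene], annotations, tads) == []
    # but does in intronic-distal mode
    links = assign_distal(
        [intronic],
        fragmap,
        loop,
        [gene],
        annotations,
        tads,
        distal_classes=("intergenic", "intronic"),
    )
    assert len(links) == 1


def test_distal_order_invariant(distal_fixture):
    fragmap, gene, variant, annotations, interactions, tads = distal_fixture
    fwd = assign_distal([variant], fragmap, interactions, [gene], annotations, tads)
    rev = assign_distal(
        [variant], fragmap, interactions[::-1], [gene], annotations, tads
    )
    assert fwd == rev


# ---------------------------------------------------------------------------
# Within-TAD counting and the permutation test
# ---------------------------------------------------------------------------

def brute_force_within(interactions, fragmap, tads):
    n = 0
    for x in interactions:
        b, o = fragmap.by_id[x.bait], fragmap.by_id[x.other_end]
        for t in tads:
            if (
                t.interval.contains(b.interval.chrom, b.midpoint)
                and t.interval.contains(o.interval.chrom, o.midpoint)
            ):
                n += 1
                break
    return n


def test_within_tad_count_matches_pair_oracle(rng):
    fragmap = tile_fragments(n=500, size=1_000)
    tads = []
    pos = 0
    while pos < 500_000:
        end = pos + int(rng.integers(20_000, 80_000))
        tads.append(TAD(GenomicInterval("chr1", pos, min(end, 500_000))))
        pos = end + int(rng.integers(0, 10_000))
    xs = []
    for _ in range(400):
        b, o = rng.integers(0, 500, size=2)
        if b != o:
            xs.append(interaction(int(b), int(o)))
    assert within_tad_count(xs, fragmap, tads) == brute_force_within(xs, fragmap, tads)


def region(rid, start, end, chrom="chr1"):
    return MHDCRRegion(rid, GenomicInterval(chrom, start, end), frozenset({"A", "B"}))


def test_tad_test_degenerate_full_cover():
    """A TAD covering a whole region: every rotation reproduces it."""
    fragmap = tile_fragments(n=50, size=1_000)
    tads = [TAD(GenomicInterval("chr1", 0, 50_000))]
    xs = [interaction(0, 10), interaction(5, 20)]
    res = tad_enrichment(xs, fragmap, tads, [region(1, 0, 50_000)], n_perms=50, rng_seed=1)
    assert res.observed == 2
    assert res.p_empirical == 1.0
    assert not res.z_defined


def test_tad_test_no_tads():
    fragmap = tile_fragments(n=50, size=1_000)
    res = tad_enrichment(
        [interaction(0, 10)], fragmap, [], [region(1, 0, 50_000)], n_perms=20, rng_seed=1
    )
    assert res.observed == 0
    assert res.p_empirical == 1.0


def test_tad_larger_than_region_is_error():
    fragmap = tile_fragments(n=50, size=1_000)
    tads = [TAD(GenomicInterval("chr1", 0, 40_000))]
    with pytest.raises(ValueError, match="region 1"):
        tad_enrichment(
            [interaction(0, 10)], fragmap, tads, [region(1, 10_000, 30_000)],
            n_perms=10, rng_seed=1,
        )
    # permissive mode drops the TAD instead
    res = tad_enrichment(
        [interaction(0, 10)], fragmap, tads, [region(1, 10_000, 30_000)],
        n_perms=10, rng_seed=1, oversized="skip",
    )
    assert res.observed == 0


def test_tad_shift_conserves_tad_length():
    """Rotated TADs keep their size: the null count can never exceed the
    count attainable with TADs of the same lengths."""
    fragmap = tile_fragments(n=100, size=1_000)
    tads = [
        TAD(GenomicInterval("chr1", 10_000, 30_000)),
        TAD(GenomicInterval("chr1", 40_000, 55_000)),
    ]
    xs = [interaction(i, i + 2) for i in range(0, 90, 3)]
    res = tad_enrichment(
        xs, fragmap, tads, [region(1, 0, 100_000)], n_perms=200, rng_seed=3
    )
    assert res.null_values.max() <= len(xs)
    assert res.null_values.min() >= 0
    assert res.observed == brute_force_within(xs, fragmap, tads)


def test_tad_observed_matches_brute_force_within_regions(rng):
    fragmap = tile_fragments(n=400, size=1_000)
    tads = [
        TAD(GenomicInterval("chr1", 20_000, 90_000)),
        TAD(GenomicInterval("chr1", 90_000, 150_000)),
        TAD(GenomicInterval("chr1", 210_000, 280_000)),
    ]
    regions = [region(1, 0, 200_000), region(2, 200_000, 350_000)]
    xs = []
    for _ in range(200):
        b, o = rng.integers(0, 400, size=2)
        if b != o:
            xs.append(interaction(int(b), int(o)))
    res = tad_enrichment(xs, fragmap, tads, regions, n_perms=10, rng_seed=0)
    # restrict to interactions with both midpoints inside one region
    retained = [
        x
        for x in xs
        if any(
            r.interval.contains("chr1", fragmap.by_id[x.bait].midpoint)
            and r.interval.contains("chr1", fragmap.by_id[x.other_end].midpoint)
            for r in regions
        )
    ]
    assert res.observed == brute_force_within(retained, fragmap, tads)
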