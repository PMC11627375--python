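"""Coordinate plumbing: interval arithmetic against per-base oracles, file
round-trips, and input validation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleiogene.genome_core import (
    GenomeAssembly,
    GenomicInterval,
    ParseError,
    coverage_segments,
    merge_intervals,
    read_genes_gff3,
    read_genes_tsv,
    read_variants,
    write_genes_gff3,
    write_genes_tsv,
    write_variants,
)
from .conftest import make_gene, make_variant


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def covered_bp_oracle(intervals, chrom_len=10_000):
    """Per-base boolean occupancy, one chromosome at a time."""
    total = 0
    for chrom in {iv.chrom for iv in intervals}:
        mask = np.zeros(chrom_len, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start : iv.end] = True
        total += int(mask.sum())
    return total


def depth_segments_oracle(interval_sets, min_labels, chrom_len=10_000):
    """Per-base distinct-label depth; returns {(chrom, pos)} qualifying."""
    out = set()
    chroms = {iv.chrom for ivs in interval_sets.values() for iv in ivs}
    for chrom in chroms:
        depth = np.zeros(chrom_len, dtype=int)
        for ivs in interval_sets.values():
            mask = np.zeros(chrom_len, dtype=bool)
            for iv in ivs:
                if iv.chrom == chrom:
                    mask[iv.start : iv.end] = True
            depth += mask
        for pos in np.nonzero(depth >= min_labels)[0]:
            out.add((chrom, int(pos)))
    return out


def random_intervals(rng, n, chrom_len=10_000, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(chrom_len, start + 500) + 1))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, end))
    return out


# ---------------------------------------------------------------------------
# merge_intervals
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "raw,expected",
    [
        # overlapping
        ([("chr1", 100, 200), ("chr1", 150, 300)], [("chr1", 100, 300)]),
        # book-ended half-open intervals merge
        ([("chr1", 100, 200), ("chr1", 200, 300)], [("chr1", 100, 300)]),
        # different chromosomes never merge
        ([("chr1", 100, 200), ("chr2", 100, 200)], [("chr1", 100, 200), ("chr2", 100, 200)]),
        ([], []),
    ],
)
def test_merge_examples(raw, expected):
    got = merge_intervals([GenomicInterval(*t) for t in raw])
    assert [(iv.chrom, iv.start, iv.end) for iv in got] == expected


def test_merge_against_per_base_oracle(rng):
    for _ in range(5):
        ivs = random_intervals(rng, 1000)
        merged = merge_intervals(ivs)
        assert sum(len(iv) for iv in merged) == covered_bp_oracle(ivs)
        # disjoint, non-adjacent, sorted
        for a, b in zip(merged, merged[1:]):
            if a.chrom == b.chrom:
                assert a.end < b.start


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 100)).map(
            lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
        ),
        max_size=30,
    )
)
def test_merge_idempotent(ivs):
    once = merge_intervals(ivs)
    assert merge_intervals(once) == once


# ---------------------------------------------------------------------------
# coverage_segments
# ---------------------------------------------------------------------------

def test_coverage_two_label_intersection():
    sets = {
        "A": [GenomicInterval("chr1", 0, 700_000)],
        "B": [GenomicInterval("chr1", 600_000, 900_000)],
    }
    segs = coverage_segments(sets, 2)
    assert [(iv.chrom, iv.start, iv.end) for iv, _ in segs] == [("chr1", 600_000, 700_000)]
    assert segs[0][1] == frozenset({"A", "B"})


def test_coverage_single_label_below_min():
    assert coverage_segments({"A": [GenomicInterval("chr1", 0, 100)]}, 2) == []


def test_coverage_min_labels_validation():
    with pytest.raises(ValueError):
        coverage_segments({}, 0)


def test_coverage_against_depth_oracle(rng):
    for _ in range(10):
        sets = {
            label: merge_intervals(random_intervals(rng, 8, chroms=("chr1",)))
            for label in "ABC"
        }
        for min_labels in (2, 3):
            segs = coverage_segments(sets, min_labels)
            got = {
                (iv.chrom, pos)
                for iv, _ in segs
                for pos in range(iv.start, iv.end)
            }
            assert got == depth_segments_oracle(sets, min_labels)
            # segments disjoint and labels correct
            for iv, labels in segs:
                for label in labels:
                    assert any(x.overlaps(iv) for x in sets[label])


# ---------------------------------------------------------------------------
# Variant TSV I/O
# ---------------------------------------------------------------------------

def test_variant_round_trip(tmp_path, toy_assembly):
    variants = [
        make_variant("rs1", "chr1", 100, "breast", r2=0.95, is_index=False),
        make_variant("rs2", "chr2", 1_400_000, "prostate"),
        make_variant("rs3", "chr1", 0, "ovarian"),
    ]
    path = tmp_path / "v.tsv"
    write_variants(path, variants)
    assert read_variants(path, toy_assembly) == variants


def test_variant_position_at_chromosome_length_rejected(tmp_path, toy_assembly):
    path = tmp_path / "v.tsv"
    write_variants(path, [make_variant("rs1", "chr2", 1_500_000)])
    with pytest.raises(ParseError, match="outside chr2"):
        read_variants(path, toy_assembly)


def test_variant_unknown_chromosome_is_error(tmp_path, toy_assembly):
    path = tmp_path / "v.tsv"
    path.write_text("variant_id\tchrom\tpos\tcancer\nrs1\tchrX\t5\tbreast\n")
    with pytest.raises(ParseError, match="chrX"):
        read_variants(path, toy_assembly)


def test_variant_unknown_cancer_label_lists_allowed(tmp_path, toy_assembly):
    path = tmp_path / "v.tsv"
    path.write_text("variant_id\tchrom\tpos\tcancer\nrs1\tchr1\t5\tlung\n")
    with pytest.raises(ParseError, match="breast, endometrial, ovarian, prostate"):
        read_variants(path, toy_assembly)
    # arbitrary trait labels accepted on request
    got = read_variants(path, toy_assembly, allowed_cancers=None)
    assert got[0].cancer == "lung"


def test_malformed_position_names_line(tmp_path, toy_assembly):
    path = tmp_path / "v.tsv"
    path.write_text("variant_id\tchrom\tpos\tcancer\nrs1\tchr1\toops\tbreast\n")
    with pytest.raises(ParseError, match=":2"):
        read_variants(path, toy_assembly)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def test_tss_respects_strand():
    plus = make_gene(strand="+")
    minus = make_gene(strand="-")
    assert plus.tss == 10_000
    assert minus.tss == 15_799
    assert len(plus.promoter) == 2 * 2000 + 1


def test_gene_gff3_and_tsv_round_trip(tmp_path):
    genes = [
        make_gene("G1", strand="+"),
        make_gene("L1", strand="-", biotype="lncRNA", chrom="chr2"),
    ]
    gff = tmp_path / "g.gff3"
    tsv = tmp_path / "g.tsv"
    write_genes_gff3(gff, genes)
    write_genes_tsv(tsv, genes)
    assert read_genes_gff3(gff) == genes
    assert read_genes_tsv(tsv) == genes


def test_assembly_validation():
    with pytest.raises(ValueError):
        GenomeAssembly("bad", (("chr1", 10), ("chr1", 20)))
    with pytest.raises(ValueError):
        GenomeAssembly("bad", (("chr1", 0),))
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
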