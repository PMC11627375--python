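"""Construct multi-cancer risk regions from extended per-cancer intervals.

Each cancer's index variants are extended by ``flank`` bp on either side
(default 0.5 Mb), clamped to chromosome bounds and merged into
cancer-specific risk regions. Multi-cancer risk regions are the maximal
segments where at least ``min_cancers`` cancers' risk regions overlap;
contiguous qualifying segments are fused into one numbered region carrying
every overlapping cancer, and per-region independent-signal counts are
tallied from index variants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .genome_core import (
    GenomeAssembly,
    GenomicInterval,
    Variant,
    coverage_segments,
    merge_intervals,
)

__all__ = [
    "MHDCRRegion",
    "build_cancer_regions",
    "build_mhdcr_regions",
    "count_signals",
    "combination_summary",
]


@dataclass
class MHDCRRegion:
    """A maximal genomic segment covered by >= 2 cancers' risk regions."""

    region_id: int
    interval: GenomicInterval
    cancers: frozenset
    signal_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.cancers) < 2:
            raise ValueError(
                f"region {self.region_id}: needs >= 2 cancers, got {set(self.cancers)}"
            )


def build_cancer_regions(
    variants: list[Variant],
    assembly: GenomeAssembly,
    flank: int = 500_000,
    index_only: bool = True,
) -> dict[str, list[GenomicInterval]]:
    """Per cancer: extend each (index) variant by ``flank`` bp each side,
    clamp to ``[0, chrom length)`` and merge. A variant at position p yields
    ``[p - flank, p + flank + 1)`` so the window is symmetric around the
    variant base."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    lengths = assembly.lengths
    per_cancer: dict[str, list[GenomicInterval]] = {}
    for v in variants:
        if index_only and not v.is_index:
            continue
        length = lengths[v.chrom]
        start = max(0, v.pos - flank)
        end = min(length, v.pos + flank + 1)
        per_cancer.setdefault(v.cancer, []).append(GenomicInterval(v.chrom, start, end))
    return {cancer: merge_intervals(ivs) for cancer, ivs in sorted(per_cancer.items())}


def build_mhdcr_regions(
    per_cancer_intervals: dict[str, list[GenomicInterval]],
    min_cancers: int = 2,
) -> list[MHDCRRegion]:
    """Fuse >= ``min_cancers``-deep coverage segments into numbered regions.

    Region IDs run 1..N in (chromosome order, start) order, following the
    chromosome order implied by sorted chromosome names within the coverage
    sweep. The attached cancer set is every cancer whose risk region
    overlaps the fused segment, even if the contributing pair changes along
    it.
    """
    segments = coverage_segments(per_cancer_intervals, min_cancers)
    regions = []
    for i, (iv, labels) in enumerate(segments, 1):
        regions.append(MHDCRRegion(region_id=i, interval=iv, cancers=labels))
    return regions


def count_signals(
    regions: list[MHDCRRegion], variants: list[Variant]
) -> list[MHDCRRegion]:
    """Count distinct independent GWAS signals per (region, cancer).

    A signal counts toward a region when its index variant's position lies
    inside the region interval. Counts are recorded for every cancer with a
    qualifying index variant (normally a subset of the region's cancer set,
    but any cancer overlapping the region is admitted). Mutates and returns
    ``regions``.
    """
    for region in regions:
        signals: dict[str, set[str]] = {}
        for v in variants:
            if not v.is_index:
                continue
            if region.interval.contains(v.chrom, v.pos):
                signals.setdefault(v.cancer, set()).add(v.signal_id or v.id)
        region.signal_counts = {c: len(s) for c, s in sorted(signals.items())}
    return regions


def combination_summary(regions: list[MHDCRRegion]) -> dict:
    """Histogram of regions per cancer combination and per cardinality."""
    by_combo = Counter(region.cancers for region in regions)
    by_cardinality = Counter(len(region.cancers) for region in regions)
    return {
        "by_combination": dict(by_combo),
        "by_cardinality": dict(by_cardinality),
        "n_regions": len(regions),
    }
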