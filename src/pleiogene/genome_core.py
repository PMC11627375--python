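"""Genomic coordinate system, interval arithmetic and file readers/writers.

All coordinates are 0-based, half-open ``[start, end)`` — the BED convention —
everywhere in memory and in BED output. 1-based positions appear only in
human-readable messages. Book-ended intervals (``end == start`` of the next)
merge, matching ``bedtools merge`` defaults.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "HDC_CANCERS",
    "GenomeAssembly",
    "GenomicInterval",
    "Variant",
    "GeneModel",
    "read_chrom_sizes",
    "read_variants",
    "write_variants",
    "read_bed",
    "write_bed",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_genes_gff3",
    "write_genes_gff3",
    "merge_intervals",
    "coverage_segments",
]

#: The four hormone-dependent cancers studied; readers accept other trait
#: labels when given an explicit allowed set (or None for "any").
HDC_CANCERS = ("breast", "endometrial", "ovarian", "prostate")


class ParseError(ValueError):
    """A malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class GenomeAssembly:
    """A named set of chromosomes with lengths (UCSC chrom.sizes dialect)."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in assembly")
        for c, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {length}")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def __contains__(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self.chromosomes)

    def length_of(self, chrom: str) -> int:
        for c, length in self.chromosomes:
            if c == chrom:
                return length
        raise KeyError(chrom)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Variant:
    """A GWAS variant: one record per (rsID, trait) pair.

    ``pos`` is 0-based. ``signal_id`` identifies the independent GWAS signal
    the variant belongs to; ``is_index`` marks the lead variant of that
    signal, and ``r2`` is the LD with the index variant (None for the index
    itself). LD proxies retained for annotation carry r2 >= 0.8.
    """

    id: str
    chrom: str
    pos: int
    cancer: str
    signal_id: str = ""
    is_index: bool = True
    r2: float | None = None


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS, exons and a promoter window.

    The TSS is the 5'-most exon boundary respecting strand (gene start on
    '+', gene end on '-'); the promoter is TSS +/- ``promoter_flank``
    (default 2 kb), i.e. the half-open window ``[tss - flank, tss + flank + 1)``.
    """

    gene_id: str
    name: str
    biotype: str  # protein_coding | lncRNA | other
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    promoter_flank: int = 2000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
        if list(self.exons) != sorted(self.exons, key=lambda e: e.start):
            raise ValueError(f"gene {self.gene_id}: exons not sorted")

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end)

    @property
    def tss(self) -> int:
        # 5'-most transcribed base: first base on '+', last base on '-'
        if self.strand == "+":
            return self.exons[0].start
        return self.exons[-1].end - 1

    @property
    def promoter(self) -> GenomicInterval:
        start = max(0, self.tss - self.promoter_flank)
        return GenomicInterval(self.chrom, start, self.tss + self.promoter_flank + 1)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_chrom_sizes(path, name: str = "custom") -> GenomeAssembly:
    """Read a two-column (chrom, length) TSV into a :class:`GenomeAssembly`."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                chroms.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad length {fields[1]!r}") from exc
    return GenomeAssembly(name=name, chromosomes=tuple(chroms))


VARIANT_COLUMNS = ("variant_id", "chrom", "pos", "cancer", "signal_id", "is_index", "r2")


def read_variants(
    path,
    assembly: GenomeAssembly,
    allowed_cancers: Sequence[str] | None = HDC_CANCERS,
) -> list[Variant]:
    """Read a variant TSV (header ``variant_id chrom pos cancer ...``).

    Rows on chromosomes absent from ``assembly`` are an error, not silently
    dropped: silent loss would corrupt permutation counts downstream. Pass
    ``allowed_cancers=None`` to accept arbitrary trait labels.
    """
    variants: list[Variant] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"variant_id", "chrom", "pos", "cancer"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, 2):
            chrom = row["chrom"]
            if chrom not in assembly:
                raise ParseError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in assembly "
                    f"{assembly.name!r}"
                )
            try:
                pos = int(row["pos"])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad position {row['pos']!r}") from exc
            length = assembly.length_of(chrom)
            if not (0 <= pos < length):
                raise ParseError(
                    f"{path}:{lineno}: position {pos} outside {chrom} "
                    f"(0-based, length {length})"
                )
            cancer = row["cancer"]
            if allowed_cancers is not None and cancer not in allowed_cancers:
                raise ParseError(
                    f"{path}:{lineno}: unknown cancer label {cancer!r}; "
                    f"allowed: {', '.join(allowed_cancers)}"
                )
            r2_raw = (row.get("r2") or "").strip()
            r2 = float(r2_raw) if r2_raw not in ("", "NA", ".") else None
            is_index = (row.get("is_index") or "1").strip().lower() in ("1", "true", "yes")
            variants.append(
                Variant(
                    id=row["variant_id"],
                    chrom=chrom,
                    pos=pos,
                    cancer=cancer,
                    signal_id=row.get("signal_id", "") or "",
                    is_index=is_index,
                    r2=r2,
                )
            )
    return variants


def write_variants(path, variants: Iterable[Variant]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in variants:
            writer.writerow(
                [
                    v.id,
                    v.chrom,
                    v.pos,
                    v.cancer,
                    v.signal_id,
                    1 if v.is_index else 0,
                    "" if v.r2 is None else f"{v.r2:g}",
                ]
            )


def read_bed(path) -> list[tuple[GenomicInterval, str]]:
    """Read BED3/BED4/BED6; returns (interval, name) with name '' for BED3."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append((iv, fields[3] if len(fields) > 3 else ""))
    return out


def write_bed(path, records: Iterable[tuple[GenomicInterval, str]]) -> None:
    """Write BED; emits BED4 when names are present, else BED3."""
    with open(path, "w") as fh:
        for iv, name in records:
            if name:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


GENE_TSV_COLUMNS = (
    "gene_id",
    "name",
    "biotype",
    "chrom",
    "strand",
    "exon_starts",
    "exon_ends",
)


def write_genes_tsv(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TSV_COLUMNS)
        for g in genes:
            writer.writerow(
                [
                    g.gene_id,
                    g.name,
                    g.biotype,
                    g.chrom,
                    g.strand,
                    ",".join(str(e.start) for e in g.exons),
                    ",".join(str(e.end) for e in g.exons),
                ]
            )


def read_genes_tsv(path, promoter_flank: int = 2000) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, 2):
            try:
                starts = [int(s) for s in row["exon_starts"].split(",") if s]
                ends = [int(s) for s in row["exon_ends"].split(",") if s]
                exons = tuple(
                    GenomicInterval(row["chrom"], s, e) for s, e in zip(starts, ends)
                )
                genes.append(
                    GeneModel(
                        gene_id=row["gene_id"],
                        name=row["name"],
                        biotype=row["biotype"],
                        chrom=row["chrom"],
                        strand=row["strand"],
                        exons=exons,
                        promoter_flank=promoter_flank,
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_genes_gff3(path, genes: Iterable[GeneModel]) -> None:
    """Write a GFF3 subset: one ``gene`` line plus ``exon`` children per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};gene_id={g.gene_id};gene_name={g.name};"
                f"gene_biotype={g.biotype}"
            )
            span = g.span
            fh.write(
                f"{g.chrom}\tpleiogene\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tpleiogene\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def _parse_gff3_attrs(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_genes_gff3(path, promoter_flank: int = 2000) -> list[GeneModel]:
    """Read the GFF3 subset (gene + exon features with gene_id/gene_name/
    gene_biotype attributes). GFF3 is 1-based inclusive; converted to the
    internal 0-based half-open convention on read."""
    meta: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attr_text = fields
            attrs = _parse_gff3_attrs(attr_text)
            if ftype == "gene":
                gid = attrs.get("gene_id") or attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene without gene_id/ID")
                meta[gid] = {
                    "name": attrs.get("gene_name", gid),
                    "biotype": attrs.get("gene_biotype", "other"),
                    "chrom": chrom,
                    "strand": strand,
                }
                order.append(gid)
            elif ftype == "exon":
                gid = attrs.get("Parent") or attrs.get("gene_id")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: exon without Parent")
                exons.setdefault(gid, []).append(
                    GenomicInterval(chrom, int(start) - 1, int(end))
                )
    genes = []
    for gid in order:
        m = meta[gid]
        exon_list = sorted(exons.get(gid, []), key=lambda e: e.start)
        genes.append(
            GeneModel(
                gene_id=gid,
                name=m["name"],
                biotype=m["biotype"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=tuple(exon_list),
                promoter_flank=promoter_flank,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and book-ended intervals per chromosome.

    Output is sorted by (chrom, start), pairwise disjoint and non-adjacent;
    the union of covered positions is preserved. Idempotent.
    """
    ivs = sorted(intervals, key=lambda x: (x.chrom, x.start, x.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def coverage_segments(
    interval_sets: Mapping[str, Sequence[GenomicInterval]],
    min_labels: int,
) -> list[tuple[GenomicInterval, frozenset]]:
    """Maximal segments covered by at least ``min_labels`` distinct labels.

    Each label's interval list must already be merged (so per-label coverage
    is 0/1 everywhere). Contiguous qualifying segments are fused; the label
    set attached to each output segment is every label whose intervals
    overlap the segment anywhere.
    """
    if min_labels < 1:
        raise ValueError("min_labels must be >= 1")
    # Boundary sweep per chromosome over label-count depth. Each label's
    # set is merged first so depth equals the distinct-label count.
    merged_sets = {label: merge_intervals(ivs) for label, ivs in interval_sets.items()}
    events: dict[str, list[tuple[int, int]]] = {}
    for label, ivs in merged_sets.items():
        for iv in ivs:
            events.setdefault(iv.chrom, []).append((iv.start, +1))
            events[iv.chrom].append((iv.end, -1))
    raw: list[GenomicInterval] = []
    for chrom in sorted(events):
        evs = sorted(events[chrom])
        depth = 0
        seg_start = None
        i = 0
        while i < len(evs):
            pos = evs[i][0]
            while i < len(evs) and evs[i][0] == pos:
                depth += evs[i][1]
                i += 1
            if depth >= min_labels and seg_start is None:
                seg_start = pos
            elif depth < min_labels and seg_start is not None:
                if pos > seg_start:
                    raw.append(GenomicInterval(chrom, seg_start, pos))
                seg_start = None
    segments = merge_intervals(raw)  # fuse book-ended qualifying segments
    out = []
    for seg in segments:
        labels = frozenset(
            label
            for label, ivs in merged_sets.items()
            if any(iv.overlaps(seg) for iv in ivs)
        )
        out.append((seg, labels))
    return out
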