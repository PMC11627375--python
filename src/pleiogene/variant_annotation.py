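"""Classify candidate variants against gene models and score thresholds.

Location classes are assigned per (variant, gene) pair with the precedence
exon > promoter > intron, where the promoter is TSS +/- 2 kb (inclusive
boundaries). A variant is intergenic only when it has no gene context at
all; it may simultaneously be a promoter variant of one gene and intronic
in another.

Score-based filters follow fixed thresholds on externally computed scores
(their computation is upstream of this package):

* splice-altering (intronic): SpliceAI delta >= 0.2 OR |MaxEntScan| > 0;
* regulatory: RegulomeDB probability strictly > 0.55 (the median of the
  genome-wide score distribution);
* coding: VEP class in {frameshift, missense, synonymous, 5'UTR, 3'UTR};
* chromatin support: any relevant biosample in an active ChromHMM state
  (TSS/enhancer classes by default).

Missing scores never qualify: absence of evidence is treated conservatively.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .genome_core import GeneModel, Variant

__all__ = [
    "AnnotationRecord",
    "GeneIndex",
    "classify_location",
    "summary_location",
    "is_splice_altering",
    "is_regulatory",
    "coding_evidence",
    "chromhmm_support",
    "read_scores",
    "write_scores",
    "DEFAULT_ACTIVE_STATES",
    "CODING_CLASSES",
    "SPLICEAI_THRESHOLD",
    "REGULOME_THRESHOLD",
]

SPLICEAI_THRESHOLD = 0.2
REGULOME_THRESHOLD = 0.55
CODING_CLASSES = ("frameshift", "missense", "synonymous", "utr5", "utr3")

#: ChromHMM state labels treated as "active" (TSS and enhancer classes,
#: EpiMap/Roadmap 18-state vocabulary). Configurable in every caller.
DEFAULT_ACTIVE_STATES = frozenset(
    {
        "TssA",
        "TssFlnk",
        "TssFlnkU",
        "TssFlnkD",
        "EnhA1",
        "EnhA2",
        "EnhG1",
        "EnhG2",
        "EnhWk",
    }
)


@dataclass
class AnnotationRecord:
    """Per-variant functional scores plus gene-context location classes."""

    variant_id: str
    location_class: dict[str, str] = field(default_factory=dict)  # gene_id -> class
    vep_class: str = "none"  # frameshift|missense|synonymous|utr5|utr3|other|none
    spliceai_delta: float | None = None
    maxentscan: float | None = None
    regulome_rank: str | None = None
    regulome_probability: float | None = None
    chromhmm_states: dict[str, str] = field(default_factory=dict)  # biosample -> state

    def __post_init__(self) -> None:
        if self.spliceai_delta is not None and not 0 <= self.spliceai_delta <= 1:
            raise ValueError(f"{self.variant_id}: SpliceAI delta outside [0,1]")
        if self.regulome_probability is not None and not (
            0 <= self.regulome_probability <= 1
        ):
            raise ValueError(f"{self.variant_id}: RegulomeDB probability outside [0,1]")


class GeneIndex:
    """Interval index over gene footprints (gene span union promoter)."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self.by_id = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for i, g in enumerate(self.genes):
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            span = g.span
            prom = g.promoter
            start = min(span.start, prom.start)
            end = max(span.end, prom.end)
            tree.addi(start, end, i)

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[hit.data] for hit in tree.overlap(start, end)]

    def at(self, chrom: str, pos: int) -> list[GeneModel]:
        return self.overlapping(chrom, pos, pos + 1)


def classify_location(
    variant: Variant, genes: GeneIndex | Sequence[GeneModel]
) -> dict[str, str]:
    """Per-gene location class for one variant.

    Returns ``{gene_id: class}`` with class in {exonic, promoter, intronic};
    an empty mapping means intergenic. Precedence within one gene is
    exon > promoter > intron, so every (variant, gene) pair gets exactly one
    class.
    """
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    out: dict[str, str] = {}
    for g in index.at(variant.chrom, variant.pos):
        if any(e.start <= variant.pos < e.end for e in g.exons):
            out[g.gene_id] = "exonic"
        elif g.promoter.contains(variant.chrom, variant.pos):
            out[g.gene_id] = "promoter"
        elif g.span.contains(variant.chrom, variant.pos):
            out[g.gene_id] = "intronic"
        # footprint hit outside both span and promoter cannot happen: the
        # footprint is exactly their union
    return out


def summary_location(location_class: Mapping[str, str]) -> str:
    """Single per-variant class using exon > promoter > intron > intergenic.

    This is the convention for variant-level tallies (a variant exonic in any
    gene counts as exonic, etc.); per-gene evidence keeps the full mapping.
    """
    classes = set(location_class.values())
    for cls in ("exonic", "promoter", "intronic"):
        if cls in classes:
            return cls
    return "intergenic"


def is_splice_altering(record: AnnotationRecord) -> bool:
    """SpliceAI delta >= 0.2 OR a nonzero MaxEntScan entropy score.

    Intended for intronic variants; missing scores do not qualify.
    """
    if record.spliceai_delta is not None and record.spliceai_delta >= SPLICEAI_THRESHOLD:
        return True
    if record.maxentscan is not None and abs(record.maxentscan) > 0:
        return True
    return False


def is_regulatory(record: AnnotationRecord) -> bool:
    """RegulomeDB probability strictly greater than 0.55; missing -> False."""
    if record.regulome_probability is None:
        return False
    return record.regulome_probability > REGULOME_THRESHOLD


def coding_evidence(record: AnnotationRecord) -> str | None:
    """Evidence category for a coding-consequence variant, else None."""
    if record.vep_class in CODING_CLASSES:
        return record.vep_class
    return None


def chromhmm_support(
    record: AnnotationRecord,
    relevant_biosamples: set[str] | None = None,
    active_states: frozenset = DEFAULT_ACTIVE_STATES,
) -> bool:
    """True iff any relevant biosample carries an active chromatin state.

    ``relevant_biosamples=None`` admits every recorded biosample.
    """
    for biosample, state in record.chromhmm_states.items():
        if relevant_biosamples is not None and biosample not in relevant_biosamples:
            continue
        if state in active_states:
            return True
    return False


# ---------------------------------------------------------------------------
# Score table I/O
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = (
    "variant_id",
    "vep_class",
    "spliceai_delta",
    "maxentscan",
    "regulome_rank",
    "regulome_probability",
)


def _opt_float(text: str | None) -> float | None:
    if text is None:
        return None
    text = text.strip()
    if text in ("", "NA", ".", "nan"):
        return None
    value = float(text)
    return None if math.isnan(value) else value


def read_scores(path) -> dict[str, AnnotationRecord]:
    """Read the per-variant score table.

    Accepts either the wide layout (one row per variant; ChromHMM states in
    ``chromhmm_<biosample>`` columns) or the long layout (repeated
    ``variant_id``/``biosample``/``state`` rows alongside the score columns).
    """
    records: dict[str, AnnotationRecord] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        fieldnames = reader.fieldnames or ()
        wide_cols = [c for c in fieldnames if c.startswith("chromhmm_")]
        long_layout = "biosample" in fieldnames and "state" in fieldnames
        for row in reader:
            vid = row["variant_id"]
            rec = records.get(vid)
            if rec is None:
                rec = AnnotationRecord(
                    variant_id=vid,
                    vep_class=(row.get("vep_class") or "none").strip() or "none",
                    spliceai_delta=_opt_float(row.get("spliceai_delta")),
                    maxentscan=_opt_float(row.get("maxentscan")),
                    regulome_rank=(row.get("regulome_rank") or "").strip() or None,
                    regulome_probability=_opt_float(row.get("regulome_probability")),
                )
                records[vid] = rec
            for col in wide_cols:
                state = (row.get(col) or "").strip()
                if state:
                    rec.chromhmm_states[col[len("chromhmm_"):]] = state
            if long_layout:
                biosample = (row.get("biosample") or "").strip()
                state = (row.get("state") or "").strip()
                if biosample and state:
                    rec.chromhmm_states[biosample] = state
    return records


def write_scores(path, records: Iterable[AnnotationRecord]) -> None:
    """Write the wide score-table layout."""
    records = list(records)
    biosamples = sorted({b for r in records for b in r.chromhmm_states})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(_SCORE_COLUMNS) + [f"chromhmm_{b}" for b in biosamples])
        for r in records:
            writer.writerow(
                [
                    r.variant_id,
                    r.vep_class,
                    "" if r.spliceai_delta is None else f"{r.spliceai_delta:g}",
                    "" if r.maxentscan is None else f"{r.maxentscan:g}",
                    r.regulome_rank or "",
                    ""
                    if r.regulome_probability is None
                    else f"{r.regulome_probability:g}",
                ]
                + [r.chromhmm_states.get(b, "") for b in biosamples]
            )
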