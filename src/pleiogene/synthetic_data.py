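"""Seedable generators for every pipeline input.

The generator emulates the study conditions end to end: four cancers' index
variant sets (196 breast / 17 endometrial / 60 ovarian / 258 prostate by
default) with tunable cross-cancer positional sharing, gene models with
strand-consistent TSSs and exons, a restriction-fragment tiling with
exponential-ish lengths, TAD tilings, per-variant score tables whose
regulatory fraction is controlled, and distance-decaying promoter-anchored
interactions enriched within TADs.

Planted-truth mode designates "true" pleiotropic target genes and places
qualifying variants (and, for a subset, within-TAD distal loops) for two
cancers around each, emitting a truth table; recovery precision/recall
against that table is the headline synthetic benchmark. In planted mode
background co-location is kept low (the sharing signal is modelled as driven
by the planted genes), which is why :meth:`SimulationConfig.planted` lowers
``pleiotropy_fraction`` to 0.1.

Every generator is a pure function of (config, seed): the same pair yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome_core import (
    GenomeAssembly,
    GenomicInterval,
    GeneModel,
    Variant,
    write_bed,
    write_genes_gff3,
    write_genes_tsv,
    write_variants,
)
from .chromatin_linking import (
    Fragment,
    FragmentMap,
    Interaction,
    TAD,
    TADIndex,
    promoter_baits,
    write_ibed,
)
from .variant_annotation import (
    AnnotationRecord,
    GeneIndex,
    classify_location,
    summary_location,
    write_scores,
)

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_all",
    "simulate_variants",
    "simulate_genome_annotation",
    "simulate_scores",
    "simulate_interactions",
    "digest_sequence",
    "evaluate_recovery",
    "CELL_LINES",
    "BIOSAMPLES",
]

DEFAULT_VARIANTS_PER_CANCER = {
    "breast": 196,
    "endometrial": 17,
    "ovarian": 60,
    "prostate": 258,
}

#: One PCHiC cell line and one ChromHMM biosample per cancer type.
CELL_LINES = {
    "breast": "MCF7",
    "endometrial": "ISHIKAWA",
    "ovarian": "OVCAR4",
    "prostate": "LNCAP",
}
BIOSAMPLES = {
    "breast": "breast_epithelium",
    "endometrial": "endometrium",
    "ovarian": "ovary",
    "prostate": "prostate_gland",
}

HINDIII_SITE = "AAGCTT"
HINDIII_CUT_OFFSET = 1  # HindIII cuts A^AGCTT


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic world; defaults are the study conditions."""

    n_chromosomes: int = 8
    chrom_length: int = 50_000_000
    variants_per_cancer: dict = field(
        default_factory=lambda: dict(DEFAULT_VARIANTS_PER_CANCER)
    )
    pleiotropy_fraction: float = 0.5
    co_locate_window: int = 50_000
    n_genes: int = 400
    lncrna_fraction: float = 0.2
    promoter_flank: int = 2000
    fragment_mean_length: int = 4_000
    fragment_min_length: int = 150
    tad_mean_length: int = 500_000
    interaction_count: int = 1_000
    interaction_decay_mean_fragments: int = 75
    within_tad_enrichment: float = 3.0
    score_pass_fraction: float = 0.8
    regulatory_fraction: float = 0.3
    n_true_genes: int = 0
    cosmic_fraction: float = 0.10
    drug_fraction: float = 0.10
    true_category_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "pleiotropy_fraction",
            "lncrna_fraction",
            "score_pass_fraction",
            "regulatory_fraction",
            "cosmic_fraction",
            "drug_fraction",
            "true_category_fraction",
        ):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0,1], got {value}")
        if self.within_tad_enrichment < 1:
            raise ValueError("within_tad_enrichment must be >= 1")
        for name in ("chrom_length", "fragment_mean_length", "tad_mean_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def planted(cls, n_true_genes: int = 12, seed: int = 0, **kwargs) -> "SimulationConfig":
        """Planted-truth configuration: background sharing is residual
        (pleiotropy 0.1); co-location comes from the planted genes."""
        kwargs.setdefault("pleiotropy_fraction", 0.1)
        return cls(n_true_genes=n_true_genes, seed=seed, **kwargs)


@dataclass
class PlantedGene:
    gene_id: str
    cancers: tuple[str, ...]
    channels: tuple[str, ...]  # evidence channel planted per cancer


@dataclass
class SyntheticDataset:
    """All pipeline inputs for one simulated world, in memory."""

    config: SimulationConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    fragmap: FragmentMap
    tads: list[TAD]
    variants: list[Variant]
    annotations: dict[str, AnnotationRecord]
    interactions: list[Interaction]
    category_lists: dict[str, set]
    truth: list[PlantedGene]

    def write(self, outdir) -> dict[str, Path]:
        """Dump every input in its standard text format; returns the paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        sizes = outdir / "chrom.sizes"
        with open(sizes, "w") as fh:
            for chrom, length in self.assembly.chromosomes:
                fh.write(f"{chrom}\t{length}\n")
        paths["chrom_sizes"] = sizes
        write_variants(outdir / "variants.tsv", self.variants)
        paths["variants"] = outdir / "variants.tsv"
        write_genes_gff3(outdir / "genes.gff3", self.genes)
        write_genes_tsv(outdir / "genes.tsv", self.genes)
        paths["genes"] = outdir / "genes.gff3"
        write_bed(
            outdir / "fragments.bed",
            [(f.interval, str(f.fragment_id)) for f in self.fragmap.fragments],
        )
        paths["fragments"] = outdir / "fragments.bed"
        write_bed(outdir / "tads.bed", [(t.interval, "") for t in self.tads])
        paths["tads"] = outdir / "tads.bed"
        write_scores(outdir / "scores.tsv", self.annotations.values())
        paths["scores"] = outdir / "scores.tsv"
        by_line: dict[str, list[Interaction]] = {}
        for x in self.interactions:
            by_line.setdefault(x.cell_line, []).append(x)
        for line, xs in sorted(by_line.items()):
            p = outdir / f"interactions_{line}.ibed"
            write_ibed(p, xs, self.fragmap)
            paths[f"interactions_{line}"] = p
        for name, members in sorted(self.category_lists.items()):
            p = outdir / f"{name}_genes.txt"
            with open(p, "w") as fh:
                for gid in sorted(members):
                    fh.write(gid + "\n")
            paths[name] = p
        truth_path = outdir / "truth.tsv"
        with open(truth_path, "w") as fh:
            fh.write("gene_id\tcancers\tchannels\n")
            for t in self.truth:
                fh.write(f"{t.gene_id}\t{','.join(t.cancers)}\t{','.join(t.channels)}\n")
        paths["truth"] = truth_path
        return paths


# ---------------------------------------------------------------------------
# Genome annotation: genes, fragments, TADs
# ---------------------------------------------------------------------------

def _make_assembly(config: SimulationConfig) -> GenomeAssembly:
    return GenomeAssembly(
        name="synthetic",
        chromosomes=tuple(
            (f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)
        ),
    )


def _simulate_genes(config: SimulationConfig, rng: np.random.Generator) -> list[GeneModel]:
    genes = []
    chroms = [c for c, _ in _make_assembly(config).chromosomes]
    for i in range(config.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        n_exons = int(rng.integers(2, 11))
        exon_lens = rng.integers(100, 1501, size=n_exons)
        intron_lens = rng.integers(500, 20_001, size=n_exons - 1)
        span = int(exon_lens.sum() + intron_lens.sum())
        start = int(rng.integers(10_000, config.chrom_length - span - 10_000))
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        lnc = rng.random() < config.lncrna_fraction
        gid = f"{'LNC' if lnc else 'GENE'}{i:04d}"
        genes.append(
            GeneModel(
                gene_id=gid,
                name=gid,
                biotype="lncRNA" if lnc else "protein_coding",
                chrom=chrom,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                promoter_flank=config.promoter_flank,
            )
        )
    return genes


def _simulate_fragments(config: SimulationConfig, rng: np.random.Generator) -> FragmentMap:
    fragments = []
    fid = 0
    for chrom, length in _make_assembly(config).chromosomes:
        pos = 0
        # draw a generous batch of exponential-ish lengths, then tile
        mean = config.fragment_mean_length - config.fragment_min_length
        n_est = int(length / config.fragment_mean_length * 1.3) + 10
        lens = config.fragment_min_length + rng.exponential(mean, size=n_est).astype(np.int64)
        i = 0
        while pos < length:
            if i >= len(lens):
                extra = config.fragment_min_length + rng.exponential(
                    mean, size=1000
                ).astype(np.int64)
                lens = np.concatenate([lens, extra])
            end = min(length, pos + int(lens[i]))
            fragments.append(Fragment(fid, GenomicInterval(chrom, pos, end)))
            fid += 1
            pos = end
            i += 1
    return FragmentMap(fragments)


def _simulate_tads(config: SimulationConfig, rng: np.random.Generator) -> list[TAD]:
    tads = []
    for chrom, length in _make_assembly(config).chromosomes:
        pos = 0
        while pos < length:
            size = int(rng.uniform(0.5, 1.5) * config.tad_mean_length)
            end = min(length, pos + size)
            if end - pos >= config.tad_mean_length // 10:
                tads.append(TAD(GenomicInterval(chrom, pos, end)))
            pos = end
    return tads


def simulate_genome_annotation(
    config: SimulationConfig, rng: np.random.Generator | None = None
):
    """Genes, restriction-fragment tiling and TAD tiling for the config."""
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    assembly = _make_assembly(config)
    genes = _simulate_genes(config, rng)
    fragmap = _simulate_fragments(config, rng)
    tads = _simulate_tads(config, rng)
    return assembly, genes, fragmap, tads


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_PAIR_CYCLE = (
    ("breast", "prostate"),
    ("breast", "ovarian"),
    ("ovarian", "prostate"),
    ("endometrial", "prostate"),
)


def _plant(
    config: SimulationConfig,
    genes: list[GeneModel],
    tads: list[TAD],
    rng: np.random.Generator,
):
    """Choose true pleiotropic genes and construct their qualifying variants.

    Per gene, cancer A gets a promoter variant; cancer B gets either an
    exonic missense variant or (every third gene) a distal intergenic
    regulatory variant that will be looped to the gene's promoter within a
    TAD. All planted variants are index variants, so the pair also seeds a
    multi-cancer region around the gene.
    """
    pc = [g for g in genes if g.biotype == "protein_coding"]
    order = rng.permutation(len(pc))
    chosen: list[GeneModel] = []
    for idx in order:
        g = pc[idx]
        if any(
            g.chrom == h.chrom and abs(g.tss - h.tss) < 3_000_000 for h in chosen
        ):
            continue
        if not (1_000_000 < g.tss < config.chrom_length - 1_000_000):
            continue
        chosen.append(g)
        if len(chosen) == config.n_true_genes:
            break
    gene_index = GeneIndex(genes)
    tad_index = TADIndex(tads)
    planted_variants: list[tuple[Variant, dict]] = []  # (variant, score overrides)
    planted_loops: list[tuple[str, str, str]] = []  # (variant_id, gene_id, cancer)
    truth: list[PlantedGene] = []
    counter = 0

    def promoter_pos(g: GeneModel) -> int:
        off = int(rng.integers(200, min(1800, config.promoter_flank) + 1))
        return g.tss - off if g.strand == "+" else g.tss + off

    for k, g in enumerate(chosen):
        c_a, c_b = _PAIR_CYCLE[k % len(_PAIR_CYCLE)]
        distal = k % 3 == 2
        channels = ["promoter"]
        # cancer A: promoter variant with active chromatin in both cancers
        counter += 1
        v_a = Variant(
            id=f"rsP{counter:05d}",
            chrom=g.chrom,
            pos=promoter_pos(g),
            cancer=c_a,
            signal_id=f"sig_P{counter:05d}",
        )
        planted_variants.append(
            (
                v_a,
                {
                    "regulome_probability": 0.85,
                    "chromhmm": {BIOSAMPLES[c_a]: "TssA", BIOSAMPLES[c_b]: "TssA"},
                },
            )
        )
        counter += 1
        if distal:
            pos_b = _distal_position(g, gene_index, tad_index, rng)
            if pos_b is None:
                distal = False  # no intergenic spot in this TAD; fall back
        if distal:
            channels.append("distal_reg_within_tad")
            v_b = Variant(
                id=f"rsP{counter:05d}",
                chrom=g.chrom,
                pos=pos_b,
                cancer=c_b,
                signal_id=f"sig_P{counter:05d}",
            )
            planted_variants.append(
                (
                    v_b,
                    {
                        "regulome_probability": 0.92,
                        "chromhmm": {BIOSAMPLES[c_b]: "EnhA1"},
                    },
                )
            )
            planted_loops.append((v_b.id, g.gene_id, c_b))
        else:
            channels.append("missense")
            exon = g.exons[len(g.exons) // 2]
            v_b = Variant(
                id=f"rsP{counter:05d}",
                chrom=g.chrom,
                pos=exon.start + len(exon) // 2,
                cancer=c_b,
                signal_id=f"sig_P{counter:05d}",
            )
            planted_variants.append((v_b, {"vep_class": "missense"}))
        truth.append(PlantedGene(g.gene_id, (c_a, c_b), tuple(channels)))
    return planted_variants, planted_loops, truth


def _distal_position(g, gene_index: GeneIndex, tad_index: TADIndex, rng) -> int | None:
    """An intergenic position in the gene's TAD, within 400 kb of the TSS."""
    ti = tad_index.at(g.chrom, g.tss)
    if ti is None:
        return None
    tad = tad_index.tads[ti].interval
    # keep clear of TAD edges so restriction-fragment midpoints stay inside
    if not (tad.start + 10_000 <= g.tss < tad.end - 10_000):
        return None
    lo = max(tad.start + 10_000, g.tss - 400_000)
    hi = min(tad.end - 10_000, g.tss + 400_000)
    if hi - lo < 1_000:
        return None
    for _ in range(200):
        pos = int(rng.integers(lo, hi))
        probe = Variant(id="probe", chrom=g.chrom, pos=pos, cancer="breast")
        if not classify_location(probe, gene_index):
            return pos
    return None


def simulate_variants(
    config: SimulationConfig,
    assembly: GenomeAssembly,
    rng: np.random.Generator,
    planted: list[tuple[Variant, dict]] | None = None,
) -> list[Variant]:
    """Four cancers' index variant sets with tunable co-location.

    Breast variants are uniform per chromosome; each other cancer's variant
    is, with probability ``pleiotropy_fraction``, placed within
    ``co_locate_window`` of a random breast variant, else uniform. Planted
    variants (if any) consume their cancer's quota first, so per-cancer
    totals always equal ``variants_per_cancer``.
    """
    chroms = [c for c, _ in assembly.chromosomes]
    lengths = assembly.lengths
    planted = planted or []
    planted_by_cancer: dict[str, int] = {}
    for v, _ in planted:
        planted_by_cancer[v.cancer] = planted_by_cancer.get(v.cancer, 0) + 1
    for cancer, n_planted in planted_by_cancer.items():
        quota = config.variants_per_cancer.get(cancer, 0)
        if n_planted > quota:
            raise ValueError(
                f"{n_planted} planted {cancer} variants exceed quota {quota}"
            )
    variants: list[Variant] = [v for v, _ in planted]
    counter = 0

    def uniform_variant(cancer: str) -> Variant:
        nonlocal counter
        counter += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pos = int(rng.integers(0, lengths[chrom]))
        return Variant(
            id=f"rsB{counter:05d}",
            chrom=chrom,
            pos=pos,
            cancer=cancer,
            signal_id=f"sig_B{counter:05d}",
        )

    n_bg_breast = config.variants_per_cancer.get("breast", 0) - planted_by_cancer.get(
        "breast", 0
    )
    breast_bg = [uniform_variant("breast") for _ in range(n_bg_breast)]
    variants.extend(breast_bg)
    breast_all = [v for v in variants if v.cancer == "breast"]

    for cancer, quota in config.variants_per_cancer.items():
        if cancer == "breast":
            continue
        n_bg = quota - planted_by_cancer.get(cancer, 0)
        for _ in range(n_bg):
            if breast_all and rng.random() < config.pleiotropy_fraction:
                anchor = breast_all[int(rng.integers(len(breast_all)))]
                w = config.co_locate_window
                off = int(rng.integers(-w, w + 1))
                pos = min(max(0, anchor.pos + off), lengths[anchor.chrom] - 1)
                counter += 1
                variants.append(
                    Variant(
                        id=f"rsB{counter:05d}",
                        chrom=anchor.chrom,
                        pos=pos,
                        cancer=cancer,
                        signal_id=f"sig_B{counter:05d}",
                    )
                )
            else:
                variants.append(uniform_variant(cancer))
    return variants


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

_VEP_CHOICES = ("missense", "synonymous", "utr5", "utr3", "frameshift", "other")
_VEP_WEIGHTS = (0.42, 0.28, 0.10, 0.10, 0.02, 0.08)
_ACTIVE_CHOICES = ("TssA", "TssFlnk", "EnhA1", "EnhA2", "EnhWk")


def simulate_scores(
    variants: list[Variant],
    genes: list[GeneModel],
    config: SimulationConfig,
    rng: np.random.Generator,
    overrides: dict[str, dict] | None = None,
) -> dict[str, AnnotationRecord]:
    """Per-variant score table consistent with the variants' gene context.

    Noncoding variants exceed the 0.55 RegulomeDB probability threshold with
    probability ``regulatory_fraction``; exonic variants get sparse VEP
    consequences; SpliceAI/MaxEntScan are mostly missing with occasional
    qualifying values on intronic variants. ``overrides`` force specific
    values (used by the planted-truth generator).
    """
    overrides = overrides or {}
    index = GeneIndex(genes)
    records: dict[str, AnnotationRecord] = {}
    for v in variants:
        loc = classify_location(v, index)
        summary = summary_location(loc)
        ov = overrides.get(v.id, {})
        if summary == "exonic":
            vep = ov.get(
                "vep_class",
                str(rng.choice(_VEP_CHOICES, p=_VEP_WEIGHTS)),
            )
            prob = float(rng.uniform(0.02, 0.55))
        else:
            vep = ov.get("vep_class", "none")
            if rng.random() < config.regulatory_fraction:
                prob = float(rng.uniform(0.5501, 0.98))
            else:
                prob = float(rng.uniform(0.02, 0.55))
        prob = ov.get("regulome_probability", prob)
        spliceai = None
        maxent = None
        if summary == "intronic":
            u = rng.random()
            if u < 0.02:
                spliceai = float(rng.uniform(0.2, 0.6))
            elif u < 0.22:
                spliceai = float(rng.uniform(0.0, 0.15))
            if rng.random() < 0.02:
                maxent = float(rng.normal(0.0, 2.0))
        spliceai = ov.get("spliceai_delta", spliceai)
        maxent = ov.get("maxentscan", maxent)
        rank = "1a" if prob > 0.9 else ("2b" if prob > 0.55 else "5")
        states: dict[str, str] = {}
        for biosample in BIOSAMPLES.values():
            if prob > 0.55:
                active = rng.random() < 0.5
            else:
                active = rng.random() < 0.1
            states[biosample] = (
                str(rng.choice(_ACTIVE_CHOICES)) if active else "Quies"
            )
        states.update(ov.get("chromhmm", {}))
        rec = AnnotationRecord(
            variant_id=v.id,
            location_class=loc,
            vep_class=vep,
            spliceai_delta=spliceai,
            maxentscan=maxent,
            regulome_rank=rank,
            regulome_probability=prob,
            chromhmm_states=states,
        )
        records[v.id] = rec
    return records


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

def simulate_interactions(
    fragmap: FragmentMap,
    genes: list[GeneModel],
    tads: list[TAD],
    config: SimulationConfig,
    rng: np.random.Generator,
    planted_loops: list[tuple[str, str, str]] | None = None,
    variants_by_id: dict[str, Variant] | None = None,
) -> list[Interaction]:
    """Promoter-anchored interactions with distance decay and TAD enrichment.

    Baits are fragments overlapping a gene promoter; other ends are drawn at
    a geometric fragment offset from the bait (mean
    ``interaction_decay_mean_fragments``, ~300 kb at the default fragment
    size, so the within-TAD fraction is informative about TADs). Proposed
    pairs whose midpoints do not share a TAD are accepted with probability
    ``1 / within_tad_enrichment``, giving the configured within-TAD odds
    enrichment. Scores are drawn so ``score_pass_fraction`` of interactions
    clear the CHiCAGO >= 5 threshold. Planted loops (variant fragment ->
    target promoter fragment) are appended with high confidence.
    """
    baited = sorted(promoter_baits(fragmap, genes))
    if not baited:
        raise ValueError("no baited fragments: no promoters overlap the fragment map")
    by_chrom: dict[str, list[Fragment]] = {}
    for f in fragmap.fragments:
        by_chrom.setdefault(f.interval.chrom, []).append(f)
    for fr in by_chrom.values():
        fr.sort(key=lambda f: f.interval.start)
    chrom_pos = {
        f.fragment_id: (f.interval.chrom, i)
        for fr in by_chrom.values()
        for i, f in enumerate(fr)
    }
    tad_index = TADIndex(tads)
    cell_lines = sorted(CELL_LINES.values())

    def draw_score() -> float:
        if rng.random() < config.score_pass_fraction:
            return float(rng.uniform(5.0, 15.0))
        return float(rng.uniform(0.0, 5.0))

    interactions: list[Interaction] = []
    while len(interactions) < config.interaction_count:
        bait_id = int(baited[int(rng.integers(len(baited)))])
        chrom, bi = chrom_pos[bait_id]
        row = by_chrom[chrom]
        for _attempt in range(50):
            offset = int(rng.geometric(1.0 / config.interaction_decay_mean_fragments))
            sign = 1 if rng.random() < 0.5 else -1
            oi = bi + sign * offset
            if not (0 <= oi < len(row)) or oi == bi:
                continue
            bait_frag = row[bi]
            other_frag = row[oi]
            same = tad_index.same_tad(chrom, bait_frag.midpoint, other_frag.midpoint)
            if not same and rng.random() >= 1.0 / config.within_tad_enrichment:
                continue
            interactions.append(
                Interaction(
                    bait=bait_id,
                    other_end=other_frag.fragment_id,
                    cell_line=cell_lines[int(rng.integers(len(cell_lines)))],
                    score=draw_score(),
                    n_reads=int(rng.integers(5, 200)),
                )
            )
            break
    gene_by_id = {g.gene_id: g for g in genes}
    for vid, gid, cancer in planted_loops or ():
        v = (variants_by_id or {}).get(vid)
        g = gene_by_id[gid]
        if v is None:
            continue
        v_frag = fragmap.at(v.chrom, v.pos)
        bait_candidates = fragmap.overlapping(g.promoter)
        if v_frag is None or not bait_candidates:
            continue
        bait_frag = bait_candidates[0]
        if bait_frag.fragment_id == v_frag.fragment_id:
            continue
        interactions.append(
            Interaction(
                bait=bait_frag.fragment_id,
                other_end=v_frag.fragment_id,
                cell_line=CELL_LINES[cancer],
                score=float(rng.uniform(8.0, 15.0)),
                n_reads=int(rng.integers(50, 200)),
            )
        )
    return interactions


# ---------------------------------------------------------------------------
# Orchestrator
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig) -> SyntheticDataset:
    """Generate the whole synthetic world for (config, config.seed)."""
    root = np.random.SeedSequence(config.seed)
    rng_genome, rng_plant, rng_var, rng_score, rng_int, rng_cat = (
        np.random.default_rng(s) for s in root.spawn(6)
    )
    assembly = _make_assembly(config)
    genes = _simulate_genes(config, rng_genome)
    fragmap = _simulate_fragments(config, rng_genome)
    tads = _simulate_tads(config, rng_genome)

    planted_variants: list[tuple[Variant, dict]] = []
    planted_loops: list[tuple[str, str, str]] = []
    truth: list[PlantedGene] = []
    if config.n_true_genes > 0:
        planted_variants, planted_loops, truth = _plant(config, genes, tads, rng_plant)

    variants = simulate_variants(config, assembly, rng_var, planted=planted_variants)
    overrides = {v.id: ov for v, ov in planted_variants}
    annotations = simulate_scores(variants, genes, config, rng_score, overrides=overrides)
    interactions = simulate_interactions(
        fragmap,
        genes,
        tads,
        config,
        rng_int,
        planted_loops=planted_loops,
        variants_by_id={v.id: v for v in variants},
    )

    truth_ids = {t.gene_id for t in truth}
    cosmic, drug = set(), set()
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        p_cos = (
            config.true_category_fraction
            if g.gene_id in truth_ids
            else config.cosmic_fraction
        )
        p_drug = (
            config.true_category_fraction
            if g.gene_id in truth_ids
            else config.drug_fraction
        )
        if rng_cat.random() < p_cos:
            cosmic.add(g.gene_id)
        if rng_cat.random() < p_drug:
            drug.add(g.gene_id)

    return SyntheticDataset(
        config=config,
        assembly=assembly,
        genes=genes,
        fragmap=fragmap,
        tads=tads,
        variants=variants,
        annotations=annotations,
        interactions=interactions,
        category_lists={"cosmic": cosmic, "drug_target": drug},
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Utilities
# ---------------------------------------------------------------------------

def digest_sequence(seq: str, chrom: str = "chr1") -> list[GenomicInterval]:
    """In-silico HindIII digest: cut at every AAGCTT occurrence (A^AGCTT)."""
    seq = seq.upper()
    cuts = []
    start = 0
    while True:
        hit = seq.find(HINDIII_SITE, start)
        if hit == -1:
            break
        cuts.append(hit + HINDIII_CUT_OFFSET)
        start = hit + 1
    bounds = [0] + cuts + [len(seq)]
    return [
        GenomicInterval(chrom, a, b) for a, b in zip(bounds[:-1], bounds[1:]) if b > a
    ]


def evaluate_recovery(candidate_ids: set, truth: list[PlantedGene]) -> dict:
    """Precision/recall of called candidates against the planted truth."""
    truth_ids = {t.gene_id for t in truth}
    tp = len(candidate_ids & truth_ids)
    precision = tp / len(candidate_ids) if candidate_ids else float("nan")
    recall = tp / len(truth_ids) if truth_ids else float("nan")
    return {
        "n_true": len(truth_ids),
        "n_called": len(candidate_ids),
        "n_recovered": tp,
        "precision": precision,
        "recall": recall,
    }
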