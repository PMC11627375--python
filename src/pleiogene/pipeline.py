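"""End-to-end pipeline: simulate/load inputs, then run every stage in order.

Stage order mirrors the analysis: cluster test -> region construction ->
variant annotation -> PCHiC linking + TAD test -> candidate gene and lncRNA
calls -> category enrichment. Deterministic stages (regions, annotation,
linking, calling) are seed-independent; only the permutation stages consume
seeds. Every run writes a manifest (config hash, input hashes, seeds,
outputs) so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import fields as dataclass_fields
from pathlib import Path

from . import genome_core, synthetic_data
from .chromatin_linking import (
    assign_distal,
    filter_interactions,
    read_fragments_bed,
    read_ibed,
    read_tads_bed,
    tad_enrichment,
)
from .cluster_test import clustering_permutation_test
from .integration_enrichment import (
    call_candidate_genes,
    call_candidate_lncrnas,
    fisher_enrichment,
    genes_at_regions,
    matched_permutation_z,
)
from .region_builder import (
    build_cancer_regions,
    build_mhdcr_regions,
    combination_summary,
    count_signals,
)
from .variant_annotation import read_scores

logger = logging.getLogger(__name__)

__all__ = ["run_all", "DEFAULT_CONFIG", "load_config", "write_candidates_tsv"]

DEFAULT_CONFIG = {
    # stage thresholds (the published defaults)
    "max_gap": 100_000,
    "flank": 500_000,
    "min_cancers": 2,
    "promoter_flank": 2_000,
    "min_score": 5.0,
    "n_perms_cluster": 10_000,
    "n_perms_tad": 10_000,
    "n_perms_enrich": 10_000,
    "seed": 0,
    # input mode: simulate=True uses the synthetic generator, else file paths
    "simulate": True,
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    config = dict(DEFAULT_CONFIG)
    config.update(user)
    return config


def _sim_config(config: dict) -> synthetic_data.SimulationConfig:
    names = {f.name for f in dataclass_fields(synthetic_data.SimulationConfig)}
    kwargs = {
        key[len("sim_"):]: value
        for key, value in config.items()
        if key.startswith("sim_") and key[len("sim_"):] in names
    }
    kwargs.setdefault("seed", config.get("seed", 0))
    return synthetic_data.SimulationConfig(**kwargs)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_inputs(config: dict):
    for key in ("chrom_sizes", "variants"):
        if key not in config:
            raise FileNotFoundError(f"stage load-inputs: missing input '{key}'")
    assembly = genome_core.read_chrom_sizes(config["chrom_sizes"])
    variants = genome_core.read_variants(
        config["variants"], assembly, allowed_cancers=None
    )
    genes = []
    if "genes" in config:
        path = str(config["genes"])
        reader = (
            genome_core.read_genes_gff3
            if path.endswith((".gff3", ".gff"))
            else genome_core.read_genes_tsv
        )
        genes = reader(path, promoter_flank=config.get("promoter_flank", 2000))
    annotations = read_scores(config["scores"]) if "scores" in config else {}
    fragmap = (
        read_fragments_bed(config["fragments"]) if "fragments" in config else None
    )
    tads = read_tads_bed(config["tads"]) if "tads" in config else None
    interactions = []
    for entry in config.get("interactions", []):
        if fragmap is None:
            raise FileNotFoundError("stage link: interactions given without fragments")
        interactions.extend(
            read_ibed(entry["path"], fragmap, cell_line=entry.get("cell_line", "NA"))
        )
    return assembly, variants, genes, annotations, fragmap, tads, interactions


def write_candidates_tsv(path, candidates, cancers=genome_core.HDC_CANCERS) -> None:
    with open(path, "w") as fh:
        header = ["gene_id", "name", "biotype", "regions"] + list(cancers) + [
            "chromhmm",
            "cosmic",
            "drug_target",
        ]
        fh.write("\t".join(header) + "\n")
        for c in candidates:
            row = [
                c.gene_id,
                c.name,
                c.biotype,
                ",".join(str(r) for r in c.region_ids),
            ]
            for cancer in cancers:
                row.append("|".join(sorted(c.evidence.get(cancer, ()))))
            row += [
                "*" if c.chromhmm_support else "",
                "1" if c.cosmic else "0",
                "1" if c.drug_target else "0",
            ]
            fh.write("\t".join(row) + "\n")


def run_all(config: dict, outdir) -> dict:
    """Run every stage in order; returns the results dict and writes outputs.

    Fails fast with the first stage's error. Without TAD annotations the
    link stage runs with ``within_tad`` false everywhere (logged) and the
    TAD test and distal evidence channel are disabled.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = {**DEFAULT_CONFIG, **config}
    seed = int(config["seed"])
    manifest = {
        "subcommand": "run-all",
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "input_hashes": {},
        "outputs": [],
    }
    results: dict = {}

    if config.get("simulate", False):
        sim = _sim_config(config)
        dataset = synthetic_data.simulate_all(sim)
        assembly = dataset.assembly
        variants = dataset.variants
        genes = dataset.genes
        annotations = dataset.annotations
        fragmap = dataset.fragmap
        tads = dataset.tads
        interactions = dataset.interactions
        category_lists = dataset.category_lists
        results["truth"] = [t.gene_id for t in dataset.truth]
    else:
        assembly, variants, genes, annotations, fragmap, tads, interactions = (
            _load_inputs(config)
        )
        for key in ("chrom_sizes", "variants", "genes", "scores", "fragments", "tads"):
            if key in config:
                manifest["input_hashes"][key] = _hash_file(config[key])
        category_lists = {}
        for name in ("cosmic", "drug_target"):
            if name in config:
                with open(config[name]) as fh:
                    category_lists[name] = {
                        line.split("\t")[0].strip() for line in fh if line.strip()
                    }

    # 1. clustering permutation test (index variants only by default)
    index_variants = [v for v in variants if v.is_index]
    cluster = clustering_permutation_test(
        index_variants,
        assembly,
        max_gap=int(config["max_gap"]),
        n_perms=int(config["n_perms_cluster"]),
        rng_seed=seed,
    )
    results["cluster_test"] = cluster.to_dict()
    (outdir / "cluster.json").write_text(json.dumps(cluster.to_dict(), indent=2))

    # 2. regions
    per_cancer = build_cancer_regions(
        index_variants, assembly, flank=int(config["flank"])
    )
    regions = build_mhdcr_regions(per_cancer, min_cancers=int(config["min_cancers"]))
    count_signals(regions, index_variants)
    summary = combination_summary(regions)
    results["regions"] = {
        "n_regions": summary["n_regions"],
        "by_cardinality": {str(k): v for k, v in summary["by_cardinality"].items()},
    }
    genome_core.write_bed(
        outdir / "regions.bed",
        [(r.interval, str(r.region_id)) for r in regions],
    )
    with open(outdir / "regions_summary.tsv", "w") as fh:
        fh.write("region_id\tchrom\tstart\tend\tcancers\tsignal_counts\n")
        for r in regions:
            counts = ";".join(f"{c}:{n}" for c, n in sorted(r.signal_counts.items()))
            fh.write(
                f"{r.region_id}\t{r.interval.chrom}\t{r.interval.start}\t"
                f"{r.interval.end}\t{','.join(sorted(r.cancers))}\t{counts}\n"
            )

    # 3+4. linking and TAD test
    links = []
    tad_result = None
    hi_conf = filter_interactions(interactions, min_score=float(config["min_score"]))
    if fragmap is not None and interactions:
        if tads is None:
            logger.warning(
                "no TAD annotations: links get within_tad=false, TAD test skipped"
            )
        links = assign_distal(
            variants, fragmap, hi_conf, genes, annotations, tads or []
        )
        if tads:
            tad_result = tad_enrichment(
                hi_conf,
                fragmap,
                tads,
                regions,
                n_perms=int(config["n_perms_tad"]),
                rng_seed=seed + 1,
                oversized="skip",
            )
            results["tad_test"] = tad_result.to_dict()
            (outdir / "tad.json").write_text(
                json.dumps(tad_result.to_dict(), indent=2)
            )
    results["n_high_confidence_interactions"] = len(hi_conf)
    results["n_distal_links"] = len(links)

    # 5. candidate calls
    candidates = call_candidate_genes(
        regions, variants, annotations, links, genes, category_lists=category_lists
    )
    coding_candidates = call_candidate_genes(
        regions, variants, annotations, links, genes, coding_only=True
    )
    lncrnas = call_candidate_lncrnas(
        regions, variants, annotations, links, genes, category_lists=category_lists
    )
    results["n_candidate_genes"] = len(candidates)
    results["n_coding_only_candidates"] = len(coding_candidates)
    results["n_candidate_lncrnas"] = len(lncrnas)
    write_candidates_tsv(outdir / "candidates.tsv", candidates)
    write_candidates_tsv(outdir / "lncrnas.tsv", lncrnas)

    # 6. enrichment
    pc_genes = [g for g in genes if g.biotype == "protein_coding"]
    gene_regions = genes_at_regions(pc_genes, regions)
    background = set(gene_regions)
    enrich = {}
    if background and candidates:
        pools: dict[int, list[str]] = {}
        for gid, rids in gene_regions.items():
            for rid in rids:
                pools.setdefault(rid, []).append(gid)
        for name, members in category_lists.items():
            res = fisher_enrichment(
                {c.gene_id for c in candidates}, set(members), background
            )
            z, z_def, _ = matched_permutation_z(
                candidates,
                set(members),
                pools,
                n_perms=int(config["n_perms_enrich"]),
                rng_seed=seed + 2,
            )
            res.z_matched = z if z_def else None
            res.z_defined = z_def
            res.n_perms = int(config["n_perms_enrich"])
            res.seed = seed + 2
            enrich[name] = res.to_dict()
    results["enrichment"] = enrich
    (outdir / "enrichment.json").write_text(json.dumps(enrich, indent=2))

    if "truth" in results:
        recovery = synthetic_data.evaluate_recovery(
            {c.gene_id for c in candidates},
            [
                synthetic_data.PlantedGene(gid, (), ())
                for gid in results["truth"]
            ],
        )
        results["recovery"] = recovery

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir())
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "results.json").write_text(json.dumps(results, indent=2, default=str))
    return results
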