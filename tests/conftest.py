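import numpy as np
import pytest

from pleiogene import synthetic_data as sd
from pleiogene.genome_core import GenomeAssembly, GenomicInterval, GeneModel, Variant


@pytest.fixture
def toy_assembly() -> GenomeAssembly:
    return GenomeAssembly(
        name="toy",
        chromosomes=(("chr1", 2_000_000), ("chr2", 1_500_000)),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_gene(
    gene_id="G1",
    chrom="chr1",
    strand="+",
    exon_coords=((10_000, 10_500), (12_000, 12_400), (15_000, 15_800)),
    biotype="protein_coding",
    promoter_flank=2000,
) -> GeneModel:
    exons = tuple(GenomicInterval(chrom, s, e) for s, e in exon_coords)
    return GeneModel(
        gene_id=gene_id,
        name=gene_id,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exons=exons,
        promoter_flank=promoter_flank,
    )


def make_variant(vid="v1", chrom="chr1", pos=100, cancer="breast", **kwargs) -> Variant:
    kwargs.setdefault("signal_id", f"sig_{vid}")
    return Variant(id=vid, chrom=chrom, pos=pos, cancer=cancer, **kwargs)


@pytest.fixture(scope="session")
def planted_dataset() -> sd.SyntheticDataset:
    """One planted-truth synthetic world shared across tests (seed fixed)."""
    return sd.simulate_all(sd.SimulationConfig.planted(12, seed=11))


@pytest.fixture(scope="session")
def small_dataset() -> sd.SyntheticDataset:
    """A small non-planted world for stage-level tests."""
    return sd.simulate_all(
        sd.SimulationConfig(
            n_chromosomes=3,
            chrom_length=20_000_000,
            n_genes=120,
            interaction_count=300,
            seed=7,
        )
    )
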