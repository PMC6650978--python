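import numpy as np
import pytest

from polyfam.models import ChromosomeId, GeneModel
from polyfam.simulate import SimulationConfig, simulate_genome, simulate_expression_counts


def small_config(seed: int = 11) -> SimulationConfig:
    """Reduced study conditions for fast unit tests: 9 x 150 kb chromosomes."""
    return SimulationConfig(
        seed=seed,
        chromosomes_per_subgenome=3,
        chromosome_length=150_000,
        n_triplets=2,
        n_pairs=2,
        n_singlets=8,
        n_background_genes=30,
        n_planted_duplications=3,
        duplication_length_range=(3_000, 5_000),
        n_silent_genes=5,
        n_tissue_specific=3,
    )


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    assembly, genes, truth = simulate_genome(cfg)
    return cfg, assembly, genes, truth


@pytest.fixture(scope="session")
def small_sim_counts(small_sim):
    cfg, _assembly, genes, truth = small_sim
    counts, samples = simulate_expression_counts(genes, truth, cfg)
    return counts, samples, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default study conditions (21 x 1 Mb chromosomes), built once."""
    cfg = SimulationConfig(seed=1)
    assembly, genes, truth = simulate_genome(cfg)
    return cfg, assembly, genes, truth


def make_gene(
    gene_id: str = "g1",
    exon_cds_lengths: list[int] | None = None,
    intron_lengths: list[int] | None = None,
    cds: str | None = None,
    chromosome: ChromosomeId | None = None,
    strand: str = "+",
    offset: int = 1_000,
    rng: np.random.Generator | None = None,
) -> GeneModel:
    """Construct a plus-strand toy gene with the requested exon CDS lengths."""
    from polyfam.io import translate
    from polyfam.simulate import random_cds

    if rng is None:
        rng = np.random.default_rng(hash(gene_id) % (2**31))
    if exon_cds_lengths is None:
        exon_cds_lengths = [306, 174]
    total = sum(exon_cds_lengths)
    assert total % 3 == 0
    if cds is None:
        cds = random_cds(total // 3, rng)
    assert len(cds) == total
    if intron_lengths is None:
        intron_lengths = [100] * (len(exon_cds_lengths) - 1)
    exons = []
    pos = offset
    for i, elen in enumerate(exon_cds_lengths):
        exons.append((pos, pos + elen))
        pos += elen
        if i < len(intron_lengths):
            pos += intron_lengths[i]
    return GeneModel(
        gene_id=gene_id,
        chromosome=chromosome or ChromosomeId(1, "A"),
        strand=strand,
        exons=exons,
        cds=cds,
        protein=translate(cds),
    )
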