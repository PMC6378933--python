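import numpy as np
import pytest

from cdsortho import CDSGene, GeneSet, SimParams, simulate_pair


def make_gene(species, gene_id, seqs, transcript_id=None):
    return CDSGene(species, gene_id, transcript_id or f"{gene_id}.t1", tuple(seqs))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_fixture():
    """60 planted ortholog pairs + 10 decoys per species, 1% divergence."""
    return simulate_pair(SimParams(seed=101, n_genes=60, n_decoys=10))


@pytest.fixture(scope="session")
def structural_fixture():
    """Every ortholog carries exactly one fusion or split event."""
    return simulate_pair(SimParams(seed=202, n_genes=80, n_decoys=10, p_structural=1.0))


def random_gene_set(rng, species, n_genes, min_exons=1, max_exons=6,
                    len_lo=6, len_hi=40):
    """Small random gene set for oracle-equivalence tests: short exons and a
    narrow length range force length collisions and near-threshold distances."""
    genes = []
    for k in range(n_genes):
        n = int(rng.integers(min_exons, max_exons + 1))
        seqs = tuple(
            "".join(rng.choice(list("ACGT"), size=int(rng.integers(len_lo, len_hi))))
            for _ in range(n)
        )
        genes.append(CDSGene(species, f"{species}_g{k:04d}", f"{species}_g{k:04d}.t1", seqs))
    return GeneSet(species, tuple(genes))
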