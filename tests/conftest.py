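import numpy as np
import pytest

from treescan import (
    HaplotypeMatrix,
    SimulationConfig,
    filter_monomorphic,
    recode_minor,
    simulate_haplotypes,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20251)


def make_haps(entries, positions=None, chrom="1"):
    """Build a HaplotypeMatrix from a raw 0/1 array with default ids."""
    entries = np.asarray(entries, dtype=np.uint8)
    n_rows, n_snps = entries.shape
    if positions is None:
        positions = np.arange(1, n_snps + 1) * 100
    return HaplotypeMatrix(
        entries=entries,
        positions=np.asarray(positions, dtype=np.int64),
        snp_ids=tuple(f"snp{j}" for j in range(n_snps)),
        individual_ids=tuple(f"ind{i:03d}" for i in range(n_rows // 2)),
        chrom=chrom,
    )


def random_haps(rng, n_individuals=10, n_snps=20, p=0.3):
    """A random (not genealogy-structured) polymorphic haplotype matrix."""
    while True:
        entries = (rng.random((2 * n_individuals, n_snps)) < p).astype(np.uint8)
        counts = entries.sum(axis=0)
        if np.all((counts > 0) & (counts < 2 * n_individuals)):
            return make_haps(entries)


@pytest.fixture
def small_config():
    return SimulationConfig(seed=11, n_individuals=30, n_blocks=2, theta=1.5, block_span_bp=10_000)


@pytest.fixture
def small_gene(small_config):
    return recode_minor(filter_monomorphic(simulate_haplotypes(small_config)))
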