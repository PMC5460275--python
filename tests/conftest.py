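import numpy as np
import pytest

from palmgs.containers import GenotypeMatrix
from palmgs.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_pop():
    """A compact half-sib population with a polygenic trait (n=240, m=300)."""
    cfg = SimConfig(
        n_founders=14,
        n_families=12,
        progeny_per_family=20,
        n_chromosomes=3,
        markers_per_chromosome=100,
        n_qtl=60,
        qtl_effect_distribution="gaussian",
        target_h2=0.6,
        seed=42,
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def oligo_pop():
    """An oligogenic population: 6 QTL with geometric-series effects, h2 0.7."""
    cfg = SimConfig(
        n_founders=14,
        n_families=12,
        progeny_per_family=25,
        n_chromosomes=3,
        markers_per_chromosome=120,
        n_qtl=6,
        qtl_effect_distribution="geometric-series",
        target_h2=0.7,
        seed=5,
    )
    return simulate_population(cfg)


def unrelated_genotypes(n, m, seed, maf=(0.1, 0.5)):
    """Unstructured genotypes: independent individuals, independent loci."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*maf, size=m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return GenotypeMatrix(
        dosages=dos,
        marker_ids=np.array([f"m{j}" for j in range(m)], dtype=object),
        chrom=np.ones(m, dtype=int),
        pos_cm=np.arange(m, dtype=float),
        individual_ids=np.array([f"i{i}" for i in range(n)], dtype=object),
    )
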