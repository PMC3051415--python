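import numpy as np
import pytest

from ancestrykit.informativeness import AlleleFrequencyTable
from ancestrykit.io import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_genotypes():
    """2 individuals x 3 loci with one missing cell."""
    return GenotypeMatrix(
        individual_ids=["i1", "i2"],
        locus_ids=["rs1", "rs2", "rs3"],
        dosages=np.array([[0, 1, 2], [2, MISSING, 0]]),
        labels=["a", "b"],
        region=["north", "south"],
        sex=["M", "F"],
    )


@pytest.fixture
def random_freq_table(rng):
    def make(K=4, L=24, seed=None):
        r = np.random.default_rng(seed) if seed is not None else rng
        return AlleleFrequencyTable(
            population_ids=[f"pop{i}" for i in range(K)],
            locus_ids=[f"rs{j}" for j in range(L)],
            freq=r.uniform(0.02, 0.98, size=(K, L)),
        )

    return make


def two_pop_fixed_panel(L=24, n_per_pop=20):
    """Parental panel with opposite fixed alleles: maximally diverged."""
    dosA = np.full((n_per_pop, L), 2)
    dosB = np.zeros((n_per_pop, L), dtype=int)
    return GenotypeMatrix(
        [f"A{i}" for i in range(n_per_pop)] + [f"B{i}" for i in range(n_per_pop)],
        [f"rs{j}" for j in range(L)],
        np.vstack([dosA, dosB]),
        labels=["A"] * n_per_pop + ["B"] * n_per_pop,
    )
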