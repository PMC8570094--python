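import numpy as np
import pytest
import scipy.sparse as sp

from seqpick.haplib import IncidenceMatrix
from seqpick.simulator import SimConfig, genome_overrides, simulate_population


def make_incidence(A: np.ndarray, h: np.ndarray | None = None) -> IncidenceMatrix:
    """Wrap a dense 0/1 array (and optional frequencies) as an IncidenceMatrix."""
    A = np.asarray(A)
    p, n = A.shape
    if h is None:
        h = A.sum(axis=1) / (2 * n)
    return IncidenceMatrix(
        A=sp.csr_matrix(A),
        h=np.asarray(h, dtype=float),
        animal_ids=np.arange(n),
        haplotype_ids=np.arange(p),
    )


def random_instance(rng: np.random.Generator, n_max_animals: int = 15, p_max: int = 30):
    """A random small incidence matrix with no zero rows, for oracle checks."""
    n = int(rng.integers(4, n_max_animals + 1))
    p = int(rng.integers(5, p_max + 1))
    A = (rng.random((p, n)) < rng.uniform(0.15, 0.5)).astype(np.int8)
    empty = A.sum(axis=1) == 0
    if empty.any():
        A[empty, rng.integers(0, n, size=int(empty.sum()))] = 1
    h = rng.uniform(0.01, 0.5, size=p)
    return make_incidence(A, h)


@pytest.fixture
def small_config():
    return SimConfig(
        n_founders=40,
        n_generations=3,
        n_sires=3,
        n_dams=10,
        offspring_per_gen=20,
        n_chromosomes=2,
        snps_per_chromosome=50,
        n_qtl=10,
        founder_pool_size=6,
        seed=11,
    )


@pytest.fixture
def small_pop(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def scenario1_pipeline():
    """One scenario-1 population at the reduced 2,000-SNP genome, with its
    library and incidence matrices; shared across the slower tests."""
    from seqpick.haplib import build_incidence, build_library, filter_common
    from seqpick.simulator import simulate_scenario

    pop = simulate_scenario(1, seed=20260930, **genome_overrides(200))
    library = build_library(pop)
    M_all = build_incidence(pop, library)
    M_common = filter_common(M_all, 0.01)
    return pop, library, M_all, M_common
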