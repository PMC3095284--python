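import numpy as np
import pytest

from corekit import GenotypeMatrix, GroupAssignment, SimulationConfig, simulate_structured_population


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 accessions x 2 loci, hand-enumerable."""
    calls = np.array(
        [
            [[1, 2], [10, 10]],
            [[2, 3], [10, 11]],
            [[4, 4], [11, 11]],
        ]
    )
    return GenotypeMatrix(["a1", "a2", "a3"], ["LOC1", "LOC2"], calls)


@pytest.fixture
def grouped_matrix() -> tuple[GenotypeMatrix, GroupAssignment]:
    """Two groups of homozygotes fixed for different alleles."""
    calls = np.array(
        [
            [[1, 1], [5, 5]],
            [[1, 1], [5, 5]],
            [[1, 1], [5, 5]],
            [[2, 2], [6, 6]],
            [[2, 2], [6, 6]],
            [[2, 2], [6, 6]],
        ]
    )
    ids = [f"x{i}" for i in range(6)]
    G = GenotypeMatrix(ids, ["L1", "L2"], calls)
    groups = GroupAssignment({ids[i]: ("A" if i < 3 else "B") for i in range(6)})
    return G, groups


@pytest.fixture(scope="session")
def rice_panel():
    """One synthetic rice-like collection shared across tests (session
    scope: the generator is deterministic for a fixed config)."""
    cfg = SimulationConfig(seed=20260901)
    G, groups = simulate_structured_population(cfg)
    return G, groups, cfg


def random_genotypes(rng: np.random.Generator, n: int, L: int, max_allele: int = 4,
                     missing_rate: float = 0.0) -> GenotypeMatrix:
    """Small random diploid matrix for property tests."""
    calls = rng.integers(1, max_allele + 1, size=(n, L, 2)).astype(np.int32)
    if missing_rate > 0:
        mask = rng.random((n, L)) < missing_rate
        for l in range(L):
            if mask[:, l].all():
                mask[rng.integers(n), l] = False
        calls[mask] = -9
    return GenotypeMatrix([f"s{i}" for i in range(n)], [f"L{j}" for j in range(L)], calls)
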