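import numpy as np
import pytest

from landgen.io_formats import (MISSING, GenotypeTable, PairwiseMatrix,
                                PointSet, RasterSurface)


def make_gt(pop_calls: dict[str, list[list[tuple[int, int]]]],
            loci: list[str] | None = None) -> GenotypeTable:
    """Build a GenotypeTable from {pop: [per-individual list of (a, b)]}."""
    individuals, populations, calls = [], [], []
    n_loci = len(next(iter(pop_calls.values()))[0])
    loci = loci or [f"L{i + 1}" for i in range(n_loci)]
    for pop, rows in pop_calls.items():
        for i, row in enumerate(rows):
            individuals.append(f"{pop}_{i + 1}")
            populations.append(pop)
            calls.append([list(pair) for pair in row])
    return GenotypeTable(individuals, populations, loci, np.array(calls))


@pytest.fixture
def two_pop_toy() -> GenotypeTable:
    """pop1: 5x AA + 5x Aa, pop2: 2x Aa + 8x aa at a single locus (A=1, a=2)."""
    return make_gt({
        "pop1": [[(1, 1)]] * 5 + [[(1, 2)]] * 5,
        "pop2": [[(1, 2)]] * 2 + [[(2, 2)]] * 8,
    })


@pytest.fixture
def fixed_demes() -> GenotypeTable:
    """Two demes fixed for different alleles at 10 loci (fully separable)."""
    return make_gt({
        "demeA": [[(10, 10)] * 10] * 12,
        "demeB": [[(20, 20)] * 10] * 12,
    })


def random_pairwise(rng: np.random.Generator, labels) -> PairwiseMatrix:
    n = len(labels)
    M = rng.random((n, n))
    M = 0.5 * (M + M.T)
    np.fill_diagonal(M, 0.0)
    return PairwiseMatrix(list(labels), M)


@pytest.fixture
def labels12():
    return [f"p{i:02d}" for i in range(12)]
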