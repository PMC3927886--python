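import numpy as np
import pytest

from coastibd.genotypes import GenotypeMatrix


def make_matrix(pop_calls: dict[str, list[list[tuple[int, int]]]],
                loci: list[str] | None = None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {pop: [per-individual [(a,b) per locus]]}."""
    ids, pops, calls = [], [], []
    for pop, inds in pop_calls.items():
        for k, geno in enumerate(inds):
            ids.append(f"{pop}_{k}")
            pops.append(pop)
            calls.append(geno)
    n_loci = len(calls[0])
    loci = loci or [f"L{i+1}" for i in range(n_loci)]
    return GenotypeMatrix(ids, pops, loci, np.array(calls, dtype=np.int64))


@pytest.fixture
def fixed_difference_matrix() -> GenotypeMatrix:
    """Two populations fixed for different alleles at one locus."""
    return make_matrix({
        "A": [[(1, 1)]] * 20,
        "B": [[(2, 2)]] * 20,
    })


@pytest.fixture
def random_two_pop_matrix() -> GenotypeMatrix:
    """Two populations drawn from one panmictic allele pool (null case)."""
    rng = np.random.default_rng(42)
    p = np.array([0.4, 0.3, 0.2, 0.1])

    def draw(n):
        return [
            [tuple(rng.choice(4, size=2, p=p) + 1) for _ in range(3)]
            for _ in range(n)
        ]

    return make_matrix({"A": draw(25), "B": draw(25)})
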