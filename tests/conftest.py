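import numpy as np
import pytest

from guavapop.genotypes import MISSING, GenotypeMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_matrix():
    """Hand-written 6-individual, 3-locus, 2-population matrix."""
    alleles = np.array([
        # L1        L2        L3
        [[1, 2], [5, 5], [9, 9]],
        [[1, 1], [5, 6], [9, 8]],
        [[2, 2], [6, 6], [8, 8]],
        [[3, 3], [5, 5], [9, 9]],
        [[1, 3], [6, 6], [8, 9]],
        [[3, 3], [5, 6], [9, 9]],
    ], dtype=np.int64)
    return GenotypeMatrix(
        individuals=[f"i{k}" for k in range(6)],
        loci=["L1", "L2", "L3"],
        alleles=alleles,
        pop=np.asarray(["A", "A", "A", "B", "B", "B"], dtype=object),
    )


@pytest.fixture
def toy_with_missing(toy_matrix):
    alleles = toy_matrix.alleles.copy()
    alleles[1, 0] = MISSING
    alleles[4, 2] = MISSING
    return GenotypeMatrix(individuals=list(toy_matrix.individuals),
                          loci=list(toy_matrix.loci), alleles=alleles,
                          pop=toy_matrix.pop.copy())


def hwe_population(rng, freqs, n, pops=("P",), loci=2):
    """Random-mating population(s) drawn from given allele frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    k = freqs.size
    n_tot = n * len(pops)
    alleles = rng.choice(np.arange(1, k + 1), size=(n_tot, loci, 2), p=freqs)
    pop = np.repeat(list(pops), n)
    return GenotypeMatrix(individuals=[f"x{j}" for j in range(n_tot)],
                          loci=[f"L{j}" for j in range(loci)],
                          alleles=alleles, pop=pop.astype(object))
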