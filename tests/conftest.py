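import numpy as np
import pytest

from ovimp.containers import GenotypeMatrix
from ovimp.popsim import BreedModel, MatingDesign, make_snp_map, simulate_population


@pytest.fixture(scope="session")
def small_population():
    """One-breed population with family structure: 60 founders + 120 progeny
    on a single 60-marker chromosome. Shared across read-only tests."""
    snp_map = make_snp_map(1, 60, 100.0, 4)
    breed_model = BreedModel(["Merino"], fst=0.0)
    design = MatingDesign(
        n_founder_sires={"Merino": 12},
        n_founder_dams={"Merino": 48},
        purebred_progeny={"Merino": 120},
        n_flocks=3,
    )
    genotypes, haplotypes, records = simulate_population(breed_model, snp_map, design, 11)
    return snp_map, genotypes, haplotypes, records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_genotypes(rng, n, m, ids_prefix="s"):
    vals = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    return GenotypeMatrix(
        [f"{ids_prefix}{i}" for i in range(n)],
        np.array([f"snp{j}" for j in range(m)]),
        vals,
    )
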