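import numpy as np
import pytest

from shannonhet import (
    LocusGenotypeTable,
    PopulationProfile,
    VariantProfile,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def two_individual_population():
    """One individual fixed on A, one split A/B: H_I = 0 and ln 2."""
    return PopulationProfile(
        [
            VariantProfile("i1", {"A": 4}),
            VariantProfile("i2", {"A": 2, "B": 2}),
        ]
    )


@pytest.fixture
def hw_table(rng):
    """24 individuals x 3 loci drawn under Hardy-Weinberg equilibrium."""
    freqs = np.array([0.4, 0.3, 0.2, 0.1])
    alleles = np.empty((24, 3, 2), dtype=object)
    for j in range(3):
        draws = rng.choice(4, size=(24, 2), p=freqs)
        for i in range(24):
            alleles[i, j, :] = [f"A{a}" for a in draws[i]]
    return LocusGenotypeTable(
        tuple(f"i{k}" for k in range(24)),
        ("L1", "L2", "L3"),
        alleles,
    )


@pytest.fixture
def locus_fixation_table():
    """Every individual C1C1;C2C2;C3C3;C4C4 - each locus fixed for its own
    variant, the pattern that makes F_IS undefined but the Shannon statistic
    read maximal diversity."""
    alleles = np.array(
        [[[f"C{j + 1}", f"C{j + 1}"] for j in range(4)] for _ in range(10)],
        dtype=object,
    )
    return LocusGenotypeTable(
        tuple(f"i{k}" for k in range(10)),
        ("L1", "L2", "L3", "L4"),
        alleles,
    )


def random_population(rng, n_ind=6, n_var=5, max_count=20):
    """Random variant profiles for property tests."""
    profiles = []
    for i in range(n_ind):
        counts = {}
        while not counts:
            raw = rng.integers(0, max_count, size=n_var)
            counts = {f"v{k}": int(c) for k, c in enumerate(raw) if c > 0}
        profiles.append(VariantProfile(f"i{i}", counts))
    return PopulationProfile(profiles)
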