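import numpy as np
import pytest

from twinhap import (
    FrequencyTable,
    Genotype,
    GenotypeProfile,
    PlasmaLocusCounts,
    SimScenario,
    simulate_case,
    simulate_frequencies,
)


@pytest.fixture
def small_freqs():
    """Two handmade loci with frequencies summing to 1."""
    return FrequencyTable(
        {
            "L1": {"A": 0.4, "B": 0.3, "C": 0.2, "D": 0.1},
            "L2": {"A": 0.5, "B": 0.5},
        }
    )


@pytest.fixture
def mother_ab():
    return Genotype("L1", ("A", "B"))


@pytest.fixture
def panel_freqs():
    return simulate_frequencies(60, (4, 8), seed=11)


@pytest.fixture
def dz_case(panel_freqs):
    """A noise-free dizygotic case fathered by the AF, FFs 5% and 8%."""
    scenario = SimScenario(
        zygosity="DZ",
        paternity="AF_BOTH",
        ff_twin1=0.05,
        ff_twin2=0.08,
        mean_depth=5000,
        depth_dispersion=0.0,
        seed=42,
    )
    truth, plasma = simulate_case(panel_freqs, scenario)
    return truth, plasma


@pytest.fixture
def mz_case(panel_freqs):
    scenario = SimScenario(
        zygosity="MZ",
        paternity="AF_BOTH",
        ff_twin1=0.12,
        mean_depth=5000,
        depth_dispersion=0.0,
        seed=43,
    )
    truth, plasma = simulate_case(panel_freqs, scenario)
    return truth, plasma


def make_counts(locus_id, depth_map):
    return PlasmaLocusCounts(locus_id, depth_map)


def profile_from(sample_id, genotypes):
    profile = GenotypeProfile(sample_id)
    for locus_id, pair in genotypes.items():
        profile.add(Genotype(locus_id, pair))
    return profile


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
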