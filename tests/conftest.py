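import numpy as np
import pytest

from gak.report import analyze_genome
from gak.simulate import SimulationConfig, simulate_assembly


@pytest.fixture(scope="session")
def default_sim():
    """One synthetic assembly under the default study conditions."""
    return simulate_assembly(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_analysis(default_sim):
    """Full pipeline output on the default synthetic assembly."""
    return analyze_genome(default_sim.records, default_sim.genes,
                          default_sim.labels, name="synthetic")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_dna(rng, n, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=n))
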