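import numpy as np
import pytest

from protoscan import SimulationConfig, simulate_scenario
from protoscan.genome import Feature, GenomeRecord


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def scenario(default_config):
    """One fully simulated synthetic study, shared across tests."""
    return simulate_scenario(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture()
def toy_genome() -> GenomeRecord:
    """A 2-kb genome with two genes, an RNA gene and a repeat."""
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    feats = [
        Feature("geneA", 100, 500, "+", "gene"),
        Feature("geneB", 700, 1100, "-", "gene"),
        Feature("rnaC", 1200, 1300, "+", "rna"),
        Feature("repD", 1500, 1600, "-", "repeat"),
    ]
    return GenomeRecord(name="toy", sequence=seq, features=feats)
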