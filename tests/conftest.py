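import numpy as np
import pytest

from milkgene.model import Locus
from milkgene.popgen import GenotypeCounts
from milkgene.simulate import SimulationConfig, simulate_herd

# Observed genotype counts of a published three-SNP Holstein dataset
# (major-homozygote, heterozygote, minor-homozygote), used as a fixed
# real-data fixture for the descriptive-genetics stage.
TABLE1_COUNTS = {
    "c.908": GenotypeCounts("c.908", 295, 407, 139),
    "c.1571": GenotypeCounts("c.1571", 678, 146, 17),
    "c.2776": GenotypeCounts("c.2776", 562, 253, 26),
}


@pytest.fixture(scope="session")
def table1_counts():
    return TABLE1_COUNTS


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced herd that still exercises every factor of the model."""
    return SimulationConfig(
        n_cows=120, n_sires=24, daughters_min=2, daughters_max=10,
        max_parity=3, tests_per_lactation=6, seed=11,
    )


@pytest.fixture(scope="session")
def small_herd(small_sim_config):
    return simulate_herd(small_sim_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def demo_loci():
    return [
        Locus("c.908", "C", "T", dbsnp_id="rs211580559"),
        Locus("c.1571", "G", "A", dbsnp_id="rs210169303"),
        Locus("c.2776", "A", "G", dbsnp_id="rs207932003"),
    ]
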