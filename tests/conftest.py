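import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nglyc.records import ProteinRecord
from nglyc.simulate import SimulationConfig, generate_secretome

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=11, n_proteins=30, length_range=(100, 300))


@pytest.fixture(scope="session")
def small_secretome(small_config):
    return generate_secretome(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_protein(rng, length=200, pid="P1") -> ProteinRecord:
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
    return ProteinRecord(id=pid, sequence=seq)
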