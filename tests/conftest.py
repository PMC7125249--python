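import pytest
from hypothesis import HealthCheck, settings

from pmvlogp import (
    Phase,
    SyntheticSpec,
    TrainingDataset,
    generate_dataset,
    load_builtin_fixture,
)

settings.register_profile(
    "package",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("package")


@pytest.fixture(scope="session")
def table2():
    return load_builtin_fixture("table2_logp")


@pytest.fixture(scope="session")
def table4():
    return load_builtin_fixture("table4_relative_energies")


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small noise-free synthetic dataset with known true parameters."""
    return generate_dataset(SyntheticSpec(n_molecules=25, sigma=0.0, seed=11))


@pytest.fixture(scope="session")
def noiseless_training(noiseless_dataset):
    return TrainingDataset(
        noiseless_dataset.all_states(),
        list(noiseless_dataset.experiments),
        Phase.octanol_wet,
    )
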