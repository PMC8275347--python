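import pytest

from epmix import SyntheticSpec, prepare_experiment, simulate_two_samples


@pytest.fixture(scope="session")
def small_dataset():
    """Two synthetic samples over 40 fully divergent pairs."""
    return simulate_two_samples(SyntheticSpec(n_pairs=40, seed=7))


@pytest.fixture(scope="session")
def small_experiment(small_dataset):
    d = small_dataset
    return prepare_experiment(d.molecules_A, d.molecules_B, d.regions, seed=7)
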