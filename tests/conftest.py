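import numpy as np
import pytest

from neurocult import ExperimentDesign, ThresholdSpec, generate_experiment


@pytest.fixture(scope="session")
def default_spec() -> ThresholdSpec:
    return ThresholdSpec()


@pytest.fixture(scope="session")
def tiny_design() -> ExperimentDesign:
    """2 densities × 2 conditions × 2 biological × 5 technical = 40 wells."""
    return ExperimentDesign(densities=(1000.0, 50000.0))


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_design):
    """A 40-well viability-only dataset on disk, shared across tests."""
    root = tmp_path_factory.mktemp("dataset")
    truth = generate_experiment(
        root, tiny_design, stages=("viability",), seed=11
    )
    return root, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
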