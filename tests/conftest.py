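import numpy as np
import pytest

from aquasorb import (
    ModelSpec,
    SimulationDesign,
    default_initial_parameters,
    fit,
    generate,
)


@pytest.fixture(scope="session")
def dlp_spec():
    return ModelSpec("dlp", generalized=True)


@pytest.fixture(scope="session")
def dlp_truth(dlp_spec):
    return default_initial_parameters(dlp_spec)


@pytest.fixture(scope="session")
def dlp_design(dlp_spec, dlp_truth):
    """Default DDI-style design: 3 reps x {25,35,45} degC x 76 a_w points."""
    return SimulationDesign(spec=dlp_spec, true_parameters=dlp_truth, seed=7)


@pytest.fixture(scope="session")
def dlp_dataset(dlp_design):
    return generate(dlp_design)


@pytest.fixture(scope="session")
def dlp_fit(dlp_dataset, dlp_spec):
    return fit(dlp_dataset, dlp_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250924)
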