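import numpy as np
import pytest

from dissopt import (
    FormulationDataset,
    ReleaseModelParams,
    generate_study,
    study_design_fixture,
)


@pytest.fixture(scope="session")
def design():
    return study_design_fixture()


@pytest.fixture(scope="session")
def study() -> FormulationDataset:
    """The synthetic 30-run corpus at the default calibration, seed 0."""
    return generate_study(ReleaseModelParams(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
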