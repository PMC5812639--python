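import numpy as np
import pytest

from irrevkin import (
    PUTAMEN,
    NoiseModel,
    default_study_inputs,
    frame_noise_sd,
    model_weights,
    simulate_tac,
)


@pytest.fixture(scope="session")
def study():
    """Default synthetic study inputs (Ca, Cb, 22-frame schedule)."""
    return default_study_inputs()


@pytest.fixture(scope="session")
def ca(study):
    return study[0]


@pytest.fixture(scope="session")
def cb(study):
    return study[1]


@pytest.fixture(scope="session")
def schedule(study):
    return study[2]


@pytest.fixture(scope="session")
def putamen_tac(study):
    ca, cb, schedule = study
    return simulate_tac(PUTAMEN, ca, cb, schedule)


@pytest.fixture(scope="session")
def voxel_noise_weights(putamen_tac):
    """Inverse-variance weights at voxel-level noise (weights are invariant
    to the sf scale, so any sf > 0 gives the same vector)."""
    sd = frame_noise_sd(NoiseModel(sf=120), putamen_tac)
    return model_weights(sd)


@pytest.fixture(scope="session")
def noisy_replicates(putamen_tac):
    """A reusable bank of noisy putamen TAC replicates at voxel noise."""
    sd = frame_noise_sd(NoiseModel(sf=120), putamen_tac)
    rng = np.random.default_rng(2024)
    return putamen_tac.values[None, :] + sd[None, :] * rng.standard_normal((50, sd.size))
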