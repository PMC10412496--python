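import numpy as np
import pytest

from gaitbouts import EnhancementParams, SimConfig, simulate_recording


@pytest.fixture(scope="session")
def eparams():
    return EnhancementParams()


@pytest.fixture(scope="session")
def default_scenario():
    """The default simulated scenario (seed 7): 3 bouts, artifacts, 120 s."""
    rec, truth = simulate_recording(SimConfig(seed=7))
    return rec, truth


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix, independent of the package's own."""
    from scipy.spatial.transform import Rotation

    quat = rng.normal(size=4)
    return Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
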