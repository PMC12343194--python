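import numpy as np
import pytest

from confkin.model import build_model_from_static, default_static_pose
from confkin.synth import default_cameras


@pytest.fixture(scope="session")
def static_pose():
    return default_static_pose()


@pytest.fixture(scope="session")
def body(static_pose):
    """Full-body model calibrated on the default static pose."""
    return build_model_from_static(static_pose)


@pytest.fixture(scope="session")
def rig():
    return default_cameras()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """Short noiseless scene shared by solver/evaluation tests."""
    from confkin.synth import SceneConfig, generate_scene

    return generate_scene(SceneConfig(duration=0.2, seed=42))


@pytest.fixture(scope="session")
def small_scene_solutions(small_scene):
    from confkin.solver import solve_sequence

    return solve_sequence(small_scene.confidence_specs(), small_scene.model)


def random_rotation(rng):
    """Uniform-ish random rotation via QR of a Gaussian matrix."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q
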