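import numpy as np
import pytest

from vesseltort.curves import CurveSpec, make_curve
from vesseltort.meshing import make_tube_mesh


@pytest.fixture(scope="session")
def helix_curve():
    """Full turn of the reference helix a=3, b=4 (kappa=0.12, tau=0.16)."""
    curve, truth = make_curve(CurveSpec("helix", a=3, b=4, turns=1, n_points=200))
    return curve, truth


@pytest.fixture(scope="session")
def cylinder_mesh():
    """Straight tube of radius 2 along the z-axis, 50 mm long."""
    line, _ = make_curve(CurveSpec("line", a=50, n_points=101))
    return make_tube_mesh(line, 2.0, 16)


@pytest.fixture(scope="session")
def torus_mesh():
    """Half-torus tube: arc radius 10, tube radius 2."""
    arc, truth = make_curve(CurveSpec("arc", a=10, arc_angle=np.pi, n_points=200))
    return make_tube_mesh(arc, 2.0, 24), arc, truth


def random_rigid_motion(seed):
    """Uniformly random rotation matrix + translation."""
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.normal(scale=10.0, size=3)
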