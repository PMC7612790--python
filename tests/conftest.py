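"""Shared fixtures.

Expensive objects (meshes, synthetic cases, fitted results) are
session-scoped and shared across test modules; all sizes are desk-scale.
"""

import warnings

import numpy as np
import pytest

from cardio_unload.materials import default_params
from cardio_unload.mesh import EllipsoidSpec, generate_lv_ellipsoid, \
    generate_sphere_shell
from cardio_unload.mff import run_mff
from cardio_unload.solver import SolverConfig
from cardio_unload.synth import generate_synthetic_case, soft_stress_case

warnings.filterwarnings("ignore", message="overflow encountered")
warnings.filterwarnings("ignore", message="invalid value encountered")


@pytest.fixture(scope="session")
def lv_mesh_coarse():
    """Idealized LV, ~2.3k tets (Kuhn split)."""
    return generate_lv_ellipsoid(EllipsoidSpec(resolution=10.0))


@pytest.fixture(scope="session")
def lv_mesh_tiny():
    """Smallest sensible LV for logic/smoke tests (~1.4k tets)."""
    return generate_lv_ellipsoid(EllipsoidSpec(resolution=12.0))


@pytest.fixture(scope="session")
def sphere_mesh():
    """Thick-walled spherical shell, crossed split, ~6.5k tets."""
    return generate_sphere_shell(10.0, 15.0, 5.0)


@pytest.fixture(scope="session")
def case_mid():
    """Synthetic patient of the main self-consistency study:
    reduced-HO defaults scaled by (0.35, 0.60), p_ed = 1.07 kPa,
    ~3.3k tets, 30 loading steps."""
    return generate_synthetic_case(
        EllipsoidSpec(resolution=8.0), "reduced_HO",
        true_scalings=(0.35, 0.60), p_ed=1.07,
        solver_config=SolverConfig(n_ls=30))


@pytest.fixture(scope="session")
def mff_mid(case_mid):
    """MFF fit of the main synthetic case (shared across tests)."""
    cfg = SolverConfig(n_ls=30, newton_max_iter=2)
    return run_mff(case_mid.x_dat, case_mid.p_ed, case_mid.V_ed,
                   default_params("reduced_HO"), solver_config=cfg,
                   target=case_mid.truth_pv, max_iter=20)


@pytest.fixture(scope="session")
def case_small():
    """Scaled-down twin of the main case (~1.4k tets, 20 loading steps)."""
    return generate_synthetic_case(
        EllipsoidSpec(resolution=12.0), "reduced_HO",
        true_scalings=(0.35, 0.60), p_ed=1.07,
        solver_config=SolverConfig(n_ls=20))


@pytest.fixture(scope="session")
def mff_small(case_small):
    cfg = SolverConfig(n_ls=20, newton_max_iter=2)
    return run_mff(case_small.x_dat, case_small.p_ed, case_small.V_ed,
                   default_params("reduced_HO"), solver_config=cfg,
                   target=case_small.truth_pv, max_iter=20)


@pytest.fixture(scope="session")
def stress_case():
    """Packaged soft-material stress case (non-contractive fixed point)."""
    return soft_stress_case()


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_deformations(rng, n, scale=0.12):
    """Random well-posed deformation gradients with J > 0."""
    F = np.eye(3) + scale * rng.standard_normal((n, 3, 3))
    dets = np.linalg.det(F)
    F[dets <= 0.05] = np.eye(3) + 0.02 * rng.standard_normal((3, 3))
    return F


def random_frames(rng, n):
    """Random orthonormal fiber/sheet/normal frames."""
    a = rng.standard_normal((n, 3))
    a /= np.linalg.norm(a, axis=1, keepdims=True)
    b = rng.standard_normal((n, 3))
    b -= np.einsum("ij,ij->i", a, b)[:, None] * a
    b /= np.linalg.norm(b, axis=1, keepdims=True)
    return a, b, np.cross(a, b)
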