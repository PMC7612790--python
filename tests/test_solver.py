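"""Finite-element inflation: consistency, convergence and invariants."""

import numpy as np
import pytest

from cardio_unload.materials import Kinematics, default_params, strain_energy
from cardio_unload.mesh import generate_sphere_shell
from cardio_unload.solver import (Assembler, PVCurve, SolverConfig, inflate,
                                  newton_step)


@pytest.fixture(scope="module")
def small_sphere():
    return generate_sphere_shell(8.0, 11.0, 4.0, split="kuhn")


def total_potential(asm, u, p):
    """Independent energy functional whose gradient is the residual."""
    mesh = asm.mesh
    ue = u[mesh.tets]
    F = np.eye(3) + np.einsum("eai,eaj->eij", ue, asm.grads)
    kin = Kinematics.from_F(F, mesh.f0, mesh.s0, mesh.n0)
    e_int = float(np.sum(asm.vols * strain_energy(asm.params, kin)))
    e_spring = 0.5 * float(np.sum(asm.spring_w[:, None] * u * u))
    x = (mesh.nodes + u)[mesh.surfaces["endocardium"]]
    # enclosed volume of the closed surface (normals point into the cavity)
    vol = -np.einsum("fi,fi->f", x[:, 0],
                     np.cross(x[:, 1], x[:, 2])).sum() / 6.0
    return e_int + e_spring - p * vol


def test_residual_is_gradient_of_potential(small_sphere, rng):
    """Internal + spring + follower-pressure residual matches central FD of
    the total potential on a closed shell to 1e-5 relative."""
    cfg = SolverConfig(n_ls=5, spring_stiffness_base=0.0,
                       spring_stiffness_apex=0.3)
    m = small_sphere.copy()
    m.surfaces["apex_patch"] = m.surfaces["epicardium"]
    asm = Assembler(m, default_params("demiray"), cfg)
    u = 0.02 * rng.standard_normal((m.node_count, 3))
    p = 0.4
    r = asm.residual(u, p)
    h = 1e-6
    for _ in range(4):
        d = rng.standard_normal((m.node_count, 3))
        d /= np.linalg.norm(d)
        fd = (total_potential(asm, u + h * d, p)
              - total_potential(asm, u - h * d, p)) / (2 * h)
        assert float(r @ d.ravel()) == pytest.approx(fd, rel=1e-5)


def test_newton_zero_load_zero_state(small_sphere):
    cfg = SolverConfig(n_ls=5, spring_stiffness_apex=0.2)
    m = small_sphere.copy()
    m.surfaces["apex_patch"] = m.surfaces["epicardium"]
    asm = Assembler(m, default_params("demiray"), cfg)
    u = np.zeros((m.node_count, 3))
    assert np.linalg.norm(asm.residual(u, 0.0)) == 0.0
    _, rn = newton_step(asm, u, 0.0)
    assert rn == 0.0


def test_full_newton_converges_quadratically(small_sphere):
    """Residual reduction accelerates as the iteration proceeds (consistent
    tangent) and reaches a tight tolerance in few steps."""
    m = small_sphere.copy()
    m.surfaces["apex_patch"] = m.surfaces["epicardium"]
    cfg = SolverConfig(n_ls=1, newton_max_iter=12, newton_rel_tol=1e-14,
                       spring_stiffness_base=0.0, spring_stiffness_apex=0.3)
    res = inflate(m, default_params("demiray"), cfg, 0.05)
    hist = np.array(res.newton_history[0])
    below = np.nonzero(hist < 1e-9 * hist[0])[0]
    assert below.size, "residual never reached 1e-9 of its initial value"
    k = int(below[0])                 # first arrival at the round-off floor
    assert k <= 6
    assert hist[k] / hist[k - 1] < 1e-3


def test_zero_pressure_identity(lv_mesh_tiny):
    cfg = SolverConfig(n_ls=5)
    res = inflate(lv_mesh_tiny, default_params("reduced_HO"), cfg, 0.0)
    assert np.array_equal(res.deformed_coords, lv_mesh_tiny.nodes)
    assert len(res.pv_curve.volumes) == 1


def test_pv_monotone_and_deterministic(lv_mesh_tiny):
    cfg = SolverConfig(n_ls=20)
    params = default_params("reduced_HO").scaled(0.35, 0.6)
    a = inflate(lv_mesh_tiny, params, cfg, 0.8)
    assert np.all(np.diff(a.pv_curve.volumes) > 0)
    b = inflate(lv_mesh_tiny, params, cfg, 0.8)
    assert np.array_equal(a.pv_curve.volumes, b.pv_curve.volumes)
    assert np.array_equal(a.deformed_coords, b.deformed_coords)
    assert len(a.pv_curve.pressures) == 21
    assert a.pv_curve.pressures[0] == 0.0


def test_stiffer_material_inflates_less(lv_mesh_tiny):
    cfg = SolverConfig(n_ls=6)
    soft = inflate(lv_mesh_tiny, default_params("reduced_HO"), cfg, 0.8)
    stiff = inflate(lv_mesh_tiny,
                    default_params("reduced_HO").scaled(2.0, 1.0), cfg, 0.8)
    assert stiff.pv_curve.volumes[-1] < soft.pv_curve.volumes[-1]


def test_near_incompressibility_at_default_penalty(lv_mesh_tiny):
    """kappa = 650 kPa keeps elementwise |J - 1| below 0.1 at p_ed."""
    cfg = SolverConfig(n_ls=20)
    res = inflate(lv_mesh_tiny, default_params("reduced_HO").scaled(0.35, 0.6),
                  cfg, 1.07)
    u = res.displacements
    ue = u[lv_mesh_tiny.tets]
    grads, _ = lv_mesh_tiny.shape_gradients()
    F = np.eye(3) + np.einsum("eai,eaj->eij", ue, grads)
    J = np.linalg.det(F)
    assert np.max(np.abs(J - 1.0)) < 0.1


def test_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(n_ls=0)
    with pytest.raises(ValueError):
        SolverConfig(newton_rel_tol=2.0)
    with pytest.raises(ValueError):
        SolverConfig(spring_stiffness_base=-1.0)
    with pytest.raises(ValueError):
        PVCurve(np.array([0.0, 0.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        inflate(None, None, SolverConfig(n_ls=2), -1.0)
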