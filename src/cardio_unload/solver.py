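"""Quasi-static total-Lagrangian passive inflation of a ventricular mesh.

Formulation: displacement-based linear tetrahedra with the volumetric
penalty evaluated at the element-constant deformation gradient (the "P1-P0"
element in the penalty sense).  The endocardial pressure acts as a follower
load on the deformed surface; its nonsymmetric load stiffness is included
in the tangent.  Spring-like (Robin) boundary conditions act on the basal
rim surface and an apical epicardial patch, resisting displacement with an
area-lumped linear stiffness.  Pressure is ramped in ``n_ls`` equidistant
steps from 0 to the target, with a capped Newton iteration per step and
step-halving recovery on element inversion.

Element stiffness blocks are obtained by directed central finite
differences of the analytic element internal force (built on the analytic
second Piola-Kirchhoff stress), which keeps the tangent consistent for all
constitutive laws; linear systems use a sparse direct factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import (InvertedElementError, Kinematics, MaterialParams,
                        material_tangent, pk2_stress)
from .mesh import Mesh, cavity_volume

__all__ = ["SolverConfig", "PVCurve", "ForwardResult", "Assembler",
           "inflate", "newton_step", "SolverError"]


class SolverError(RuntimeError):
    """Forward solve failed (nonconvergence, inversion or singular system)."""


@dataclass(frozen=True)
class SolverConfig:
    """Settings of the passive-inflation forward solver.

    ``newton_max_iter = 2`` reproduces the capped Newton used while
    estimating the unloaded configuration; validation runs use a fully
    converging Newton (larger cap, relative residual reduction
    ``newton_rel_tol``).  Spring stiffnesses are in kPa/mm.
    """

    n_ls: int = 100
    newton_max_iter: int = 2
    newton_rel_tol: float = 1e-6
    linear_rel_tol: float = 1e-8
    spring_stiffness_base: float = 1.0
    spring_stiffness_apex: float = 0.1
    max_halvings: int = 3
    fd_step: float = 1e-6          # relative step for element-stiffness FD
    linear_solver: str = "ilu_gmres"   # or "direct"

    def __post_init__(self):
        if self.n_ls < 1:
            raise ValueError("n_ls must be >= 1")
        for tol in (self.newton_rel_tol, self.linear_rel_tol):
            if not 0.0 < tol < 1.0:
                raise ValueError("tolerances must lie in (0, 1)")
        if self.spring_stiffness_base < 0 or self.spring_stiffness_apex < 0:
            raise ValueError("spring stiffnesses must be >= 0")

    def for_validation(self) -> "SolverConfig":
        return replace(self, newton_max_iter=25)


@dataclass
class PVCurve:
    """Monotone pressure-volume loading trace (kPa, mL); p_0 = 0."""

    pressures: np.ndarray
    volumes: np.ndarray

    def __post_init__(self):
        self.pressures = np.asarray(self.pressures, float)
        self.volumes = np.asarray(self.volumes, float)
        if self.pressures.shape != self.volumes.shape:
            raise ValueError("pressures and volumes must have equal length")
        if np.any(np.diff(self.pressures) <= 0):
            raise ValueError("pressures must be strictly increasing")

    def volume_at(self, p) -> np.ndarray:
        """Volume interpolated at pressure(s) p (linear, extrapolating)."""
        p = np.asarray(p, float)
        return np.interp(p, self.pressures, self.volumes)

    def pressure_at(self, v) -> np.ndarray:
        """Pressure interpolated at volume(s) v (linear, extrapolating)."""
        v = np.asarray(v, float)
        return np.interp(v, self.volumes, self.pressures)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.pressures, self.volumes]),
                   delimiter=",", header="pressure_kPa,volume_mL", comments="")


@dataclass
class ForwardResult:
    deformed_coords: np.ndarray        # (N, 3) mm
    pv_curve: PVCurve
    newton_history: List[List[float]]  # residual norms per load step
    converged: bool
    displacements: np.ndarray = field(default=None)  # (N, 3) mm


class Assembler:
    """Precomputed operators for one reference mesh + material + config."""

    def __init__(self, mesh: Mesh, params: MaterialParams, config: SolverConfig,
                 fixed_dofs: Optional[np.ndarray] = None):
        self.mesh = mesh
        self.params = params
        self.config = config
        self.grads, self.vols = mesh.shape_gradients()
        if np.any(self.vols <= 0):
            raise SolverError("reference mesh has non-positive tet volumes")
        self.ndof = 3 * mesh.node_count
        self.tets = mesh.tets
        self.endo = mesh.surfaces["endocardium"]
        self.char_len = float(np.mean(self.vols) ** (1.0 / 3.0))

        # area-lumped spring weights per node (reference areas)
        w = np.zeros(mesh.node_count)
        for name, k in (("basal_rim", config.spring_stiffness_base),
                        ("apex_patch", config.spring_stiffness_apex)):
            faces = mesh.surfaces.get(name)
            if faces is None or len(faces) == 0 or k == 0.0:
                continue
            x = mesh.nodes[faces]
            areas = 0.5 * np.linalg.norm(
                np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)
            np.add.at(w, faces.ravel(), np.repeat(areas * k / 3.0, 3))
        self.spring_w = w

        self.fixed = np.zeros(self.ndof, dtype=bool)
        if fixed_dofs is not None and len(fixed_dofs):
            self.fixed[np.asarray(fixed_dofs, int)] = True

        # scatter indices for the element stiffness
        edof = (3 * self.tets[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.k_rows = np.repeat(edof, 12, axis=1).ravel()
        self.k_cols = np.tile(edof, (1, 12)).ravel()
        fdof = (3 * self.endo[:, :, None] + np.arange(3)).reshape(-1, 9)
        self.p_rows = np.repeat(fdof, 9, axis=1).ravel()
        self.p_cols = np.tile(fdof, (1, 9)).ravel()
        self._ilu = None

    def solve_linear(self, K: sp.csc_matrix, rhs: np.ndarray) -> np.ndarray:
        """Solve K x = rhs to the configured relative tolerance.

        Default route: GMRES preconditioned with an incomplete LU that is
        reused across Newton and load steps and refreshed when it goes
        stale.  ``linear_solver='direct'`` forces a full factorization.
        """
        if self.config.linear_solver == "direct":
            try:
                return spla.splu(K).solve(rhs)
            except RuntimeError as exc:
                raise SolverError(f"direct solver failed: {exc}") from exc
        n_it = 0

        def cb(_):
            nonlocal n_it
            n_it += 1

        for _attempt in range(2):
            if self._ilu is None:
                try:
                    self._ilu = spla.spilu(K, drop_tol=1e-5, fill_factor=12)
                except RuntimeError as exc:
                    raise SolverError(f"ILU factorization failed: {exc}") from exc
            M = spla.LinearOperator(K.shape, self._ilu.solve)
            x, info = spla.gmres(K, rhs, M=M, rtol=self.config.linear_rel_tol,
                                 atol=0.0, restart=80, maxiter=400,
                                 callback=cb, callback_type="legacy")
            if info == 0:
                if n_it > 25:       # stale preconditioner, refresh for next call
                    self._ilu = None
                return x
            self._ilu = None        # rebuild from the current tangent and retry
        raise SolverError("preconditioned GMRES did not reach the requested "
                          "tolerance")

    # -- element internal force -----------------------------------------
    def _element_forces(self, ue: np.ndarray) -> np.ndarray:
        """Internal nodal forces (M,4,3) for element displacements (M,4,3)."""
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, self.grads)
        kin = Kinematics.from_F(F, self.mesh.f0, self.mesh.s0, self.mesh.n0)
        S = pk2_stress(self.params, kin)
        P = np.einsum("eik,ekj->eij", F, S)
        return self.vols[:, None, None] * np.einsum("eij,eaj->eai", P, self.grads)

    def internal_force(self, u: np.ndarray) -> np.ndarray:
        f = np.zeros((self.mesh.node_count, 3))
        fe = self._element_forces(u[self.tets])
        np.add.at(f, self.tets.ravel(), fe.reshape(-1, 3))
        return f

    # -- follower pressure ------------------------------------------------
    def _face_forces(self, y: np.ndarray, p: float) -> np.ndarray:
        """Pressure nodal forces (K,3,3) for deformed face coords (K,3,3)."""
        c = np.cross(y[:, 1] - y[:, 0], y[:, 2] - y[:, 0])
        f = (-p / 6.0) * c                      # same vector on each node
        return np.repeat(f[:, None, :], 3, axis=1)

    def external_force(self, u: np.ndarray, p: float) -> np.ndarray:
        f = np.zeros((self.mesh.node_count, 3))
        if p != 0.0 and len(self.endo):
            y = (self.mesh.nodes + u)[self.endo]
            fe = self._face_forces(y, p)
            np.add.at(f, self.endo.ravel(), fe.reshape(-1, 3))
        return f

    # -- residual and tangent ---------------------------------------------
    def residual(self, u: np.ndarray, p: float) -> np.ndarray:
        r = (self.internal_force(u)
             + self.spring_w[:, None] * u
             - self.external_force(u, p)).ravel()
        r[self.fixed] = 0.0
        return r

    def tangent(self, u: np.ndarray, p: float) -> sp.csc_matrix:
        """Consistent tangent: geometric + material + follower-load + springs.

        Material blocks contract the elasticity tensor (finite differences
        of the analytic stress) with F and the shape gradients; the
        geometric part is analytic.
        """
        ue = u[self.tets]
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, self.grads)
        kin = Kinematics.from_F(F, self.mesh.f0, self.mesh.s0, self.mesh.n0)
        S = pk2_stress(self.params, kin)
        CC = material_tangent(self.params, kin, rel_step=self.config.fd_step)
        G = self.grads
        kgeo = np.einsum("e,eaK,eKJ,ebJ->eab", self.vols, G, S, G)
        A1 = np.einsum("eiK,eaJ->eaiKJ", F, G)
        T = np.einsum("eaiKJ,eKJMN->eaiMN", A1, CC)
        kmat = np.einsum("e,eaiMN,ebjMN->eaibj", self.vols, T, A1)
        ke = kmat + np.einsum("eab,ij->eaibj", kgeo, np.eye(3))
        ke = ke.reshape(-1, 12, 12)
        data = [ke.ravel()]
        rows = [self.k_rows]
        cols = [self.k_cols]

        if p != 0.0 and len(self.endo):
            h = self.config.fd_step * max(self.char_len, 1.0)
            y = (self.mesh.nodes + u)[self.endo]
            kf = np.empty((len(self.endo), 9, 9))
            for a in range(3):
                for i in range(3):
                    dp = np.zeros_like(y)
                    dp[:, a, i] = h
                    fp = self._face_forces(y + dp, p)
                    fm = self._face_forces(y - dp, p)
                    # external force enters the residual with a minus sign
                    kf[:, :, 3 * a + i] = -((fp - fm) / (2 * h)).reshape(-1, 9)
            data.append(kf.ravel())
            rows.append(self.p_rows)
            cols.append(self.p_cols)

        sw = np.repeat(self.spring_w, 3)
        nz = sw != 0.0
        if np.any(nz):
            idx = np.nonzero(nz)[0]
            data.append(sw[idx])
            rows.append(idx)
            cols.append(idx)

        K = sp.coo_matrix((np.concatenate(data),
                           (np.concatenate(rows), np.concatenate(cols))),
                          shape=(self.ndof, self.ndof)).tocsr()
        if np.any(self.fixed):
            K = K.tolil()
            idx = np.nonzero(self.fixed)[0]
            K[idx, :] = 0.0
            K[:, idx] = 0.0
            K[idx, idx] = 1.0
            K = K.tocsr()
        return K.tocsc()


def newton_step(asm: Assembler, u: np.ndarray, p: float):
    """One Newton update at load p; returns (u_new, residual_norm_before)."""
    r = asm.residual(u, p)
    rn = np.linalg.norm(r)
    K = asm.tangent(u, p)
    du = asm.solve_linear(K, -r)
    u_new = u + du.reshape(-1, 3)
    return u_new, rn


def _solve_load_step(asm: Assembler, u: np.ndarray, p: float,
                     max_iter: Optional[int] = None):
    """Newton iterations at fixed load p (capped); returns (u, history)."""
    cfg = asm.config
    history = []
    r = asm.residual(u, p)
    rn0 = np.linalg.norm(r)
    history.append(rn0)
    scale = max(rn0, 1e-12)
    for _ in range(max_iter or cfg.newton_max_iter):
        if history[-1] <= cfg.newton_rel_tol * scale:
            break
        K = asm.tangent(u, p)
        du = asm.solve_linear(K, -r)
        if not np.all(np.isfinite(du)):
            raise SolverError("linear solve returned non-finite update")
        u = u + du.reshape(-1, 3)
        # J > 0 check happens inside the residual evaluation
        r = asm.residual(u, p)
        history.append(np.linalg.norm(r))
    return u, history


def inflate(mesh: Mesh, params: MaterialParams, config: SolverConfig,
            p_target: float, fixed_dofs: Optional[np.ndarray] = None) -> ForwardResult:
    """Ramp the endocardial pressure from 0 to ``p_target`` (kPa).

    Returns the deformed coordinates and the simulated loading PV-curve
    with ``n_ls + 1`` points (p_0 = 0).  On element inversion within a load
    step the increment is halved (up to ``config.max_halvings`` times)
    before a :class:`SolverError` is raised.
    """
    if p_target < 0:
        raise ValueError("p_target must be >= 0")
    asm = Assembler(mesh, params, config, fixed_dofs)
    u = np.zeros((mesh.node_count, 3))
    if p_target == 0.0:
        pv = PVCurve(np.array([0.0]), np.array([cavity_volume(mesh)]))
        return ForwardResult(mesh.nodes.copy(), pv, [], True, u)
    n_ls = config.n_ls
    pressures = np.linspace(0.0, p_target, n_ls + 1)
    volumes = [cavity_volume(mesh)]
    newton_history: List[List[float]] = []
    converged = True

    for i in range(1, n_ls + 1):
        p_prev, p_next = pressures[i - 1], pressures[i]
        u_new = hist = vol = None
        # on failure, halve the increment; as a last resort repeat the
        # ladder with a fully converging Newton (the capped iteration is a
        # speed optimization that can break down for very soft materials)
        caps = [None]
        if config.newton_max_iter < 10:
            caps.append(25)
        attempts = [(cap, halving) for cap in caps
                    for halving in range(config.max_halvings + 1)]
        for cap, halving in attempts:
            try:
                if halving == 0:
                    u_try, hist_try = _solve_load_step(asm, u, p_next, cap)
                else:
                    u_try, hist_try = _substep_once(asm, u, p_prev, p_next,
                                                    2 ** halving, cap)
                # physical validity: finite residual, inflating cavity
                if not np.all(np.isfinite(hist_try)):
                    raise SolverError("non-finite residual in load step")
                vol_try = cavity_volume(mesh, u_try)
                if vol_try <= volumes[-1]:
                    raise SolverError("cavity volume did not increase "
                                      "(diverged load step)")
            except (InvertedElementError, SolverError, ValueError):
                continue
            u_new, hist, vol = u_try, hist_try, vol_try
            break
        if u_new is None:
            raise SolverError(
                f"load step {p_prev:.4g} -> {p_next:.4g} kPa failed after "
                f"{config.max_halvings} halvings")
        u = u_new
        newton_history.append(hist)
        if hist[-1] > config.newton_rel_tol * max(hist[0], 1e-12) \
                and len(hist) - 1 >= config.newton_max_iter \
                and config.newton_max_iter > 2:
            converged = False
        volumes.append(vol)

    pv = PVCurve(pressures, np.asarray(volumes))
    return ForwardResult(mesh.nodes + u, pv, newton_history, converged, u)


def _substep_once(asm: Assembler, u, p_prev, p_next, n_sub,
                  max_iter: Optional[int] = None):
    """One step-halving attempt with ``n_sub`` substeps."""
    uu = u.copy()
    hist_all = []
    for ps in np.linspace(p_prev, p_next, n_sub + 1)[1:]:
        uu, hist = _solve_load_step(asm, uu, ps, max_iter)
        hist_all.extend(hist)
    return uu, hist_all
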