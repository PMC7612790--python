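"""Backward-displacement (fixed-point) recovery of the unloaded geometry.

Given a geometry imaged under a known cavity pressure p_ed, the backward
displacement method iterates on a candidate reference configuration X^k:
inflate X^k to the measured pressure, compare the result x^k with the
measured coordinates x_dat, and subtract the mismatch.  Three variants are
provided:

* ``sellier`` -- plain fixed point, X^{k+1} = X^k - R^k with
  R^k = x^k - x_dat;
* ``aitken``  -- scalar Aitken delta-squared acceleration,
  X^{k+1} = X^k - beta R^k;
* ``armijo``  -- the Aitken step augmented with a backtracking line search:
  candidates X^l = X^k - l beta R^k for l in {1, 1/2, 1/4, ..., l_min} are
  forward-solved and the first that decreases the maximal nodal error
  r_inf = max_i ||x_i - x_i_dat||_2 is accepted (falling back to the
  candidate of smallest residual norm); unfavourable search directions are
  thereby damped.

Iteration stops when r_inf < eps (default 0.1 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .materials import MaterialParams
from .mesh import Mesh
from .solver import ForwardResult, SolverConfig, SolverError, inflate

__all__ = ["aitken_update", "unload", "Unloader", "UnloadResult",
           "UnloadState", "VARIANTS", "DEFAULT_EPS_MM"]

VARIANTS = ("sellier", "aitken", "armijo")
DEFAULT_EPS_MM = 0.1
DEFAULT_ELL_MIN = 1.0 / 8.0


def aitken_update(beta_prev: float, R_prev: np.ndarray,
                  R_cand: np.ndarray) -> float:
    """Aitken delta-squared update of the augmentation parameter.

    beta = -beta_prev * (R_prev : dR) / (dR : dR),  dR = R_cand - R_prev,
    where ':' sums elementwise products over all nodal components.  A
    vanishing denominator (stagnated residual) keeps beta unchanged.
    """
    R_prev = np.asarray(R_prev, float)
    R_cand = np.asarray(R_cand, float)
    if R_prev.shape != R_cand.shape:
        raise ValueError("residual shapes differ")
    dR = R_cand - R_prev
    denom = float(np.sum(dR * dR))
    if denom <= 1e-14 * float(np.sum(R_prev * R_prev)) or denom == 0.0:
        return beta_prev
    return -beta_prev * float(np.sum(R_prev * dR)) / denom


@dataclass
class UnloadState:
    """Accepted fixed-point iterate of the backward-displacement method."""

    k: int
    X: np.ndarray               # accepted reference coordinates (N, 3) mm
    x: np.ndarray               # forward-solved deformed coordinates (N, 3)
    R: np.ndarray               # nodal residual x - x_dat (N, 3)
    beta: float
    ell: float                  # accepted line-search factor
    r_inf: float                # max nodal error, mm
    forward: ForwardResult
    n_solves: int               # forward solves spent on this iteration


@dataclass
class UnloadResult:
    unloaded_mesh: Mesh
    history: List[UnloadState]
    converged: bool
    n_forward_solves: int

    @property
    def r_inf(self) -> float:
        return self.history[-1].r_inf if self.history else np.inf


class Unloader:
    """Stateful driver allowing one accepted iteration at a time.

    The parameter-fitting loop updates the material between iterations while
    beta, the residual and the iteration index persist; ``unload`` wraps
    this driver for a fixed material.
    """

    def __init__(self, x_dat: Mesh, params: MaterialParams, p_ed: float,
                 config: Optional[SolverConfig] = None,
                 variant: str = "armijo",
                 eps: float = DEFAULT_EPS_MM,
                 ell_min: float = DEFAULT_ELL_MIN):
        if variant not in VARIANTS:
            raise ValueError(f"unknown unloading variant {variant!r}")
        if p_ed < 0:
            raise ValueError("p_ed must be >= 0")
        self.x_dat = x_dat
        self.params = params
        self.p_ed = p_ed
        self.config = config or SolverConfig()
        self.variant = variant
        self.eps = eps
        ladder = [1.0]
        while ladder[-1] / 2.0 >= ell_min - 1e-12:
            ladder.append(ladder[-1] / 2.0)
        self.Lambda = ladder
        self.k = 0
        self.beta = 1.0
        self.state: Optional[UnloadState] = None
        self.n_forward_solves = 0

    #: relative parameter change above which the Aitken factor is restarted
    #: (the delta-squared extrapolation assumes a stationary fixed-point map)
    BETA_RESET_PARAM_CHANGE = 0.05

    def set_params(self, params: MaterialParams) -> None:
        if self.state is not None and params is not self.params:
            a_old = next(iter(self.params.a.values()))
            b_old = next(iter(self.params.b.values()))
            a_new = next(iter(params.a.values()))
            b_new = next(iter(params.b.values()))
            change = max(abs(a_new / a_old - 1.0), abs(b_new / b_old - 1.0))
            if change > self.BETA_RESET_PARAM_CHANGE:
                self.beta = 1.0
        self.params = params

    @property
    def converged(self) -> bool:
        return self.state is not None and self.state.r_inf < self.eps

    def _solve(self, X: np.ndarray) -> ForwardResult:
        self.n_forward_solves += 1
        return inflate(self.x_dat.with_nodes(X), self.params, self.config,
                       self.p_ed)

    def step(self) -> UnloadState:
        """Perform one accepted fixed-point iteration (Armijo-damped)."""
        tgt = self.x_dat.nodes
        if self.state is None:                   # k = 0: accept immediately
            X = tgt.copy()
            fwd = self._solve(X)
            R = fwd.deformed_coords - tgt
            r_inf = float(np.max(np.linalg.norm(R, axis=1)))
            self.state = UnloadState(0, X, fwd.deformed_coords, R, self.beta,
                                     1.0, r_inf, fwd, 1)
            self.k = 1
            return self.state

        prev = self.state
        if self.variant == "sellier":
            factors = [1.0]
            beta = 1.0
        elif self.variant == "aitken":
            factors = [1.0]
            beta = self.beta
        else:
            factors = self.Lambda
            beta = self.beta

        best = None
        accepted = None
        n_solves = 0
        if self.variant == "armijo":
            # rescue tail: if every regular candidate's forward problem
            # fails, keep damping (the map is continuous in X, so small
            # enough steps stay solvable with the current material); tried
            # only when the whole regular ladder failed to solve
            rescue = [factors[-1] / 2 ** i for i in range(1, 6)]
        else:
            rescue = []
        for phase, ells in enumerate((factors, rescue)):
            if phase == 1 and (accepted is not None or best is not None):
                break
            for ell in ells:
                X_c = prev.X - ell * beta * prev.R
                try:
                    fwd = self._solve(X_c)
                except SolverError:
                    n_solves += 1
                    continue
                n_solves += 1
                R_c = fwd.deformed_coords - tgt
                r_c = float(np.max(np.linalg.norm(R_c, axis=1)))
                cand = UnloadState(self.k, X_c, fwd.deformed_coords, R_c,
                                   beta, ell, r_c, fwd, n_solves)
                if self.variant != "armijo" or r_c < prev.r_inf or phase == 1:
                    accepted = cand
                    break
                if best is None or np.linalg.norm(R_c) < np.linalg.norm(best.R):
                    best = cand
            if accepted is not None:
                break
        if accepted is None:
            if best is None:
                raise SolverError(
                    f"forward solve failed for every line-search factor at "
                    f"unloading iteration {self.k}")
            accepted = best          # no decrease: smallest residual norm
        accepted.n_solves = n_solves

        if self.variant in ("aitken", "armijo"):
            self.beta = aitken_update(beta, prev.R, accepted.R)
            # the update subtracts beta*R; a non-positive beta would reverse
            # the search direction (which cannot converge for inflation), so
            # restart the acceleration
            if self.beta <= 0.0:
                self.beta = 1.0
        self.state = accepted
        self.k += 1
        return accepted


def unload(x_dat: Mesh, params: MaterialParams, p_ed: float,
           config: Optional[SolverConfig] = None, variant: str = "armijo",
           max_iter: int = 50, eps: float = DEFAULT_EPS_MM,
           ell_min: float = DEFAULT_ELL_MIN) -> UnloadResult:
    """Run the backward-displacement method until r_inf < eps.

    Returns the recovered unloaded mesh X* and the accepted-iterate history;
    ``converged`` is False when ``max_iter`` accepted iterations did not
    reach the nodal tolerance.
    """
    drv = Unloader(x_dat, params, p_ed, config, variant, eps, ell_min)
    history: List[UnloadState] = []
    try:
        while len(history) < max_iter:
            st = drv.step()
            history.append(st)
            if st.r_inf < eps:
                break
    except SolverError:
        if not history:
            raise
    X_star = x_dat.with_nodes(history[-1].X if history else x_dat.nodes)
    converged = bool(history and history[-1].r_inf < eps)
    return UnloadResult(X_star, history, converged, drv.n_forward_solves)
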