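"""Cost-functional fitting (CFF): the derivative-free verification baseline.

Instead of the fixed-point rescaling of :mod:`cardio_unload.mff`, CFF
minimizes an explicit pressure/volume mismatch functional by the downhill
simplex (Nelder-Mead) method.  Every cost evaluation performs a *full*
unloading of the measured geometry with the trial parameters followed by a
loading simulation, which makes the approach far more expensive than MFF
(one unloading step per parameter update there).  The cost is

    J = 1/2 sum_p ((V_tgt(p) - V_sim(p)) / V_ed)^2
      + 1/2 sum_V ((p_tgt(V) - p_sim(V)) / p_ed)^2
      + gamma * ((V0_tgt - V0_sim) / V_ed)^2,

evaluated on equidistant-pressure and equidistant-volume grids; a failed
forward solve or an out-of-bounds trial point returns a large sentinel
cost (Nelder-Mead is unconstrained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy.optimize import minimize

from .klotz import KlotzCurve, build_klotz
from .materials import MaterialParams
from .mesh import Mesh
from .metrics import goodness_report
from .solver import PVCurve, SolverConfig, SolverError
from .unloading import unload

__all__ = ["CFFConfig", "CFFResult", "cff_cost", "cost_from_curves", "run_cff"]

SENTINEL_COST = 1e8


@dataclass(frozen=True)
class CFFConfig:
    """Settings of the cost-functional fit.

    ``n_opt`` selects the scaling parametrization: 1 -- a_scale only (all
    b_(.) fixed at 0.5 x default); 2 -- (a_scale, b_scale); 3 -- (a_scale,
    b_scale_iso, b_scale_aniso) with the isotropic exponent scaled
    separately.  ``init`` chooses the simplex start: scalings of 0.5
    ("literature", the default halving of too-stiff ex vivo parameters) or
    an MFF pre-fit ("mff_init").
    """

    n_opt: int = 2
    gamma: float = 1.0
    lower_bound: float = 0.1
    simplex_xatol: float = 0.001
    init: str = "literature"
    unload_max_iter: int = 15
    max_evals: int = 400

    def __post_init__(self):
        if self.n_opt not in (1, 2, 3):
            raise ValueError("n_opt must be 1, 2 or 3")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.init not in ("literature", "mff_init"):
            raise ValueError("init must be 'literature' or 'mff_init'")


@dataclass
class CFFResult:
    scalings: np.ndarray          # optimized scaling vector (length n_opt)
    cost: float
    n_evals: int                  # cost-functional evaluations
    n_forward_solves: int         # passive inflations spent in total
    converged: bool
    report: Optional[object] = None
    final_pv: Optional[PVCurve] = None
    fitted_params: Optional[MaterialParams] = None
    history: List[dict] = field(default_factory=list)


def _scaled_params(base: MaterialParams, x: np.ndarray, n_opt: int) -> MaterialParams:
    if n_opt == 1:
        return base.scaled(float(x[0]), 0.5)
    if n_opt == 2:
        return base.scaled(float(x[0]), float(x[1]))
    # n_opt == 3: split the exponent scaling into isotropic vs anisotropic
    p = base.scaled(float(x[0]), 1.0)
    b = dict(p.b)
    for key in b:
        b[key] *= float(x[1]) if key == "b" else float(x[2])
    from dataclasses import replace
    return replace(p, b=b)


def cost_from_curves(target_v_at_p, target_p_at_v, sim: PVCurve,
                     V0_tgt: float, V_ed: float, p_ed: float,
                     gamma: float, n_samples: Optional[int] = None) -> float:
    """Evaluate the mismatch functional between a target EDPVR and a
    simulated loading curve.

    ``target_v_at_p``/``target_p_at_v`` are callables (kPa -> mL, mL -> kPa).
    """
    n = n_samples or (len(sim.pressures) - 1)
    p_grid = np.linspace(0.0, p_ed, n + 1)[1:]
    V0_sim = float(sim.volumes[0])
    v_lo = max(V0_tgt, V0_sim)
    v_grid = np.linspace(v_lo, V_ed, n + 1)[1:]
    dv = (np.asarray(target_v_at_p(p_grid), float) - sim.volume_at(p_grid)) / V_ed
    dp = (np.asarray(target_p_at_v(v_grid), float) - sim.pressure_at(v_grid)) / p_ed
    dv0 = (V0_tgt - V0_sim) / V_ed
    return float(0.5 * np.sum(dv ** 2) + 0.5 * np.sum(dp ** 2)
                 + gamma * dv0 ** 2)


def cff_cost(target: Union[KlotzCurve, PVCurve], x: np.ndarray,
             base_params: MaterialParams, mesh: Mesh, p_ed: float,
             V_ed: float, config: CFFConfig,
             solver_config: Optional[SolverConfig] = None,
             _counter: Optional[dict] = None) -> float:
    """Full-pipeline cost of one trial scaling vector.

    Runs the backward-displacement unloading to convergence (or its
    iteration cap) with the scaled parameters; the loading curve of the
    final accepted iterate is compared with the target.  Any forward-solver
    failure maps to a large sentinel cost.
    """
    x = np.asarray(x, float)
    if np.any(x <= config.lower_bound):
        return SENTINEL_COST * (1.0 + float(np.sum(config.lower_bound - x)))
    params = _scaled_params(base_params, x, config.n_opt)
    cfg = solver_config or SolverConfig()
    try:
        res = unload(mesh, params, p_ed, cfg, variant="armijo",
                     max_iter=config.unload_max_iter)
    except SolverError:
        return SENTINEL_COST
    if _counter is not None:
        _counter["solves"] += res.n_forward_solves
        _counter["last"] = res
    pv = res.history[-1].forward.pv_curve
    if isinstance(target, KlotzCurve):
        return cost_from_curves(target.volume_at, target.pressure_at, pv,
                                target.V0_klotz, V_ed, p_ed, config.gamma)
    return cost_from_curves(target.volume_at, target.pressure_at, pv,
                            float(target.volumes[0]), V_ed, p_ed, config.gamma)


def run_cff(mesh: Mesh, p_ed: float, V_ed: float,
            base_params: MaterialParams, config: CFFConfig,
            solver_config: Optional[SolverConfig] = None,
            target: Union[KlotzCurve, PVCurve, None] = None,
            x0: Optional[np.ndarray] = None) -> CFFResult:
    """Nelder-Mead optimization of the scaling parameters.

    ``x0`` overrides the initial scalings (e.g. an MFF pre-fit when
    ``config.init == 'mff_init'``); the default starts all scalings at 0.5.
    Bounds (> ``config.lower_bound``) are enforced by the sentinel cost.
    """
    if target is None:
        target = build_klotz(V_ed, p_ed)
    cfg = solver_config or SolverConfig()
    if x0 is None:
        x0 = np.full(config.n_opt, 0.5)
    x0 = np.asarray(x0, float)
    if x0.shape != (config.n_opt,):
        raise ValueError(f"x0 must have length n_opt = {config.n_opt}")

    counter = {"solves": 0, "last": None}
    history: List[dict] = []

    def fun(x):
        c = cff_cost(target, x, base_params, mesh, p_ed, V_ed, config, cfg,
                     _counter=counter)
        history.append({"x": np.array(x), "cost": c})
        return c

    sol = minimize(fun, x0, method="Nelder-Mead",
                   options={"xatol": config.simplex_xatol, "fatol": np.inf,
                            "maxfev": config.max_evals, "adaptive": False})
    x_best = np.asarray(sol.x, float)
    best_cost = fun(x_best)       # re-evaluate to populate counter["last"]
    res_last = counter["last"]
    params_best = _scaled_params(base_params, x_best, config.n_opt)
    pv = res_last.history[-1].forward.pv_curve if res_last else None
    report = None
    if res_last is not None:
        a_s = float(x_best[0])
        b_s = float(x_best[1]) if config.n_opt >= 2 else 0.5
        report = goodness_report(target, res_last.history[-1].forward, mesh,
                                 (a_s, b_s), V_ed, p_ed)
    return CFFResult(
        scalings=x_best, cost=float(best_cost), n_evals=len(history),
        n_forward_solves=counter["solves"],
        converged=bool(sol.success or sol.status == 0),
        report=report, final_pv=pv, fitted_params=params_best,
        history=history)
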