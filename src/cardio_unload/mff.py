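"""Model-function fitting (MFF): the fixed-point parameter-identification loop.

Each iteration performs one accepted backward-displacement step (yielding a
candidate unloaded geometry and its simulated loading curve), fits the
exponential model function

    Phi(x, x0) = a/(2b) * (exp(b (x - x0)/x0) - 1)

independently to the target EDPVR and to the simulated curve
(Levenberg-Marquardt, x0 fixed to the respective unloaded volume), and
rescales all stress-like parameters a_(.) by a_scale = a_klotz/a_sim and
all exponents b_(.) by b_scale = b_klotz/|b_sim| (each clamped to
[1/5, 5]).  Geometry update and parameter update share the same iteration
index; convergence requires the volume, nodal and parameter-update
criteria of :mod:`cardio_unload.metrics`.

The target defaults to the single-beat empirical EDPVR built from the
measured pair; any sampled PV-curve (e.g. an experimentally measured or a
model-generated EDPVR) can be fitted in exactly the same fashion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Union

import numpy as np
from scipy.optimize import least_squares

from .klotz import KlotzCurve, build_klotz, sample_klotz
from .materials import MaterialParams
from .mesh import Mesh, cavity_volume
from .metrics import ConvergenceReport, check_convergence, goodness_report
from .solver import PVCurve, SolverConfig, SolverError
from .unloading import Unloader

__all__ = ["ModelFunctionFit", "ScalePair", "MFFResult", "model_function",
           "fit_model_function", "compute_scalings", "apply_scalings",
           "run_mff", "SCALE_BOUNDS"]

SCALE_BOUNDS = (0.2, 5.0)
LM_INITIAL_GUESS = (1.0, 5.0)


def model_function(x, x0: float, a: float, b: float):
    """Exponential pressure-volume model Phi(x, x0); Phi(x0, x0) = 0."""
    x = np.asarray(x, float)
    return a / (2.0 * b) * np.expm1(b * (x - x0) / x0)


@dataclass(frozen=True)
class ModelFunctionFit:
    a_fit: float           # kPa
    b_fit: float
    x0: float              # mL, fixed during the fit
    residual_norm: float
    success: bool = True


@dataclass(frozen=True)
class ScalePair:
    a_scale: float
    b_scale: float
    a_clamped: bool = False
    b_clamped: bool = False

    def __iter__(self):
        return iter((self.a_scale, self.b_scale))


@dataclass
class MFFResult:
    unloaded_mesh: Mesh
    fitted_params: MaterialParams
    history: List[dict] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    stagnated: bool = False
    target: Union[KlotzCurve, PVCurve, None] = None
    final_pv: Optional[PVCurve] = None
    n_forward_solves: int = 0

    @property
    def final_report(self) -> Optional[ConvergenceReport]:
        return self.history[-1]["report"] if self.history else None

    @property
    def final_scalings(self) -> Optional[ScalePair]:
        return self.history[-1]["scalings"] if self.history else None

    @property
    def cumulative_scalings(self) -> tuple:
        """Product of all per-iteration scalings (total change from the
        initial parameter set)."""
        a = float(np.prod([h["scalings"].a_scale for h in self.history]))
        b = float(np.prod([h["scalings"].b_scale for h in self.history]))
        return a, b


def fit_model_function(pv: PVCurve, x0: float) -> ModelFunctionFit:
    """Least-squares fit of (a, b) to the points i = 1..n of a PV-curve.

    The p = 0 point enters only through the fixed unloaded volume ``x0``.
    Deterministic: the Levenberg-Marquardt iteration always starts from the
    same initial guess.
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    vols = pv.volumes[1:] if pv.pressures[0] == 0.0 else pv.volumes
    pres = pv.pressures[1:] if pv.pressures[0] == 0.0 else pv.pressures
    if len(vols) < 3:
        raise ValueError("need at least 3 fit points above p = 0")
    if not (np.all(np.isfinite(vols)) and np.all(np.isfinite(pres))):
        raise ValueError("non-finite PV data")

    def resid(theta):
        return model_function(vols, x0, theta[0], theta[1]) - pres

    # LM can land in a spurious negative-a minimum for coarsely sampled
    # curves; retry from a deterministic ladder of starts and keep the best
    # admissible (a > 0) solution
    best = None
    for start in (LM_INITIAL_GUESS, (0.5, 10.0), (2.0, 2.0), (5.0, 1.0),
                  (0.1, 20.0)):
        sol = least_squares(resid, start, method="lm", xtol=1e-12,
                            ftol=1e-12, max_nfev=2000)
        rn = float(np.linalg.norm(sol.fun))
        if sol.x[0] > 0 and (best is None or rn < best[1]):
            best = (sol, rn)
        if best is not None and start == LM_INITIAL_GUESS and sol.x[0] > 0:
            break  # the canonical start succeeded
    if best is None:        # keep the canonical-fit result, caller decides
        best = (sol, rn)
        warnings.warn("model-function fit found no admissible (a > 0) "
                      "solution")
    sol, rn = best
    a_fit, b_fit = float(sol.x[0]), float(sol.x[1])
    if not sol.success:
        warnings.warn(f"model-function fit did not fully converge "
                      f"(residual {rn:.3g})")
    return ModelFunctionFit(a_fit, b_fit, float(x0), rn, bool(sol.success))


def compute_scalings(fit_klotz: ModelFunctionFit,
                     fit_sim: ModelFunctionFit) -> ScalePair:
    """Parameter scalings from the two fits, clamped to [1/5, 5].

    ``b_sim`` enters through its absolute value (it can be negative for a
    concave simulated curve); a_sim must be positive (inflation increases
    volume).
    """
    if fit_sim.a_fit <= 0:
        raise ValueError("a_fit of the simulated curve must be > 0")
    lo, hi = SCALE_BOUNDS
    a_raw = fit_klotz.a_fit / fit_sim.a_fit
    b_raw = fit_klotz.b_fit / abs(fit_sim.b_fit)
    a_scale = min(max(a_raw, lo), hi)
    b_scale = min(max(b_raw, lo), hi)
    return ScalePair(a_scale, b_scale,
                     a_clamped=a_scale != a_raw, b_clamped=b_scale != b_raw)


def apply_scalings(params: MaterialParams, s: ScalePair) -> MaterialParams:
    """Multiply every a_(.) by a_scale and every b_(.) by b_scale
    (bulk modulus and dispersion parameters unchanged)."""
    return params.scaled(s.a_scale, s.b_scale)


def _prepare_target(target, p_ed, V_ed, n_ls):
    """Return (target_object, sampled PVCurve, V0_target, fit of target)."""
    if target is None:
        target = build_klotz(V_ed, p_ed)
    if isinstance(target, KlotzCurve):
        sampled = sample_klotz(target, n_ls, p_ed)
        V0_tgt = target.V0_klotz
    elif isinstance(target, PVCurve):
        if target.pressures[0] != 0.0:
            raise ValueError("target curve must start at p = 0")
        if abs(target.pressures[-1] - p_ed) > 1e-9 * max(p_ed, 1.0):
            raise ValueError("target curve must end at p_ed")
        sampled = target
        V0_tgt = float(target.volumes[0])
    else:
        raise TypeError("target must be a KlotzCurve, a PVCurve or None")
    fit_tgt = fit_model_function(sampled, V0_tgt)
    return target, sampled, V0_tgt, fit_tgt


def run_mff(x_dat: Mesh, p_ed: float, V_ed: float,
            params0: MaterialParams,
            solver_config: Optional[SolverConfig] = None,
            target: Union[KlotzCurve, PVCurve, None] = None,
            max_iter: int = 50,
            unload_variant: str = "armijo",
            eps_nodal: float = 0.1) -> MFFResult:
    """Fixed-point identification of material parameters and unloaded shape.

    ``x_dat`` is the measured (loaded) geometry, ``(p_ed, V_ed)`` the
    measured PV-pair (kPa, mL).  Returns the converged unloaded mesh X*,
    the fitted parameter set and the per-iteration history.
    """
    if p_ed <= 0:
        raise ValueError("p_ed must be > 0 (a degenerate target EDPVR "
                         "cannot be fitted)")
    if V_ed <= 0:
        raise ValueError("V_ed must be > 0")
    cfg = solver_config or SolverConfig()
    v_mesh = cavity_volume(x_dat)
    if abs(v_mesh - V_ed) > 0.01 * V_ed:
        warnings.warn(
            f"mesh cavity volume ({v_mesh:.1f} mL) deviates more than 1% "
            f"from the measured V_ed ({V_ed:.1f} mL)")

    target, tgt_curve, V0_tgt, fit_tgt = _prepare_target(target, p_ed, V_ed,
                                                         cfg.n_ls)

    unloader = Unloader(x_dat, params0, p_ed, cfg, variant=unload_variant,
                        eps=eps_nodal)
    params = params0
    history: List[dict] = []
    reports: List[ConvergenceReport] = []
    converged = stagnated = False

    aborted = False
    for _k in range(max_iter):
        unloader.set_params(params)
        try:
            state = unloader.step()
        except SolverError as exc:
            # forward-solver failure: abort with the history accumulated
            warnings.warn(f"fixed-point iteration aborted: {exc}")
            aborted = True
            break
        pv = state.forward.pv_curve
        fit_sim = fit_model_function(pv, float(pv.volumes[0]))
        scalings = compute_scalings(fit_tgt, fit_sim)
        params = apply_scalings(params, scalings)
        report = goodness_report(
            tgt_curve if not isinstance(target, KlotzCurve) else target,
            state.forward, x_dat, scalings, V_ed, p_ed)
        status = check_convergence(report, reports)
        reports.append(report)
        history.append({
            "k": state.k, "ell": state.ell, "beta": state.beta,
            "r_inf": state.r_inf, "scalings": scalings,
            "fit_sim": fit_sim, "report": report, "pv": pv,
            "status": status,
        })
        if status == "converged":
            converged = True
            break
        if status == "stagnated":
            stagnated = True
            break

    X_star = x_dat.with_nodes(unloader.state.X if unloader.state is not None
                              else x_dat.nodes)
    return MFFResult(
        unloaded_mesh=X_star, fitted_params=params, history=history,
        iterations=len(history), converged=converged,
        stagnated=stagnated or aborted,
        target=target, final_pv=history[-1]["pv"] if history else None,
        n_forward_solves=unloader.n_forward_solves)
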