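"""Model/Results interface to the inverse passive-mechanics problem.

:class:`PassiveLVModel` bundles the data of one case -- the loaded
(imaged) geometry and the measured end-diastolic pressure-volume pair --
with the modelling choices (constitutive law, solver settings).  ``fit()``
runs the fixed-point identification (or the cost-functional baseline) and
returns a :class:`PassiveLVResults` carrying the unloaded geometry, the
fitted parameters, per-iteration diagnostics and a ``summary()`` table.

    >>> model = PassiveLVModel(mesh, p_ed=1.07, V_ed=159.3,
    ...                        model_id="reduced_HO")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .cff import CFFConfig, run_cff
from .klotz import KlotzCurve, build_klotz
from .materials import MaterialParams, default_params
from .mesh import Mesh, cavity_volume
from .metrics import goodness_report
from .mff import MFFResult, run_mff
from .solver import PVCurve, SolverConfig, inflate

__all__ = ["PassiveLVModel", "PassiveLVResults"]


class PassiveLVModel:
    """Inverse model: unloaded configuration + passive material parameters.

    Parameters
    ----------
    x_dat : Mesh
        Loaded (in vivo) geometry with fiber frames and surface labels.
    p_ed, V_ed : float
        Measured end-diastolic pressure (kPa) and volume (mL).  ``V_ed``
        defaults to the mesh cavity volume.
    model_id : str
        Constitutive law (see :mod:`cardio_unload.materials`).
    params0 : MaterialParams, optional
        Initial parameters; defaults to the literature values of the law.
    target : KlotzCurve or PVCurve, optional
        Fitting target; defaults to the single-beat empirical EDPVR built
        from (p_ed, V_ed).
    """

    def __init__(self, x_dat: Mesh, p_ed: float,
                 V_ed: Optional[float] = None,
                 model_id: str = "reduced_HO",
                 params0: Optional[MaterialParams] = None,
                 solver_config: Optional[SolverConfig] = None,
                 target: Union[KlotzCurve, PVCurve, None] = None):
        self.x_dat = x_dat
        self.p_ed = float(p_ed)
        self.V_ed = float(V_ed) if V_ed is not None else cavity_volume(x_dat)
        self.params0 = params0 or default_params(model_id)
        self.solver_config = solver_config or SolverConfig()
        self.target = target

    def fit(self, method: str = "mff", max_iter: int = 50,
            cff_config: Optional[CFFConfig] = None) -> "PassiveLVResults":
        """Identify parameters and the unloaded configuration.

        ``method='mff'`` runs the fixed-point model-function fitting;
        ``method='cff'`` the Nelder-Mead cost-functional baseline.
        """
        if method == "mff":
            res = run_mff(self.x_dat, self.p_ed, self.V_ed, self.params0,
                          solver_config=self.solver_config,
                          target=self.target, max_iter=max_iter)
            return PassiveLVResults(self, mff=res)
        if method == "cff":
            cfg = cff_config or CFFConfig()
            res = run_cff(self.x_dat, self.p_ed, self.V_ed, self.params0,
                          cfg, solver_config=self.solver_config,
                          target=self.target)
            return PassiveLVResults(self, cff=res)
        raise ValueError("method must be 'mff' or 'cff'")


@dataclass
class PassiveLVResults:
    """Fit results; exposes estimates, diagnostics and a summary table."""

    model: PassiveLVModel
    mff: Optional[MFFResult] = None
    cff: Optional[object] = None

    # -- estimates --------------------------------------------------------
    @property
    def params(self) -> MaterialParams:
        return self.mff.fitted_params if self.mff else self.cff.fitted_params

    @property
    def unloaded_mesh(self) -> Mesh:
        if self.mff is None:
            raise AttributeError("the CFF baseline does not retain X*; "
                                 "rerun the unloading with .params")
        return self.mff.unloaded_mesh

    @property
    def scalings(self) -> tuple:
        if self.mff:
            return self.mff.cumulative_scalings
        x = self.cff.scalings
        return tuple(float(v) for v in x)

    @property
    def converged(self) -> bool:
        return self.mff.converged if self.mff else self.cff.converged

    @property
    def V0(self) -> float:
        """Cavity volume of the fitted unloaded configuration (mL)."""
        if self.mff:
            return float(self.mff.final_pv.volumes[0])
        return float(self.cff.final_pv.volumes[0])

    def history_frame(self) -> pd.DataFrame:
        """Per-iteration diagnostics as a DataFrame."""
        if self.mff:
            rows = []
            for h in self.mff.history:
                r = h["report"]
                rows.append({
                    "k": h["k"], "ell": h["ell"], "beta": h["beta"],
                    "a_scale": h["scalings"].a_scale,
                    "b_scale": h["scalings"].b_scale,
                    "r_inf_mm": h["r_inf"], "r_V0_mL": r.r_V0,
                    "r_ed_mL": r.r_ed, "r_param": r.r_param,
                    "r_V0_rel_pct": r.r_V0_rel, "r_An_rel_pct": r.r_An_rel,
                    "status": h["status"],
                })
            return pd.DataFrame(rows)
        return pd.DataFrame([{"eval": i, **{f"x{j}": v for j, v in
                                            enumerate(h["x"])},
                              "cost": h["cost"]}
                             for i, h in enumerate(self.cff.history)])

    def validate(self, n_ls: Optional[int] = None):
        """Full-Newton re-inflation of the fitted unloaded configuration.

        Returns (ForwardResult, ConvergenceReport): the goodness of fit of
        the validation loading curve against the target EDPVR.
        """
        cfg = self.model.solver_config.for_validation()
        if n_ls is not None:
            from dataclasses import replace
            cfg = replace(cfg, n_ls=n_ls)
        fwd = inflate(self.unloaded_mesh, self.params, cfg, self.model.p_ed)
        target = self.model.target or build_klotz(self.model.V_ed,
                                                  self.model.p_ed)
        report = goodness_report(target, fwd, self.model.x_dat,
                                 (1.0, 1.0), self.model.V_ed, self.model.p_ed)
        return fwd, report

    def summary(self) -> str:
        lines = ["Passive LV inverse fit", "=" * 52]
        m = self.model
        lines.append(f"constitutive law:     {self.params.model_id}")
        lines.append(f"measured PV-pair:     p_ed = {m.p_ed:.3f} kPa, "
                     f"V_ed = {m.V_ed:.2f} mL")
        if isinstance(m.target, KlotzCurve) or m.target is None:
            tgt = m.target or build_klotz(m.V_ed, m.p_ed)
            lines.append(f"target EDPVR:         single-beat empirical "
                         f"(V0 = {tgt.V0_klotz:.2f} mL)")
        else:
            lines.append("target EDPVR:         user-supplied PV-curve "
                         f"(V0 = {m.target.volumes[0]:.2f} mL)")
        method = "MFF (fixed point)" if self.mff else "CFF (Nelder-Mead)"
        lines.append(f"method:               {method}")
        a_s, b_s = self.scalings[:2]
        lines.append(f"fitted scalings:      a_scale = {a_s:.4f}, "
                     f"b_scale = {b_s:.4f}")
        lines.append(f"unloaded volume V0:   {self.V0:.2f} mL")
        if self.mff:
            lines.append(f"iterations:           {self.mff.iterations} "
                         f"({self.mff.n_forward_solves} forward solves)")
            rep = self.mff.final_report
            if rep:
                lines.append(f"goodness of fit:      r_V0,rel = "
                             f"{rep.r_V0_rel:.3f} %V_ed, r_An,rel = "
                             f"{rep.r_An_rel:.2f} %A_klotz")
                lines.append(f"max nodal error:      "
                             f"{rep.r_nodal_inf:.4f} mm")
        else:
            lines.append(f"cost evaluations:     {self.cff.n_evals} "
                         f"({self.cff.n_forward_solves} forward solves)")
            lines.append(f"final cost:           {self.cff.cost:.3e}")
        lines.append(f"converged:            {self.converged}")
        lines.append("parameters:")
        for k, v in {**self.params.a, **self.params.b}.items():
            unit = " kPa" if k.startswith("a") else ""
            lines.append(f"    {k:6s} = {v:.4f}{unit}")
        return "\n".join(lines)
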