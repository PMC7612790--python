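"""Error estimates, goodness of fit and convergence/stagnation detection.

The parameter-fitting loop monitors four errors per iteration:

* ``r_V0``        -- |V0_target - V0_sim| (mL), unloaded-volume mismatch;
* ``r_ed``        -- |V_ed_dat - V_ed_sim| (mL), end-diastolic-volume
  mismatch;
* ``r_nodal_inf`` -- max_i ||x_i - x_i_dat||_2 (mm), maximal nodal error;
* ``r_param``     -- max(|1 - a_scale|, |1 - b_scale|), the parameter
  update between iterations.

Convergence requires r_ed and r_V0 below 0.5 % of V_ed_dat, r_nodal_inf
below 0.1 mm and r_param below 0.001.  A small r_param while another
criterion keeps failing over several iterations flags stagnation.

Goodness of fit reports the relative unloaded-volume error (percent of
V_ed) and the relative area between the normalized simulated and target
curves (percent of the area under the target curve); the area between two
polylines sums shoelace areas of the quadrilaterals spanned by consecutive
point pairs of the two curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .klotz import KlotzCurve, normalize_pv, sample_klotz
from .solver import ForwardResult, PVCurve

__all__ = ["ConvergenceReport", "area_between_curves", "goodness_report",
           "check_convergence", "EPS_VOL_PCT", "EPS_NODAL_MM", "EPS_PARAM"]

EPS_VOL_PCT = 0.5      # percent of V_ed_dat
EPS_NODAL_MM = 0.1
EPS_PARAM = 0.001
STAGNATION_WINDOW = 3


@dataclass
class ConvergenceReport:
    r_V0: float            # mL
    r_ed: float            # mL
    r_nodal_inf: float     # mm
    r_param: float
    r_V0_rel: float        # percent of V_ed_dat
    r_An: float            # normalized-area units
    r_An_rel: float        # percent of A_klotz
    A_klotz: float
    V_ed_dat: float
    eps_vol_pct: float = EPS_VOL_PCT
    eps_nodal_mm: float = EPS_NODAL_MM
    eps_param: float = EPS_PARAM

    @property
    def volume_criteria_met(self) -> bool:
        lim = self.eps_vol_pct / 100.0 * self.V_ed_dat
        return self.r_ed < lim and self.r_V0 < lim

    @property
    def converged(self) -> bool:
        return (self.volume_criteria_met
                and self.r_nodal_inf < self.eps_nodal_mm
                and self.r_param < self.eps_param)

    def to_dict(self) -> dict:
        return {
            "r_V0_mL": self.r_V0,
            "r_ed_mL": self.r_ed,
            "r_nodal_inf_mm": self.r_nodal_inf,
            "r_param": self.r_param,
            "r_V0_rel_pct_Ved": self.r_V0_rel,
            "r_An_rel_pct_Aklotz": self.r_An_rel,
            "converged": self.converged,
        }


def _as_points(curve: Union[PVCurve, np.ndarray]) -> np.ndarray:
    """Coerce a curve into an (n, 2) array of (x, y) = (volume, pressure)."""
    if isinstance(curve, PVCurve):
        return np.column_stack([curve.volumes, curve.pressures])
    pts = np.asarray(curve, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("curve must be an (n>=2, 2) array or a PVCurve")
    return pts


def area_between_curves(curve_a, curve_b, n_resample: int | None = None) -> float:
    """Total area between two polylines by the quadrilateral/shoelace method.

    Each pair of consecutive points on the two curves spans a quadrilateral
    whose area follows from Gauss' shoelace formula; the sum over all
    quadrilaterals is returned.  PVCurve inputs of unequal sampling are
    resampled to a common pressure grid first (pairing is positional).
    """
    if (isinstance(curve_a, PVCurve) and isinstance(curve_b, PVCurve)
            and (n_resample or len(curve_a.pressures) != len(curve_b.pressures))):
        n = n_resample or max(len(curve_a.pressures), len(curve_b.pressures))
        lo = max(curve_a.pressures[0], curve_b.pressures[0])
        hi = min(curve_a.pressures[-1], curve_b.pressures[-1])
        grid = np.linspace(lo, hi, n)
        a = np.column_stack([curve_a.volume_at(grid), grid])
        b = np.column_stack([curve_b.volume_at(grid), grid])
    else:
        a = _as_points(curve_a)
        b = _as_points(curve_b)
        if len(a) != len(b):
            raise ValueError("curves must have equal point counts "
                             "(or both be PVCurves for resampling)")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        import warnings
        warnings.warn("degenerate curves (all points identical); area is 0")
        return 0.0
    # quadrilateral vertices: a_i, a_{i+1}, b_{i+1}, b_i
    x1, y1 = a[:-1, 0], a[:-1, 1]
    x2, y2 = a[1:, 0], a[1:, 1]
    x3, y3 = b[1:, 0], b[1:, 1]
    x4, y4 = b[:-1, 0], b[:-1, 1]
    areas = 0.5 * np.abs(x1 * y2 + x2 * y3 + x3 * y4 + x4 * y1
                         - x2 * y1 - x3 * y2 - x4 * y3 - x1 * y4)
    return float(areas.sum())


def area_under_curve(curve: PVCurve) -> float:
    """Trapezoid area under pressure(volume)."""
    return float(np.trapezoid(curve.pressures, curve.volumes))


def goodness_report(target, sim: ForwardResult, x_dat,
                    scalings, V_ed_dat: float, p_ed_dat: float) -> ConvergenceReport:
    """Assemble the error estimates for one fitting iteration.

    ``target`` is a :class:`KlotzCurve` or an already-sampled target
    :class:`PVCurve` (whose first point is the predicted unloaded volume).
    ``scalings`` provides ``a_scale``/``b_scale`` attributes (or a tuple).
    """
    pv = sim.pv_curve
    V0_sim = float(pv.volumes[0])
    V_ed_sim = float(pv.volumes[-1])
    if isinstance(target, KlotzCurve):
        V0_tgt = target.V0_klotz
        tgt_curve = sample_klotz(target, max(len(pv.pressures) - 1, 2),
                                 p_ed=float(pv.pressures[-1]))
    else:
        V0_tgt = float(target.volumes[0])
        tgt_curve = target
    r_V0 = abs(V0_tgt - V0_sim)
    r_ed = abs(V_ed_dat - V_ed_sim)
    r_nodal = float(np.max(np.linalg.norm(sim.deformed_coords - x_dat.nodes,
                                          axis=1)))
    if isinstance(scalings, tuple):
        a_s, b_s = scalings
    else:
        a_s, b_s = scalings.a_scale, scalings.b_scale
    r_param = max(abs(1.0 - a_s), abs(1.0 - b_s))

    tgt_n = normalize_pv(tgt_curve, V_ed_dat, p_ed_dat)
    sim_n = normalize_pv(pv, V_ed_dat, p_ed_dat)
    r_An = area_between_curves(tgt_n, sim_n)
    A_tgt = area_under_curve(tgt_n)
    r_An_rel = 100.0 * r_An / A_tgt if A_tgt > 0 else np.inf
    return ConvergenceReport(
        r_V0=r_V0, r_ed=r_ed, r_nodal_inf=r_nodal, r_param=r_param,
        r_V0_rel=100.0 * r_V0 / V_ed_dat, r_An=r_An, r_An_rel=r_An_rel,
        A_klotz=A_tgt, V_ed_dat=V_ed_dat)


def check_convergence(report: ConvergenceReport,
                      recent: Sequence[ConvergenceReport] = ()) -> str:
    """Classify an iteration: 'converged', 'stagnated' or 'continue'.

    Stagnation: the parameter update is already negligible
    (r_param < eps_param) while some other criterion has kept failing for
    the last ``STAGNATION_WINDOW`` iterations (including this one).
    """
    if report.converged:
        return "converged"
    window = list(recent[-(STAGNATION_WINDOW - 1):]) + [report]
    if len(window) >= STAGNATION_WINDOW and all(
            r.r_param < r.eps_param and not r.converged for r in window):
        return "stagnated"
    return "continue"
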