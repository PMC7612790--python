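"""Empirical single-beat end-diastolic pressure-volume relation (EDPVR).

From one measured end-diastolic pressure-volume pair (p_ed, V_ed) the
classic single-beat method predicts the whole passive filling curve as a
power law ``p = alpha * V^beta`` (pressures in mmHg internally):

* unloaded volume   ``V0 = V_ed * (0.6 - 0.006 * P_ed[mmHg])``
* 30-mmHg volume    ``V30 = V0 + (V_ed - V0) / (P_ed / An)^(1/Bn)``
  with the population constants ``An = 28.2 mmHg``, ``Bn = 2.79`` of the
  normalized curve (overridable),
* exponent          ``beta = log(P_ed/30) / log(V_ed/V30)``,
* coefficient       ``alpha = 30 / V30^beta``,

so the curve passes exactly through the measured pair.  The package
interface is in kPa / mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .solver import PVCurve
from .units import kpa_to_mmhg, mmhg_to_kpa

__all__ = ["KlotzCurve", "build_klotz", "sample_klotz", "normalize_pv",
           "KLOTZ_AN_MMHG", "KLOTZ_BN"]

KLOTZ_AN_MMHG = 28.2
KLOTZ_BN = 2.79


@dataclass(frozen=True)
class KlotzCurve:
    """Single-beat empirical EDPVR anchored at one measured PV-pair."""

    V_ed_dat: float        # mL
    p_ed_dat: float        # kPa
    V0_klotz: float        # mL
    V30: float             # mL
    alpha: float           # mmHg / mL^beta
    beta: float
    An: float = KLOTZ_AN_MMHG
    Bn: float = KLOTZ_BN

    def pressure_at(self, volume) -> np.ndarray:
        """EDPVR pressure (kPa) at volume (mL)."""
        v = np.asarray(volume, float)
        return mmhg_to_kpa(self.alpha * np.power(v, self.beta))

    def volume_at(self, pressure) -> np.ndarray:
        """Inverse of the power law (mL at kPa); V(0) := V0_klotz."""
        p = np.atleast_1d(np.asarray(pressure, float))
        p_mmhg = kpa_to_mmhg(p)
        with np.errstate(divide="ignore"):
            v = np.power(p_mmhg / self.alpha, 1.0 / self.beta)
        v = np.where(p_mmhg <= 0.0, self.V0_klotz, v)
        return v if np.ndim(pressure) else float(v[0])


def build_klotz(V_ed_dat: float, p_ed_dat: float,
                An: float = KLOTZ_AN_MMHG, Bn: float = KLOTZ_BN) -> KlotzCurve:
    """Construct the single-beat EDPVR from one measured pair (mL, kPa)."""
    if V_ed_dat <= 0:
        raise ValueError("V_ed must be > 0")
    if p_ed_dat <= 0:
        raise ValueError("p_ed must be > 0")
    P_ed = kpa_to_mmhg(p_ed_dat)
    V0 = V_ed_dat * (0.6 - 0.006 * P_ed)
    if V0 <= 0:
        raise ValueError(
            f"measured pressure {p_ed_dat} kPa ({P_ed:.1f} mmHg) too large: "
            "predicted unloaded volume is non-positive")
    if np.isclose(P_ed, 30.0):
        raise ValueError("measured pressure of exactly 30 mmHg is degenerate "
                         "for the single-beat power law")
    V30 = V0 + (V_ed_dat - V0) / (P_ed / An) ** (1.0 / Bn)
    beta = np.log(P_ed / 30.0) / np.log(V_ed_dat / V30)
    alpha = 30.0 / V30 ** beta
    return KlotzCurve(V_ed_dat, p_ed_dat, V0, V30, alpha, beta, An, Bn)


def sample_klotz(curve: KlotzCurve, n_ls: int, p_ed: float | None = None) -> PVCurve:
    """Sample the EDPVR at n_ls + 1 equidistant pressures in [0, p_ed].

    The p = 0 point is the predicted unloaded volume V0_klotz.
    """
    if n_ls < 2:
        raise ValueError("n_ls must be >= 2")
    p_ed = curve.p_ed_dat if p_ed is None else p_ed
    pressures = np.linspace(0.0, p_ed, n_ls + 1)
    volumes = curve.volume_at(pressures)
    return PVCurve(pressures, volumes)


def normalize_pv(curve: PVCurve, V_ed: float, p_ed: float) -> PVCurve:
    """Normalize a PV-curve by (V_ed, p_ed); the measured point maps to (1,1)."""
    if V_ed == 0 or p_ed == 0:
        raise ValueError("cannot normalize by zero V_ed or p_ed")
    return PVCurve(curve.pressures / p_ed, curve.volumes / V_ed)
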