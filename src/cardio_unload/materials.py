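"""Hyperelastic constitutive laws for passive myocardium.

The myocardium is modelled as a nonlinear, hyperelastic, nearly
incompressible, orthotropic material with local orthonormal axes
``f0`` (myofiber), ``s0`` (sheet) and ``n0`` (sheet-normal).  The strain
energy is split into a volumetric penalty and an isochoric/anisotropic part

    Psi(C) = U(J) + Psi_isc(C),      U(J) = kappa/2 * ln(J)^2,

with ``C = F^T F`` the right Cauchy-Green tensor and ``J = det F``.

Implemented material families
-----------------------------
* ``demiray``       -- isotropic exponential in the isochoric invariant I1bar.
* ``guccione``, ``usyk`` -- single Fung-type exponentials in the isochoric
  Green-Lagrange strain projections Ebar_ij.
* ``general_HO``, ``reduced_HO``, ``original_HO``, ``one_fiber_HO``,
  ``HO_dispersion`` -- separated Fung-type (Holzapfel-Ogden) exponentials in
  I1bar plus the *unsplit* anisotropic invariants I4f/I4s/I4n and
  I8fs/I8fn/I8sn.  Fourth invariants are clamped at 1 so that compressed
  fibers carry no anisotropic stress.  ``HO_dispersion`` replaces I4i
  (i in {f, s}) by the dispersed invariant
  I4i* = kappa_i * I1bar + (1 - 3 kappa_i) * I4i.

All functions operate on batches: a deformation state is an array of
deformation gradients of shape ``(n, 3, 3)`` with per-state material axes of
shape ``(n, 3)``.  Stress-like parameters ``a_(.)`` are in kPa, exponents
``b_(.)`` are dimensionless, the bulk modulus ``kappa`` is in kPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "MODEL_IDS",
    "MaterialParams",
    "Kinematics",
    "default_params",
    "strain_energy",
    "pk2_stress",
    "material_tangent",
]

MODEL_IDS = (
    "demiray",
    "guccione",
    "usyk",
    "general_HO",
    "reduced_HO",
    "original_HO",
    "HO_dispersion",
    "one_fiber_HO",
)

#: which named a/b parameters each model carries
_MODEL_KEYS = {
    "demiray": (("a",), ("b",)),
    "guccione": (("a",), ("b_ff", "b_ss", "b_nn", "b_fs", "b_fn", "b_ns")),
    "usyk": (("a",), ("b_ff", "b_ss", "b_nn", "b_fs", "b_fn", "b_ns")),
    "general_HO": (
        ("a", "a_f", "a_s", "a_n", "a_fs", "a_fn", "a_sn"),
        ("b", "b_f", "b_s", "b_n", "b_fs", "b_fn", "b_sn"),
    ),
    "reduced_HO": (("a", "a_f", "a_n", "a_fn"), ("b", "b_f", "b_n", "b_fn")),
    "original_HO": (("a", "a_f", "a_s", "a_fs"), ("b", "b_f", "b_s", "b_fs")),
    "HO_dispersion": (("a", "a_f", "a_s", "a_fs"), ("b", "b_f", "b_s", "b_fs")),
    "one_fiber_HO": (("a", "a_f"), ("b", "b_f")),
}

_DEFAULTS = {
    "demiray": {"a": 1.0, "b": 6.5},
    "guccione": {
        "a": 0.876,
        "b_ff": 18.48, "b_ss": 3.58, "b_nn": 3.58,
        "b_fs": 3.58, "b_fn": 1.627, "b_ns": 1.627,
    },
    "usyk": {
        "a": 0.88,
        "b_ff": 5.0, "b_ss": 6.0, "b_nn": 3.0,
        "b_fs": 10.0, "b_fn": 2.0, "b_ns": 2.0,
    },
    "general_HO": {
        "a": 0.180, "b": 9.762,
        "a_f": 2.204, "b_f": 21.597,
        "a_s": 0.098, "b_s": 49.878,
        "a_n": 0.508, "b_n": 27.719,
        "a_fs": 1.291, "b_fs": 5.295,
        "a_fn": 1.345, "b_fn": 2.017,
        "a_sn": 0.947, "b_sn": 4.514,
    },
    "reduced_HO": {
        "a": 0.809, "b": 7.474,
        "a_f": 1.911, "b_f": 22.063,
        "a_n": 0.227, "b_n": 34.802,
        "a_fn": 0.547, "b_fn": 5.691,
    },
    "original_HO": {
        "a": 0.33, "b": 9.242,
        "a_f": 18.535, "b_f": 15.972,
        "a_s": 2.564, "b_s": 10.446,
        "a_fs": 0.417, "b_fs": 11.602,
    },
    "HO_dispersion": {
        "a": 0.4, "b": 6.55,
        "a_f": 3.05, "b_f": 29.05,
        "a_s": 1.25, "b_s": 36.65,
        "a_fs": 0.15, "b_fs": 6.28,
    },
    "one_fiber_HO": {
        "a": 0.809, "b": 7.474,
        "a_f": 1.911, "b_f": 22.063,
    },
}

DEFAULT_BULK_MODULUS = 650.0  # kPa, penalty formulation with linear tets


class InvertedElementError(RuntimeError):
    """Raised when a deformation state has ``J <= 0``."""


@dataclass(frozen=True)
class MaterialParams:
    """A constitutive law identifier plus its named parameter vector.

    ``a`` maps stress-like parameter names (kPa) to values, ``b`` the
    dimensionless exponents.  ``kappa`` is the bulk modulus (kPa);
    ``kappa_f``/``kappa_s`` are the collagen-dispersion parameters used by
    ``HO_dispersion`` only.
    """

    model_id: str
    a: Mapping[str, float]
    b: Mapping[str, float]
    kappa: float = DEFAULT_BULK_MODULUS
    kappa_f: float | None = None
    kappa_s: float | None = None

    def __post_init__(self):
        if self.model_id not in MODEL_IDS:
            raise KeyError(f"unknown material model {self.model_id!r}")
        a_keys, b_keys = _MODEL_KEYS[self.model_id]
        if set(self.a) != set(a_keys):
            raise ValueError(
                f"{self.model_id}: expected a-parameters {a_keys}, got {tuple(self.a)}"
            )
        if set(self.b) != set(b_keys):
            raise ValueError(
                f"{self.model_id}: expected b-parameters {b_keys}, got {tuple(self.b)}"
            )
        if any(v <= 0 for v in self.a.values()):
            raise ValueError("all a(.) parameters must be > 0")
        if any(v <= 0 for v in self.b.values()):
            raise ValueError("all b(.) parameters must be > 0")
        if not self.kappa > 0:
            raise ValueError("bulk modulus kappa must be > 0")
        if self.model_id == "HO_dispersion":
            if self.kappa_f is None or self.kappa_s is None:
                raise ValueError("HO_dispersion requires kappa_f and kappa_s")
        object.__setattr__(self, "a", dict(self.a))
        object.__setattr__(self, "b", dict(self.b))

    def scaled(self, a_scale: float, b_scale: float) -> "MaterialParams":
        """Return a copy with every a(.) and b(.) multiplied by the scales.

        ``kappa`` (and the dispersion parameters) are deliberately not
        touched: they are numerical/structural, not fitted.
        """
        return replace(
            self,
            a={k: v * a_scale for k, v in self.a.items()},
            b={k: v * b_scale for k, v in self.b.items()},
        )

    def with_kappa(self, kappa: float) -> "MaterialParams":
        return replace(self, kappa=kappa)

    def to_dict(self) -> dict:
        d = {"model_id": self.model_id, "kappa": self.kappa}
        d.update(self.a)
        d.update(self.b)
        if self.kappa_f is not None:
            d["kappa_f"] = self.kappa_f
            d["kappa_s"] = self.kappa_s
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, float | str]) -> "MaterialParams":
        d = dict(d)
        model_id = str(d.pop("model_id"))
        kappa = float(d.pop("kappa", DEFAULT_BULK_MODULUS))
        kappa_f = d.pop("kappa_f", None)
        kappa_s = d.pop("kappa_s", None)
        a_keys, b_keys = _MODEL_KEYS[model_id]
        a = {k: float(d[k]) for k in a_keys}
        b = {k: float(d[k]) for k in b_keys}
        return cls(model_id, a, b, kappa,
                   None if kappa_f is None else float(kappa_f),
                   None if kappa_s is None else float(kappa_s))


def default_params(model_id: str, kappa: float = DEFAULT_BULK_MODULUS) -> MaterialParams:
    """Literature default parameters for ``model_id``."""
    if model_id not in MODEL_IDS:
        raise KeyError(f"unknown material model {model_id!r}")
    a_keys, b_keys = _MODEL_KEYS[model_id]
    vals = _DEFAULTS[model_id]
    a = {k: vals[k] for k in a_keys}
    b = {k: vals[k] for k in b_keys}
    kf, ks = (0.08, 0.09) if model_id == "HO_dispersion" else (None, None)
    return MaterialParams(model_id, a, b, kappa, kf, ks)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def _det3(A: np.ndarray) -> np.ndarray:
    """Batched 3x3 determinant (faster than LAPACK for small blocks)."""
    return (A[..., 0, 0] * (A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1])
            - A[..., 0, 1] * (A[..., 1, 0] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 0])
            + A[..., 0, 2] * (A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]))


def _inv3(A: np.ndarray, det: np.ndarray) -> np.ndarray:
    """Batched 3x3 inverse via the adjugate."""
    out = np.empty_like(A)
    out[..., 0, 0] = A[..., 1, 1] * A[..., 2, 2] - A[..., 1, 2] * A[..., 2, 1]
    out[..., 0, 1] = A[..., 0, 2] * A[..., 2, 1] - A[..., 0, 1] * A[..., 2, 2]
    out[..., 0, 2] = A[..., 0, 1] * A[..., 1, 2] - A[..., 0, 2] * A[..., 1, 1]
    out[..., 1, 0] = A[..., 1, 2] * A[..., 2, 0] - A[..., 1, 0] * A[..., 2, 2]
    out[..., 1, 1] = A[..., 0, 0] * A[..., 2, 2] - A[..., 0, 2] * A[..., 2, 0]
    out[..., 1, 2] = A[..., 0, 2] * A[..., 1, 0] - A[..., 0, 0] * A[..., 1, 2]
    out[..., 2, 0] = A[..., 1, 0] * A[..., 2, 1] - A[..., 1, 1] * A[..., 2, 0]
    out[..., 2, 1] = A[..., 0, 1] * A[..., 2, 0] - A[..., 0, 0] * A[..., 2, 1]
    out[..., 2, 2] = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] * A[..., 1, 0]
    out /= det[..., None, None]
    return out


@dataclass
class Kinematics:
    """Batched deformation state derived from F (or directly from C).

    Arrays have leading batch dimension ``n``.  ``I4*`` fields store the raw
    (unclamped) invariants; clamping is applied inside the energy/stress
    routines so the clamp mask is available for the subgradient convention
    (zero anisotropic stress for I4 <= 1, kink resolved from below).
    """

    C: np.ndarray           # (n, 3, 3)
    J: np.ndarray           # (n,)
    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray
    Cinv: np.ndarray = field(init=False)
    I1bar: np.ndarray = field(init=False)

    def __post_init__(self):
        detC = _det3(self.C)
        if np.any(detC <= 0) or np.any(self.J <= 0):
            raise InvertedElementError("deformation state with J <= 0")
        self.Cinv = _inv3(self.C, detC)
        self.I1bar = self.J ** (-2.0 / 3.0) * np.trace(self.C, axis1=-2, axis2=-1)

    @classmethod
    def from_F(cls, F, f0, s0, n0) -> "Kinematics":
        F = np.asarray(F, float)
        if F.ndim == 2:
            F = F[None]
        f0, s0, n0 = (np.atleast_2d(np.asarray(v, float)) for v in (f0, s0, n0))
        J = _det3(F)
        if np.any(J <= 0):
            raise InvertedElementError("deformation gradient with det F <= 0")
        C = np.einsum("eki,ekj->eij", F, F)
        return cls(C, J, f0, s0, n0)

    @classmethod
    def from_C(cls, C, f0, s0, n0) -> "Kinematics":
        C = np.asarray(C, float)
        if C.ndim == 2:
            C = C[None]
        f0, s0, n0 = (np.atleast_2d(np.asarray(v, float)) for v in (f0, s0, n0))
        detC = _det3(C)
        if np.any(detC <= 0):
            raise InvertedElementError("right Cauchy-Green tensor with det C <= 0")
        return cls(C, np.sqrt(detC), f0, s0, n0)

    # -- invariants -------------------------------------------------------
    def I4(self, axis: str) -> np.ndarray:
        v = getattr(self, axis + "0")
        return np.einsum("ei,eij,ej->e", v, self.C, v)

    def I8(self, ax1: str, ax2: str) -> np.ndarray:
        v, w = getattr(self, ax1 + "0"), getattr(self, ax2 + "0")
        return np.einsum("ei,eij,ej->e", v, self.C, w)

    def Ebar(self, ax1: str, ax2: str) -> np.ndarray:
        """Isochoric Green-Lagrange strain projection Ebar_ij."""
        v, w = getattr(self, ax1 + "0"), getattr(self, ax2 + "0")
        cb = self.J ** (-2.0 / 3.0) * np.einsum("ei,eij,ej->e", v, self.C, w)
        delta = 1.0 if ax1 == ax2 else 0.0
        return 0.5 * (cb - delta)


def _sym_outer(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    return 0.5 * (np.einsum("ei,ej->eij", v, w) + np.einsum("ei,ej->eij", w, v))


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

_FUNG_PAIRS = (("f", "f"), ("s", "s"), ("n", "n"), ("f", "s"), ("f", "n"), ("n", "s"))
_HO_I4_AXES = {
    "general_HO": ("f", "s", "n"),
    "reduced_HO": ("f", "n"),
    "original_HO": ("f", "s"),
    "HO_dispersion": ("f", "s"),
    "one_fiber_HO": ("f",),
}
_HO_I8_AXES = {
    "general_HO": (("f", "s"), ("f", "n"), ("s", "n")),
    "reduced_HO": (("f", "n"),),
    "original_HO": (("f", "s"),),
    "HO_dispersion": (("f", "s"),),
    "one_fiber_HO": (),
}


def _exp_term(a: float, b: float, arg: np.ndarray) -> np.ndarray:
    """a/(2b) * (exp(b*arg) - 1) evaluated stably."""
    return a / (2.0 * b) * np.expm1(b * arg)


def strain_energy(params: MaterialParams, kin: Kinematics) -> np.ndarray:
    """Strain-energy density Psi = U(J) + Psi_isc, in kPa."""
    psi = 0.5 * params.kappa * np.log(kin.J) ** 2
    m = params.model_id

    if m == "demiray":
        psi = psi + _exp_term(params.a["a"], params.b["b"], kin.I1bar - 3.0)
    elif m in ("guccione", "usyk"):
        Q = np.zeros_like(kin.J)
        for i, j in _FUNG_PAIRS:
            key = f"b_{i}{j}"
            coef = 1.0 if i == j else 2.0
            Q = Q + coef * params.b[key] * kin.Ebar(i, j) ** 2
        psi = psi + 0.5 * params.a["a"] * np.expm1(Q)
    else:  # HO family
        psi = psi + _exp_term(params.a["a"], params.b["b"], kin.I1bar - 3.0)
        for ax in _HO_I4_AXES[m]:
            I4 = np.maximum(kin.I4(ax), 1.0)
            if m == "HO_dispersion":
                kap = params.kappa_f if ax == "f" else params.kappa_s
                I4 = kap * kin.I1bar + (1.0 - 3.0 * kap) * I4
            psi = psi + _exp_term(params.a[f"a_{ax}"], params.b[f"b_{ax}"], (I4 - 1.0) ** 2)
        for ax1, ax2 in _HO_I8_AXES[m]:
            I8 = kin.I8(ax1, ax2)
            key = f"{ax1}{ax2}"
            psi = psi + _exp_term(params.a[f"a_{key}"], params.b[f"b_{key}"], I8 ** 2)
    return psi


# ---------------------------------------------------------------------------
# second Piola-Kirchhoff stress (analytic)
# ---------------------------------------------------------------------------

def pk2_stress(params: MaterialParams, kin: Kinematics) -> np.ndarray:
    """S = 2 dPsi/dC, shape (n, 3, 3), in kPa.

    Anisotropic HO terms use the unsplit C; the I4 clamp contributes zero
    stress for I4 <= 1.  Fung-type terms use the isochoric projections.
    """
    n = kin.J.shape[0]
    J23 = kin.J ** (-2.0 / 3.0)
    eye = np.broadcast_to(np.eye(3), (n, 3, 3))

    # volumetric: kappa ln(J) C^-1
    S = params.kappa * np.log(kin.J)[:, None, None] * kin.Cinv

    # dI1bar/dC = J^(-2/3) I - (1/3) I1bar C^-1
    dI1bar = J23[:, None, None] * eye - (kin.I1bar / 3.0)[:, None, None] * kin.Cinv

    m = params.model_id
    if m == "demiray":
        g = params.a["a"] * np.exp(params.b["b"] * (kin.I1bar - 3.0))
        S = S + g[:, None, None] * dI1bar
    elif m in ("guccione", "usyk"):
        Q = np.zeros(n)
        for i, j in _FUNG_PAIRS:
            coef = 1.0 if i == j else 2.0
            Q = Q + coef * params.b[f"b_{i}{j}"] * kin.Ebar(i, j) ** 2
        eQ = np.exp(Q)
        for i, j in _FUNG_PAIRS:
            coef = 1.0 if i == j else 2.0
            Eij = kin.Ebar(i, j)
            # dPsi/dEbar_ij
            dpsi = params.a["a"] * coef * params.b[f"b_{i}{j}"] * Eij * eQ
            v, w = getattr(kin, i + "0"), getattr(kin, j + "0")
            cvw = np.einsum("ei,eij,ej->e", v, kin.C, w)
            dE = 0.5 * J23[:, None, None] * (
                _sym_outer(v, w) - (cvw / 3.0)[:, None, None] * kin.Cinv
            )
            S = S + 2.0 * dpsi[:, None, None] * dE
    else:
        g = params.a["a"] * np.exp(params.b["b"] * (kin.I1bar - 3.0))
        S = S + g[:, None, None] * dI1bar
        for ax in _HO_I4_AXES[m]:
            raw = kin.I4(ax)
            active = raw > 1.0
            I4c = np.maximum(raw, 1.0)
            v = getattr(kin, ax + "0")
            struct = np.einsum("ei,ej->eij", v, v)
            a_i, b_i = params.a[f"a_{ax}"], params.b[f"b_{ax}"]
            if m == "HO_dispersion":
                kap = params.kappa_f if ax == "f" else params.kappa_s
                I4d = kap * kin.I1bar + (1.0 - 3.0 * kap) * I4c
                dpsi = a_i * (I4d - 1.0) * np.exp(b_i * (I4d - 1.0) ** 2)
                dI4 = kap * dI1bar + (1.0 - 3.0 * kap) * np.where(
                    active[:, None, None], struct, 0.0
                )
                S = S + 2.0 * dpsi[:, None, None] * dI4
            else:
                dpsi = a_i * (I4c - 1.0) * np.exp(b_i * (I4c - 1.0) ** 2)
                S = S + 2.0 * np.where(active, dpsi, 0.0)[:, None, None] * struct
        for ax1, ax2 in _HO_I8_AXES[m]:
            I8 = kin.I8(ax1, ax2)
            key = f"{ax1}{ax2}"
            dpsi = params.a[f"a_{key}"] * I8 * np.exp(params.b[f"b_{key}"] * I8 ** 2)
            v, w = getattr(kin, ax1 + "0"), getattr(kin, ax2 + "0")
            S = S + 2.0 * dpsi[:, None, None] * _sym_outer(v, w)
    return S


# ---------------------------------------------------------------------------
# consistent tangent (directed finite differences of the analytic stress)
# ---------------------------------------------------------------------------

_SYM_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))


def material_tangent(params: MaterialParams, kin: Kinematics,
                     rel_step: float = 1e-6) -> np.ndarray:
    """Elasticity tensor CC = 2 dS/dC with minor symmetries, shape (n,3,3,3,3).

    Computed by central differences of the analytic ``pk2_stress`` along the
    six symmetric directions of C; the step is scaled by ||C||.  At the I4
    clamp kink the one-sided branches average, consistent with the
    zero-from-below subgradient convention used in the stress.
    """
    C = kin.C
    n = C.shape[0]
    h = rel_step * np.maximum(np.linalg.norm(C, axis=(1, 2)), 1.0)
    # all 6 symmetric directions, +h and -h, in one batched stress call
    pert = np.empty((12, n, 3, 3))
    for d, (k, l) in enumerate(_SYM_PAIRS):
        dC = np.zeros((n, 3, 3))
        dC[:, k, l] = 0.5 * h
        dC[:, l, k] += 0.5 * h
        pert[d] = C + dC
        pert[6 + d] = C - dC
    big = Kinematics.from_C(pert.reshape(12 * n, 3, 3),
                            np.tile(kin.f0, (12, 1)), np.tile(kin.s0, (12, 1)),
                            np.tile(kin.n0, (12, 1)))
    Sbig = pk2_stress(params, big).reshape(12, n, 3, 3)
    CC = np.zeros((n, 3, 3, 3, 3))
    for d, (k, l) in enumerate(_SYM_PAIRS):
        # dS/dC_kl (the symmetrized direction carries the 1/2 off-diagonal)
        dS = (Sbig[d] - Sbig[6 + d]) / (2.0 * h[:, None, None])
        CC[:, :, :, k, l] = 2.0 * dS
        if k != l:
            CC[:, :, :, l, k] = 2.0 * dS
    return CC
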