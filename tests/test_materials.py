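"""Constitutive laws: table defaults, energies, stresses, tangents."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cardio_unload.materials import (MODEL_IDS, InvertedElementError,
                                     Kinematics, MaterialParams,
                                     default_params, material_tangent,
                                     pk2_stress, strain_energy)
from conftest import random_deformations, random_frames


def kin_of(F, rng=None, n=None):
    if F.ndim == 2:
        F = F[None]
    n = F.shape[0]
    if rng is None:
        f0 = np.tile([1.0, 0, 0], (n, 1))
        s0 = np.tile([0, 1.0, 0], (n, 1))
        n0 = np.tile([0, 0, 1.0], (n, 1))
    else:
        f0, s0, n0 = random_frames(rng, n)
    return Kinematics.from_F(F, f0, s0, n0)


def fd_stress(params, C, axes, h=1e-6):
    """Independent central-difference oracle: 2 dPsi/dC."""
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            dC = np.zeros((3, 3))
            dC[i, j] += 0.5 * h
            dC[j, i] += 0.5 * h
            ep = strain_energy(params, Kinematics.from_C(C + dC, *axes))[0]
            em = strain_energy(params, Kinematics.from_C(C - dC, *axes))[0]
            d = (ep - em) / h
            S[i, j] = S[j, i] = d if i != j else 2 * d
    # diagonal: dC_ii of magnitude h -> derivative*2 handled above
    for i in range(3):
        dC = np.zeros((3, 3))
        dC[i, i] = h
        ep = strain_energy(params, Kinematics.from_C(C + dC, *axes))[0]
        em = strain_energy(params, Kinematics.from_C(C - dC, *axes))[0]
        S[i, i] = 2 * (ep - em) / (2 * h)
    return S


# ---------------------------------------------------------------------------
# default parameter tables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model_id,expected", [
    ("reduced_HO", {"a": 0.809, "b": 7.474, "a_f": 1.911, "b_f": 22.063,
                    "a_n": 0.227, "b_n": 34.802, "a_fn": 0.547,
                    "b_fn": 5.691}),
    ("demiray", {"a": 1.0, "b": 6.5}),
    ("guccione", {"a": 0.876, "b_ff": 18.48, "b_ss": 3.58, "b_nn": 3.58,
                  "b_fs": 3.58, "b_fn": 1.627, "b_ns": 1.627}),
    ("usyk", {"a": 0.88, "b_ff": 5.0, "b_ss": 6.0, "b_nn": 3.0,
              "b_fs": 10.0, "b_fn": 2.0, "b_ns": 2.0}),
    ("original_HO", {"a": 0.33, "b": 9.242, "a_f": 18.535, "b_f": 15.972,
                     "a_s": 2.564, "b_s": 10.446, "a_fs": 0.417,
                     "b_fs": 11.602}),
    ("one_fiber_HO", {"a": 0.809, "b": 7.474, "a_f": 1.911, "b_f": 22.063}),
])
def test_default_params_literature_values(model_id, expected):
    p = default_params(model_id)
    merged = {**p.a, **p.b}
    assert merged == pytest.approx(expected)


def test_dispersion_defaults():
    p = default_params("HO_dispersion")
    assert p.kappa_f == pytest.approx(0.08)
    assert p.kappa_s == pytest.approx(0.09)
    assert p.a["a_fs"] == pytest.approx(0.15)


def test_unknown_model_raises():
    with pytest.raises(KeyError):
        default_params("neo_hookean")


def test_param_validation():
    with pytest.raises(ValueError):
        MaterialParams("demiray", {"a": -1.0}, {"b": 6.5})
    with pytest.raises(ValueError):
        MaterialParams("demiray", {"a": 1.0}, {"b": 6.5}, kappa=0.0)
    with pytest.raises(ValueError):
        MaterialParams("demiray", {"a": 1.0, "a_f": 2.0}, {"b": 6.5})


def test_round_trip_dict():
    p = default_params("general_HO", kappa=1000.0)
    q = MaterialParams.from_dict(p.to_dict())
    assert q == p


# ---------------------------------------------------------------------------
# strain energy
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_energy_zero_at_identity(model_id):
    kin = kin_of(np.eye(3))
    assert strain_energy(default_params(model_id), kin)[0] == pytest.approx(0.0, abs=1e-14)


def test_demiray_incompressible_uniaxial_closed_form():
    lam = 1.1
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    p = default_params("demiray")
    kin = kin_of(F)
    I1 = lam ** 2 + 2.0 / lam
    expected = p.a["a"] / (2 * p.b["b"]) * (np.exp(p.b["b"] * (I1 - 3)) - 1)
    assert strain_energy(p, kin)[0] == pytest.approx(expected, rel=1e-12)


def test_compressed_fiber_contributes_nothing():
    # fiber-direction compression: the anisotropic term is clamped out, so
    # the one-fiber law coincides with its isotropic part
    lam = 0.9
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    ho = default_params("one_fiber_HO")
    iso = MaterialParams("demiray", {"a": ho.a["a"]}, {"b": ho.b["b"]},
                         kappa=ho.kappa)
    assert strain_energy(ho, kin_of(F))[0] == pytest.approx(
        strain_energy(iso, kin_of(F))[0], rel=1e-12)


def test_inverted_state_raises():
    with pytest.raises(InvertedElementError):
        kin_of(np.diag([1.0, 1.0, -1.0]))


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_energy_monotone_along_equibiaxial(model_id):
    """Psi strictly increases for lambda in [1, 1.3] (defaults)."""
    lams = np.linspace(1.0, 1.3, 16)
    F = np.zeros((16, 3, 3))
    for i, lam in enumerate(lams):
        F[i] = np.diag([lam, lam, lam ** -2])
    psi = strain_energy(default_params(model_id), kin_of(F))
    assert np.all(np.diff(psi) > 0)


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_frame_indifference(model_id, rng):
    F = random_deformations(rng, 8)
    f0, s0, n0 = random_frames(rng, 8)
    psi = strain_energy(default_params(model_id),
                        Kinematics.from_F(F, f0, s0, n0))
    # random rotations via QR
    Q, _ = np.linalg.qr(rng.standard_normal((8, 3, 3)))
    det = np.linalg.det(Q)
    Q[det < 0, :, 0] *= -1.0
    QF = np.einsum("eij,ejk->eik", Q, F)
    psi_rot = strain_energy(default_params(model_id),
                            Kinematics.from_F(QF, f0, s0, n0))
    np.testing.assert_allclose(psi_rot, psi, rtol=1e-10, atol=1e-12)


@given(s=st.floats(0.2, 5.0))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_isochoric_energy_scales_linearly_in_a(s):
    """Multiplying all a(.) by s multiplies Psi_isc by s exactly."""
    rng = np.random.default_rng(7)
    F = random_deformations(rng, 4)
    f0, s0_, n0 = random_frames(rng, 4)
    kin = Kinematics.from_F(F, f0, s0_, n0)
    p = default_params("reduced_HO")
    vol = 0.5 * p.kappa * np.log(kin.J) ** 2
    base = strain_energy(p, kin) - vol
    scaled = strain_energy(p.scaled(s, 1.0), kin) - vol
    np.testing.assert_allclose(scaled, s * base, rtol=1e-10, atol=1e-12)


# ---------------------------------------------------------------------------
# stress and tangent
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_pk2_zero_at_identity(model_id):
    S = pk2_stress(default_params(model_id), kin_of(np.eye(3)))
    np.testing.assert_allclose(S[0], 0.0, atol=1e-12)


@pytest.mark.parametrize("model_id", MODEL_IDS)
def test_pk2_matches_fd_of_energy(model_id, rng):
    F = random_deformations(rng, 5)
    f0, s0, n0 = random_frames(rng, 5)
    kin = Kinematics.from_F(F, f0, s0, n0)
    S = pk2_stress(default_params(model_id), kin)
    for e in range(5):
        axes = (f0[e:e + 1], s0[e:e + 1], n0[e:e + 1])
        S_fd = fd_stress(default_params(model_id), kin.C[e], axes)
        np.testing.assert_allclose(S[e], S_fd, rtol=1e-5, atol=1e-8)


def test_pure_volumetric_pressure_recovered():
    """F = alpha*I with the isochoric part inactive: S = kappa ln(J) C^-1."""
    alpha = 1.05
    p = default_params("demiray")
    kin = kin_of(alpha * np.eye(3))
    S = pk2_stress(p, kin)[0]
    J = alpha ** 3
    np.testing.assert_allclose(S, p.kappa * np.log(J) / alpha ** 2 * np.eye(3),
                               rtol=1e-12)


@pytest.mark.parametrize("model_id", ["demiray", "reduced_HO", "guccione"])
def test_tangent_matches_fd_of_stress(model_id, rng):
    F = random_deformations(rng, 4)
    f0, s0, n0 = random_frames(rng, 4)
    kin = Kinematics.from_F(F, f0, s0, n0)
    params = default_params(model_id)
    CC = material_tangent(params, kin)
    h = 2e-5
    for (k, l) in ((0, 0), (0, 1), (1, 2), (2, 2)):
        dC = np.zeros_like(kin.C)
        dC[:, k, l] += 0.5 * h
        dC[:, l, k] += 0.5 * h
        Sp = pk2_stress(params, Kinematics.from_C(kin.C + dC, f0, s0, n0))
        Sm = pk2_stress(params, Kinematics.from_C(kin.C - dC, f0, s0, n0))
        # (Sp - Sm)/h = 2 * d S / d C_kl (symmetrized) = CC[..., k, l]
        dS = (Sp - Sm) / h
        np.testing.assert_allclose(dS, CC[:, :, :, k, l], rtol=1e-4, atol=1e-6)


def test_tangent_fiber_block_zero_when_clamped():
    """Compressed fiber: no anisotropic stiffness along f0 x f0."""
    lam = 0.92
    F = np.diag([lam, lam ** -0.5, lam ** -0.5])
    ho = default_params("one_fiber_HO")
    iso = MaterialParams("demiray", {"a": ho.a["a"]}, {"b": ho.b["b"]},
                         kappa=ho.kappa)
    CC_ho = material_tangent(ho, kin_of(F))
    CC_iso = material_tangent(iso, kin_of(F))
    np.testing.assert_allclose(CC_ho, CC_iso, rtol=1e-6, atol=1e-9)


def test_tangent_isotropic_positive_definite_at_identity():
    CC = material_tangent(default_params("demiray"), kin_of(np.eye(3)))[0]
    rng = np.random.default_rng(3)
    for _ in range(10):
        e = rng.standard_normal((3, 3))
        e = 0.5 * (e + e.T)
        quad = np.einsum("ij,ijkl,kl->", e, CC, e)
        assert quad > 0
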