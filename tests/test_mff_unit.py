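"""Model-function fitting, scalings and parameter updates (no FE solves)."""

import numpy as np
import pytest

from cardio_unload.klotz import build_klotz, sample_klotz
from cardio_unload.materials import default_params
from cardio_unload.mff import (ModelFunctionFit, ScalePair, apply_scalings,
                               compute_scalings, fit_model_function,
                               model_function, run_mff)
from cardio_unload.solver import PVCurve


def fit_of(a, b):
    return ModelFunctionFit(a, b, 80.0, 0.0)


def test_model_function_anchored_at_x0():
    for a, b in ((1.0, 5.0), (0.3, 12.0)):
        assert model_function(80.0, 80.0, a, b) == 0.0


def test_exact_model_recovery():
    """Data generated by the model function itself is fitted to 1e-6."""
    a_true, b_true, x0 = 2.0, 6.0, 80.0
    vols = np.linspace(85, 140, 10)
    pres = model_function(vols, x0, a_true, b_true)
    pv = PVCurve(np.concatenate([[0.0], pres]),
                 np.concatenate([[x0], vols]))
    fit = fit_model_function(pv, x0)
    assert fit.a_fit == pytest.approx(a_true, rel=1e-6)
    assert fit.b_fit == pytest.approx(b_true, rel=1e-6)


def test_fit_to_klotz_curve_is_positive():
    for V_ed, p_ed in ((159.27, 1.07), (220.46, 2.8), (92.86, 0.61)):
        curve = build_klotz(V_ed, p_ed)
        fit = fit_model_function(sample_klotz(curve, 100), curve.V0_klotz)
        assert fit.a_fit > 0
        assert fit.b_fit > 0


def test_fit_rejects_bad_input():
    pv = PVCurve(np.array([0.0, 0.5, 1.0]), np.array([80.0, 90.0, 95.0]))
    with pytest.raises(ValueError):
        fit_model_function(pv, -1.0)
    with pytest.raises(ValueError):
        fit_model_function(pv, 80.0)  # only 2 points above p = 0
    bad = PVCurve(np.array([0.0, 0.3, 0.6, 1.0]),
                  np.array([80.0, np.nan, 90.0, 95.0]))
    with pytest.raises(ValueError):
        fit_model_function(bad, 80.0)


def test_scalings_identity():
    s = compute_scalings(fit_of(1.0, 5.0), fit_of(1.0, 5.0))
    assert (s.a_scale, s.b_scale) == (1.0, 1.0)
    assert not s.a_clamped and not s.b_clamped


def test_scalings_absolute_value_of_b_sim():
    """A concave simulated curve gives b_sim < 0; |b_sim| is used."""
    s = compute_scalings(fit_of(1.0, 6.0), fit_of(1.0, -3.0))
    assert s.b_scale == pytest.approx(2.0)


def test_scalings_clamped_to_bounding_interval():
    s = compute_scalings(fit_of(10.0, 5.0), fit_of(1.0, 5.0))
    assert s.a_scale == 5.0 and s.a_clamped
    s = compute_scalings(fit_of(0.1, 0.5), fit_of(1.0, 5.0))
    assert s.a_scale == pytest.approx(0.2) and s.a_clamped
    assert s.b_scale == pytest.approx(0.2) and s.b_clamped


def test_scalings_require_positive_a_sim():
    with pytest.raises(ValueError):
        compute_scalings(fit_of(1.0, 5.0), fit_of(-0.5, 5.0))


def test_apply_scalings_elementwise():
    p = apply_scalings(default_params("reduced_HO"), ScalePair(0.5, 2.0))
    assert p.a["a"] == pytest.approx(0.4045)
    assert p.b["b"] == pytest.approx(14.948)
    assert p.a["a_fn"] == pytest.approx(0.2735)
    assert p.b["b_n"] == pytest.approx(69.604)
    assert p.kappa == default_params("reduced_HO").kappa


def test_apply_scalings_identity_and_composition():
    p0 = default_params("reduced_HO")
    assert apply_scalings(p0, ScalePair(1.0, 1.0)) == p0
    p1 = apply_scalings(apply_scalings(p0, ScalePair(0.5, 2.0)),
                        ScalePair(0.4, 1.5))
    p2 = apply_scalings(p0, ScalePair(0.2, 3.0))
    for key in p0.a:
        assert p1.a[key] == pytest.approx(p2.a[key], rel=1e-12)
    for key in p0.b:
        assert p1.b[key] == pytest.approx(p2.b[key], rel=1e-12)


def test_run_mff_rejects_degenerate_target(lv_mesh_tiny):
    """A zero measured pressure is refused before any FE solve."""
    with pytest.raises(ValueError):
        run_mff(lv_mesh_tiny, 0.0, 150.0, default_params("reduced_HO"))
    with pytest.raises(ValueError):
        run_mff(lv_mesh_tiny, 1.0, -5.0, default_params("reduced_HO"))


def test_run_mff_warns_on_inconsistent_ved(lv_mesh_tiny):
    from cardio_unload.mesh import cavity_volume
    v = cavity_volume(lv_mesh_tiny)
    with pytest.warns(UserWarning, match="deviates"):
        try:
            run_mff(lv_mesh_tiny, 1.0, 2.0 * v,
                    default_params("reduced_HO"), max_iter=0)
        except Exception:
            pass
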