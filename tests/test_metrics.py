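"""Area-between-curves metric, error reports, convergence/stagnation."""

import numpy as np
import pytest

from cardio_unload.metrics import (ConvergenceReport, area_between_curves,
                                   check_convergence)
from cardio_unload.solver import PVCurve


def seg(y, x0=0.0, x1=1.0, n=2):
    """Horizontal polyline at height y as an (n, 2) array."""
    return np.column_stack([np.linspace(x0, x1, n), np.full(n, y)])


def test_identical_curves_zero_area():
    a = np.column_stack([np.linspace(0, 1, 10), np.linspace(0, 1, 10) ** 2])
    assert area_between_curves(a, a) == pytest.approx(0.0, abs=1e-14)


def test_unit_square():
    assert area_between_curves(seg(0.0), seg(1.0)) == pytest.approx(1.0)


def test_symmetry_and_nonnegativity():
    rng = np.random.default_rng(5)
    a = np.column_stack([np.sort(rng.random(12)), rng.random(12)])
    b = np.column_stack([np.sort(rng.random(12)), rng.random(12)])
    ab = area_between_curves(a, b)
    assert ab >= 0
    assert ab == pytest.approx(area_between_curves(b, a), rel=1e-14)


def test_agrees_with_trapezoid_on_dense_monotone_curves():
    """For two functions on a shared grid, the quadrilateral sum approaches
    the trapezoid integral of |f - g|."""
    x = np.linspace(0.0, 2.0, 400)
    f = np.exp(0.8 * x) - 1.0
    g = x ** 2
    area = area_between_curves(np.column_stack([x, f]),
                               np.column_stack([x, g]))
    ref = np.trapezoid(np.abs(f - g), x)
    assert area == pytest.approx(ref, rel=0.01)


def test_degenerate_curves_warn_and_return_zero():
    pts = np.tile([1.0, 2.0], (4, 1))
    with pytest.warns(UserWarning):
        assert area_between_curves(pts, pts) == 0.0


def test_resampling_of_unequal_pv_curves():
    p = np.linspace(0, 1, 21)
    a = PVCurve(p, 50 + 30 * p)
    b = PVCurve(np.linspace(0, 1, 11), 50 + 30 * np.linspace(0, 1, 11) + 5)
    # parallel lines offset by 5 mL over unit pressure span
    assert area_between_curves(a, b) == pytest.approx(5.0, rel=1e-6)


def make_report(**kw):
    base = dict(r_V0=0.0, r_ed=0.0, r_nodal_inf=0.0, r_param=0.0,
                r_V0_rel=0.0, r_An=0.0, r_An_rel=0.0, A_klotz=1.0,
                V_ed_dat=159.27)
    base.update(kw)
    return ConvergenceReport(**base)


def test_param_error_definition():
    # r_param = max(|1 - a_scale|, |1 - b_scale|) evaluated by the caller;
    # a report with r_param = 0.1 (e.g. scalings 1.1 / 0.95) must not pass
    rep = make_report(r_param=max(abs(1 - 1.1), abs(1 - 0.95)))
    assert rep.r_param == pytest.approx(0.1)
    assert not rep.converged


def test_relative_v0_hand_value():
    rep = make_report(r_V0=abs(87.9 - 88.2),
                      r_V0_rel=100.0 * abs(87.9 - 88.2) / 159.27)
    assert rep.r_V0_rel == pytest.approx(0.188, abs=2e-3)


def test_all_zero_report_converges():
    assert check_convergence(make_report()) == "converged"


def test_nodal_error_alone_blocks_convergence():
    rep = make_report(r_nodal_inf=0.2)
    assert check_convergence(rep) == "continue"


def test_volume_thresholds_scale_with_ved():
    lim = 0.5 / 100.0 * 159.27
    assert make_report(r_ed=0.9 * lim).converged
    assert not make_report(r_ed=1.1 * lim).converged
    assert not make_report(r_V0=1.1 * lim).converged


def test_stagnation_detection():
    """Negligible parameter updates with a persistently failing criterion
    over three iterations flag stagnation."""
    bad = make_report(r_param=1e-4, r_ed=5.0)
    assert check_convergence(bad, []) == "continue"
    assert check_convergence(bad, [bad]) == "continue"
    assert check_convergence(bad, [bad, bad]) == "stagnated"
    # a large parameter update inside the window resets the count
    moving = make_report(r_param=0.05, r_ed=5.0)
    assert check_convergence(bad, [moving, bad]) == "continue"
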