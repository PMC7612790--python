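"""Synthetic LV geometry, cavity volumes and mesh I/O."""

import numpy as np
import pytest

from cardio_unload.mesh import (EllipsoidSpec, Mesh, MeshParseError,
                                MeshValidationError, cavity_volume,
                                generate_lv_ellipsoid, generate_sphere_shell,
                                helix_angles, read_mesh,
                                transmural_coordinate,
                                truncated_ellipsoid_cavity_volume, write_mesh)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("split", ["kuhn", "crossed"])
def test_cavity_volume_matches_analytic(split):
    spec = EllipsoidSpec(resolution=6.0, split=split)
    m = generate_lv_ellipsoid(spec)
    exact = truncated_ellipsoid_cavity_volume(
        spec.long_axis, spec.short_axis, spec.base_fraction * spec.long_axis)
    assert cavity_volume(m) == pytest.approx(exact, rel=0.02)


def test_refinement_converges_cavity_volume():
    coarse = cavity_volume(generate_lv_ellipsoid(EllipsoidSpec(resolution=6.0)))
    fine = cavity_volume(generate_lv_ellipsoid(EllipsoidSpec(resolution=3.0)))
    assert abs(fine - coarse) / fine < 0.01


def test_degenerate_specs_rejected():
    with pytest.raises(MeshValidationError):
        EllipsoidSpec(wall_thickness=0.0)
    with pytest.raises(MeshValidationError):
        EllipsoidSpec(resolution=30.0)  # larger than the short semi-axis
    with pytest.raises(MeshValidationError):
        EllipsoidSpec(base_fraction=1.0)


def test_surfaces_partition_boundary(lv_mesh_coarse):
    m = lv_mesh_coarse
    m.validate()  # every boundary facet labeled exactly once
    n_bnd = len(m.boundary_faces())
    n_lab = sum(len(m.surfaces[k]) for k in
                ("endocardium", "epicardium", "basal_rim"))
    assert n_lab == n_bnd
    assert len(m.surfaces["apex_patch"]) > 0
    # apex facets are epicardial
    epi = {tuple(sorted(f)) for f in m.surfaces["epicardium"]}
    assert all(tuple(sorted(f)) in epi for f in m.surfaces["apex_patch"])


def test_fiber_helix_angle_near_surfaces():
    """Elements owning an epi-/endocardial facet carry helix angles within
    5 degrees of the prescribed -60/+60 surface values."""
    m = generate_lv_ellipsoid(EllipsoidSpec(resolution=6.0,
                                            transmural_layers=10))
    ha = helix_angles(m)
    zc = m.nodes[m.tets].mean(axis=1)[:, 2]
    ok = zc > -40.0  # away from the apex, where circumferential degenerates

    def facet_owners(surface):
        nodes = set(np.unique(m.surfaces[surface]))
        count = np.array([sum(v in nodes for v in tet) for tet in m.tets])
        return count >= 3

    epi = facet_owners("epicardium") & ok
    endo = facet_owners("endocardium") & ok
    assert epi.sum() > 50 and endo.sum() > 50
    assert abs(np.median(ha[epi]) - (-60.0)) < 5.0
    assert abs(np.median(ha[endo]) - 60.0) < 5.0


def test_fiber_angle_monotone_transmurally(lv_mesh_coarse):
    m = lv_mesh_coarse
    ha = helix_angles(m)
    xi = transmural_coordinate(m)[m.tets].mean(axis=1)
    zc = m.nodes[m.tets].mean(axis=1)[:, 2]
    sel = zc > -40.0
    # binned means increase monotonically from epi (xi=0) to endo (xi=1)
    bins = np.linspace(0, 1, 6)
    means = [ha[sel & (xi >= lo) & (xi < hi)].mean()
             for lo, hi in zip(bins[:-1], bins[1:])]
    assert np.all(np.diff(means) > 0)


def test_generation_deterministic():
    a = generate_lv_ellipsoid(EllipsoidSpec(resolution=10.0, seed=3))
    b = generate_lv_ellipsoid(EllipsoidSpec(resolution=10.0, seed=3))
    assert np.array_equal(a.nodes, b.nodes)
    assert np.array_equal(a.tets, b.tets)


def test_sphere_shell_watertight(sphere_mesh):
    m = sphere_mesh
    faces = m.boundary_faces()
    assert len(faces) == (len(m.surfaces["endocardium"])
                          + len(m.surfaces["epicardium"]))
    # closed shell: cavity volume close to the sphere volume
    exact = 4.0 / 3.0 * np.pi * 10.0 ** 3 / 1000.0
    assert cavity_volume(m) == pytest.approx(exact, rel=0.06)


# ---------------------------------------------------------------------------
# cavity volume
# ---------------------------------------------------------------------------

def cube_mesh(side=10.0):
    """Solid cube whose boundary is labeled as the 'cavity' surface."""
    pts = np.array([[x, y, z] for z in (0, side) for y in (0, side)
                    for x in (0, side)], float)
    hexc = {(a, b, c): a + 2 * b + 4 * c for a in (0, 1) for b in (0, 1)
            for c in (0, 1)}
    from cardio_unload.mesh import _kuhn_tets
    tets = np.array(_kuhn_tets(hexc), int)
    a = pts[tets[:, 1]] - pts[tets[:, 0]]
    b = pts[tets[:, 2]] - pts[tets[:, 0]]
    c = pts[tets[:, 3]] - pts[tets[:, 0]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    tets[vol < 0] = tets[vol < 0][:, [0, 2, 1, 3]]
    z = np.zeros((len(tets), 3))
    f0 = z + [1, 0, 0]
    s0 = z + [0, 1, 0]
    m = Mesh(pts, tets, f0, s0, np.cross(f0, s0))
    # flip outward boundary faces so normals point into the enclosed volume
    faces = m.boundary_faces()[:, [0, 2, 1]]
    m.surfaces = {"endocardium": faces,
                  "basal_rim": np.zeros((0, 3), int)}
    return m


def test_cavity_volume_unit_cube():
    assert cavity_volume(cube_mesh(10.0)) == pytest.approx(1.0, rel=1e-12)


def test_cavity_volume_translation_invariant(lv_mesh_coarse):
    m = lv_mesh_coarse
    v0 = cavity_volume(m)
    shift = np.tile([3.0, -2.0, 7.0], (m.node_count, 1))
    assert cavity_volume(m, shift) == pytest.approx(v0, rel=1e-10)
    assert cavity_volume(m, np.zeros_like(m.nodes)) == v0


def test_cavity_volume_rejects_inverted_surface():
    m = cube_mesh()
    m.surfaces["endocardium"] = m.surfaces["endocardium"][:, [0, 2, 1]]
    with pytest.raises(ValueError):
        cavity_volume(m)


def test_cavity_volume_rejects_nonfinite_displacement(lv_mesh_coarse):
    d = np.zeros_like(lv_mesh_coarse.nodes)
    d[0, 0] = np.nan
    with pytest.raises(ValueError):
        cavity_volume(lv_mesh_coarse, d)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def test_vtk_round_trip(lv_mesh_tiny, tmp_path):
    m = lv_mesh_tiny
    path = tmp_path / "lv.vtk"
    write_mesh(m, path, "vtk")
    m2 = read_mesh(path, "vtk")
    assert np.max(np.abs(m2.nodes - m.nodes)) < 1e-6
    assert np.array_equal(m2.tets, m.tets)
    np.testing.assert_allclose(m2.f0, m.f0, atol=1e-12)
    for name, faces in m.surfaces.items():
        assert np.array_equal(m2.surfaces[name], faces)


def test_vtk_file_structure(lv_mesh_tiny, tmp_path):
    """The writer emits a structurally valid legacy VTK file."""
    path = tmp_path / "lv.vtk"
    write_mesh(lv_mesh_tiny, path, "vtk")
    lines = path.read_text().splitlines()
    assert lines[0].startswith("# vtk DataFile Version")
    assert lines[2] == "ASCII"
    assert lines[3] == "DATASET UNSTRUCTURED_GRID"
    ptok = lines[4].split()
    assert ptok[0] == "POINTS" and int(ptok[1]) == lv_mesh_tiny.node_count
    idx = 5 + lv_mesh_tiny.node_count
    ctok = lines[idx].split()
    assert ctok[0] == "CELLS"
    ncell, size = int(ctok[1]), int(ctok[2])
    cell_lines = lines[idx + 1: idx + 1 + ncell]
    assert sum(len(l.split()) for l in cell_lines) == size
    assert lines[idx + 1 + ncell].split()[0] == "CELL_TYPES"


def test_carp_round_trip(lv_mesh_tiny, tmp_path):
    m = lv_mesh_tiny
    write_mesh(m, tmp_path / "lv", "carp")
    for suffix in (".pts", ".elem", ".lon", ".surf"):
        assert (tmp_path / f"lv{suffix}").exists()
    m2 = read_mesh(tmp_path / "lv", "carp")
    assert np.max(np.abs(m2.nodes - m.nodes)) < 1e-6
    assert np.array_equal(m2.tets, m.tets)
    np.testing.assert_allclose(m2.s0, m.s0, atol=1e-12)
    for name, faces in m.surfaces.items():
        assert np.array_equal(m2.surfaces[name], faces)


def test_carp_wrong_node_count_header(tmp_path):
    (tmp_path / "bad.pts").write_text("5\n0 0 0\n1 0 0\n")
    with pytest.raises(MeshParseError) as exc:
        read_mesh(tmp_path / "bad", "carp")
    assert "bad.pts" in str(exc.value)


def test_vtk_malformed_raises_with_line(tmp_path):
    (tmp_path / "bad.vtk").write_text(
        "# vtk DataFile Version 3.0\nt\nASCII\nDATASET UNSTRUCTURED_GRID\n"
        "POINTS 2 double\n0 0 0\n1 1\n")
    with pytest.raises(MeshParseError):
        read_mesh(tmp_path / "bad.vtk", "vtk")


def test_unknown_format_rejected(lv_mesh_tiny, tmp_path):
    with pytest.raises(ValueError):
        write_mesh(lv_mesh_tiny, tmp_path / "x", "stl")
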