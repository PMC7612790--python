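"""Left-ventricular mesh generation, cavity volumes and mesh I/O.

Patient anatomies are not distributable, so an idealized truncated-ellipsoid
left ventricle stands in: an ellipsoidal shell, truncated by a flat base
plane, meshed by a structured parametric grid (circumferential x
longitudinal x transmural) whose hexahedra are split into tetrahedra with
the Kuhn (6-tet) pattern.  The apex is closed by collapsing the polar ring
onto per-layer pole nodes.  Rule-based myofiber architecture rotates the
helix angle linearly across the wall (default -60 deg epicardial to +60 deg
endocardial) about the local circumferential direction, using a transmural
coordinate obtained from a Laplace solve (endo = 1, epi = 0).

Units: coordinates in mm, volumes in mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .units import mm3_to_ml

__all__ = [
    "Mesh",
    "EllipsoidSpec",
    "MeshValidationError",
    "MeshParseError",
    "generate_lv_ellipsoid",
    "generate_sphere_shell",
    "cavity_volume",
    "write_mesh",
    "read_mesh",
    "truncated_ellipsoid_cavity_volume",
]

SURFACE_NAMES = ("endocardium", "epicardium", "basal_rim", "apex_patch")


class MeshValidationError(ValueError):
    """A mesh or mesh specification violates its invariants."""


class MeshParseError(ValueError):
    """A mesh file could not be parsed; carries a line number."""

    def __init__(self, path, lineno: int, msg: str):
        super().__init__(f"{path}:{lineno}: {msg}")
        self.lineno = lineno


# ---------------------------------------------------------------------------
# core container
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Tetrahedral mesh with per-element fiber frames and labeled surfaces.

    ``surfaces`` maps a surface name to an ``(k, 3)`` integer array of facet
    node triples, oriented outward from the solid wall (hence endocardial
    facet normals point into the cavity).
    """

    nodes: np.ndarray                      # (N, 3) float, mm
    tets: np.ndarray                       # (M, 4) int
    f0: np.ndarray                         # (M, 3) unit fiber axis
    s0: np.ndarray                         # (M, 3) unit sheet axis
    n0: np.ndarray                         # (M, 3) unit sheet-normal axis
    surfaces: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def node_count(self) -> int:
        return self.nodes.shape[0]

    @property
    def elem_count(self) -> int:
        return self.tets.shape[0]

    def copy(self) -> "Mesh":
        return Mesh(self.nodes.copy(), self.tets.copy(), self.f0.copy(),
                    self.s0.copy(), self.n0.copy(),
                    {k: v.copy() for k, v in self.surfaces.items()})

    def with_nodes(self, nodes: np.ndarray) -> "Mesh":
        m = self.copy()
        m.nodes = np.asarray(nodes, float).copy()
        return m

    # -- geometry helpers -------------------------------------------------
    def tet_volumes(self, nodes: Optional[np.ndarray] = None) -> np.ndarray:
        x = self.nodes if nodes is None else nodes
        a = x[self.tets[:, 1]] - x[self.tets[:, 0]]
        b = x[self.tets[:, 2]] - x[self.tets[:, 0]]
        c = x[self.tets[:, 3]] - x[self.tets[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def shape_gradients(self):
        """Reference shape-function gradients (M,4,3) and volumes (M,)."""
        x = self.nodes
        A = np.stack([x[self.tets[:, a]] - x[self.tets[:, 0]] for a in (1, 2, 3)],
                     axis=-1)  # columns = edge vectors
        vol = np.linalg.det(A) / 6.0
        Ainv = np.linalg.inv(A)
        grads = np.empty((self.elem_count, 4, 3))
        grads[:, 1:, :] = Ainv  # rows of A^-1 are grad(lambda_2..4)
        grads[:, 0, :] = -Ainv.sum(axis=1)
        return grads, vol

    def rim_nodes(self) -> np.ndarray:
        """Nodes on the endocardial boundary loop at the base (cavity rim)."""
        endo = self.surfaces.get("endocardium")
        base = self.surfaces.get("basal_rim")
        if endo is None:
            raise MeshValidationError("mesh has no labeled endocardium")
        if base is None or base.size == 0:
            return np.array([], dtype=int)
        rim = np.intersect1d(np.unique(endo), np.unique(base))
        return rim

    def validate(self) -> None:
        """Check structural invariants; raise MeshValidationError on failure."""
        if np.any(self.tet_volumes() <= 0):
            raise MeshValidationError("non-positively-oriented tetrahedra present")
        for u, v in ((self.f0, self.s0), (self.f0, self.n0), (self.s0, self.n0)):
            if np.max(np.abs(np.einsum("ij,ij->i", u, v))) > 1e-10:
                raise MeshValidationError("fiber frame not orthogonal to 1e-10")
        for v in (self.f0, self.s0, self.n0):
            if np.max(np.abs(np.einsum("ij,ij->i", v, v) - 1.0)) > 1e-10:
                raise MeshValidationError("fiber frame not unit-norm to 1e-10")
        # boundary facets must be covered exactly once by non-overlapping labels
        bnd = {self._face_key(f) for f in self.boundary_faces()}
        seen = {}
        for name, faces in self.surfaces.items():
            if name == "apex_patch":
                continue  # subset of the epicardium by construction
            for f in faces:
                key = self._face_key(f)
                if key not in bnd:
                    raise MeshValidationError(f"labeled facet of {name} not on boundary")
                if key in seen:
                    raise MeshValidationError(
                        f"facet labeled both {seen[key]} and {name}")
                seen[key] = name
        if len(seen) != len(bnd):
            raise MeshValidationError("unlabeled boundary facets present")

    @staticmethod
    def _face_key(f):
        return tuple(sorted(int(i) for i in f))

    def boundary_faces(self) -> np.ndarray:
        """All boundary facets, oriented outward from the solid (K,3)."""
        # local faces opposite each node, ordered so normals point outward
        loc = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))
        faces = np.concatenate([self.tets[:, f] for f in loc], axis=0)
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                                   return_counts=True)
        return faces[counts[inv] == 1]


# ---------------------------------------------------------------------------
# synthetic truncated-ellipsoid LV
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EllipsoidSpec:
    """Parameters of the idealized truncated-ellipsoid left ventricle.

    ``long_axis``/``short_axis`` are the *endocardial* semi-axes (mm); the
    apex points toward -z and the base plane sits at
    ``z = base_fraction * long_axis``.  ``resolution`` is the target edge
    length (mm); ``alpha_epi``/``alpha_endo`` are the fiber helix angles in
    degrees at the epi-/endocardium.
    """

    long_axis: float = 48.0
    short_axis: float = 26.0
    wall_thickness: float = 9.0
    base_fraction: float = 0.2
    resolution: float = 6.0
    alpha_epi: float = -60.0
    alpha_endo: float = 60.0
    seed: int = 0
    #: optional override of the number of transmural element layers (the
    #: default derives it from ``resolution``)
    transmural_layers: Optional[int] = None
    #: hex-to-tet split scheme: "kuhn" (6 tets/hex) or "crossed" (24
    #: tets/hex, less volumetric locking)
    split: str = "kuhn"

    def __post_init__(self):
        if not self.wall_thickness > 0:
            raise MeshValidationError("wall thickness must be > 0")
        if not self.resolution > 0:
            raise MeshValidationError("resolution must be > 0")
        if self.resolution > self.short_axis:
            raise MeshValidationError("resolution larger than the short semi-axis")
        if not 0.0 <= self.base_fraction < 1.0:
            raise MeshValidationError(
                "base_fraction must lie in [0, 1) so the apex stays closed")
        if not self.long_axis > 0 or not self.short_axis > 0:
            raise MeshValidationError("semi-axes must be > 0")


def truncated_ellipsoid_cavity_volume(long_axis: float, short_axis: float,
                                      base_height: float, n_quad: int = 2000) -> float:
    """Analytic (1-D quadrature) cavity volume of the truncated ellipsoid, mL.

    Integrates the circular cross-section pi * r(z)^2 from the apex
    ``z = -long_axis`` up to the base plane ``z = base_height``.
    """
    z = np.linspace(-long_axis, base_height, n_quad)
    r2 = short_axis ** 2 * (1.0 - (z / long_axis) ** 2)
    return mm3_to_ml(np.trapezoid(np.pi * r2, z))


_KUHN_PERMS = ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0))

#: quad faces of the unit hexahedron (corner keys), for the crossed split
_HEX_FACES = (
    ((0, 0, 0), (0, 1, 0), (0, 1, 1), (0, 0, 1)),
    ((1, 0, 0), (1, 1, 0), (1, 1, 1), (1, 0, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 0, 1), (0, 0, 1)),
    ((0, 1, 0), (1, 1, 0), (1, 1, 1), (0, 1, 1)),
    ((0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)),
    ((0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)),
)

SPLIT_SCHEMES = ("kuhn", "crossed")


def _kuhn_tets(corner):
    """Split a hexahedron into 6 tets; ``corner[(ia, ij, it)]`` node ids."""
    tets = []
    for perm in _KUHN_PERMS:
        path = [(0, 0, 0)]
        cur = [0, 0, 0]
        for ax in perm:
            cur[ax] = 1
            path.append(tuple(cur))
        tets.append([corner[p] for p in path])
    return tets


def _split_hex_grid(hexes, nodes, layer_of, split):
    """Tetrahedralize a list of (possibly pole-degenerate) hexahedra.

    ``kuhn``: the 6-tet simplex split (conforming in index space, no new
    nodes).  ``crossed``: 24 tets per hex around the body centroid and the
    (shared) face centroids -- markedly less prone to volumetric locking
    with the penalty formulation.  Returns (tets, nodes, layer_of); new
    centroid nodes carry the layer of their face when unambiguous, else -1.
    """
    if split == "kuhn":
        tets = []
        for c in hexes:
            tets.extend(_kuhn_tets(c))
        return np.array(tets, int), nodes, layer_of
    if split != "crossed":
        raise MeshValidationError(f"unknown hex split scheme {split!r}")
    node_list = [list(p) for p in nodes]
    layer_list = list(layer_of)
    face_node = {}
    tets = []
    for c in hexes:
        pts = np.array([node_list[i] for i in c.values()])
        bc = len(node_list)
        node_list.append(list(pts.mean(axis=0)))
        layer_list.append(-1)
        for f in _HEX_FACES:
            ids = [c[k] for k in f]
            key = tuple(sorted(set(ids)))
            if len(key) < 3:
                continue  # fully collapsed pole face
            if key not in face_node:
                face_node[key] = len(node_list)
                fp = np.array([node_list[i] for i in ids])
                node_list.append(list(fp.mean(axis=0)))
                lays = {layer_list[i] for i in ids}
                layer_list.append(lays.pop() if len(lays) == 1 else -1)
            fc = face_node[key]
            for e in range(4):
                tet = (ids[e], ids[(e + 1) % 4], fc, bc)
                if len(set(tet)) == 4:
                    tets.append(tet)
    return (np.array(tets, int), np.array(node_list, float),
            np.array(layer_list))


def _finalize_tets(tets, nodes):
    """Drop degenerate tets, enforce positive orientation."""
    uniq = np.array([len(set(row)) for row in tets])
    tets = tets[uniq == 4]
    a = nodes[tets[:, 1]] - nodes[tets[:, 0]]
    b = nodes[tets[:, 2]] - nodes[tets[:, 0]]
    c = nodes[tets[:, 3]] - nodes[tets[:, 0]]
    vol = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    keep = np.abs(vol) > 1e-10
    tets, vol = tets[keep], vol[keep]
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    return tets


def generate_lv_ellipsoid(spec: EllipsoidSpec) -> Mesh:
    """Generate the idealized LV mesh with rule-based fibers.

    Deterministic given the spec (the seed is recorded for provenance of
    downstream sampling).  Raises :class:`MeshValidationError` for a
    degenerate spec.
    """
    rl_en, rs_en = spec.long_axis, spec.short_axis
    t = spec.wall_thickness
    z_b = spec.base_fraction * rl_en
    res = spec.resolution

    rs_mid = rs_en + 0.5 * t
    rl_mid = rl_en + 0.5 * t
    theta_b_mid = np.arccos(np.clip(z_b / rl_mid, -1, 1))
    n_phi = max(12, int(np.ceil(2 * np.pi * rs_mid / res)))
    n_j = max(6, int(np.ceil(rl_mid * (np.pi - theta_b_mid) / res)))
    n_t = spec.transmural_layers or max(2, int(round(t / res)))

    n_ring = n_j * n_phi
    n_layer = n_ring + 1  # + pole

    def nid(tt, j, i):
        return tt * n_layer + j * n_phi + (i % n_phi)

    def pole(tt):
        return tt * n_layer + n_ring

    nodes = np.empty(((n_t + 1) * n_layer, 3))
    layer_of = np.empty(len(nodes))
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    for tt in range(n_t + 1):
        xi = 1.0 - tt / n_t          # transmural coordinate: endo=1, epi=0
        rs = rs_en + (tt / n_t) * t
        rl = rl_en + (tt / n_t) * t
        theta_b = np.arccos(np.clip(z_b / rl, -1, 1))
        # last ring sits one nominal spacing short of the pole
        thetas = np.linspace(theta_b, np.pi, n_j + 1)[:-1]
        for j, th in enumerate(thetas):
            r = rs * np.sin(th)
            zz = rl * np.cos(th)
            base = tt * n_layer + j * n_phi
            nodes[base:base + n_phi, 0] = r * np.cos(phis)
            nodes[base:base + n_phi, 1] = r * np.sin(phis)
            nodes[base:base + n_phi, 2] = zz
        nodes[pole(tt)] = (0.0, 0.0, -rl)
        layer_of[tt * n_layer:(tt + 1) * n_layer] = tt

    hexes = []
    for tt in range(n_t):
        for j in range(n_j):
            for i in range(n_phi):
                corner = {}
                for (ia, ij, it) in [(a, b, c) for a in (0, 1) for b in (0, 1)
                                     for c in (0, 1)]:
                    if j + ij == n_j:
                        corner[(ia, ij, it)] = pole(tt + it)
                    else:
                        corner[(ia, ij, it)] = nid(tt + it, j + ij, i + ia)
                hexes.append(corner)
    tets, nodes, layer_of = _split_hex_grid(hexes, nodes, layer_of, spec.split)
    tets = _finalize_tets(tets, nodes)

    mesh = Mesh(nodes, tets,
                f0=np.zeros((len(tets), 3)), s0=np.zeros((len(tets), 3)),
                n0=np.zeros((len(tets), 3)))
    _label_surfaces(mesh, layer_of, n_t, z_b, rl_en + t)
    _assign_fibers(mesh, spec.alpha_epi, spec.alpha_endo)
    mesh.validate()
    return mesh


def _label_surfaces(mesh: Mesh, layer_of, n_t, z_b, rl_epi, apex_angle=0.35):
    faces = mesh.boundary_faces()
    lay = layer_of[faces]
    zc = mesh.nodes[faces][:, :, 2].mean(axis=1)
    is_base = np.abs(mesh.nodes[faces][:, :, 2] - z_b).max(axis=1) < 1e-8
    is_endo = (~is_base) & np.all(lay == 0, axis=1)
    is_epi = (~is_base) & np.all(lay == n_t, axis=1)
    if not np.all(is_base | is_endo | is_epi):
        raise MeshValidationError("boundary facet could not be classified")
    apex = is_epi & (zc < -rl_epi * np.cos(apex_angle))
    mesh.surfaces = {
        "endocardium": faces[is_endo],
        "epicardium": faces[is_epi],
        "basal_rim": faces[is_base],
        "apex_patch": faces[apex],
    }


def generate_sphere_shell(r_inner: float, r_outer: float,
                          resolution: float, split: str = "crossed") -> Mesh:
    """Closed thick-walled spherical shell (both poles collapsed).

    Labeled surfaces: endocardium (inner), epicardium (outer).  Fibers are a
    radially-built orthonormal frame (only isotropic materials are intended
    on this geometry).
    """
    if not 0 < r_inner < r_outer:
        raise MeshValidationError("need 0 < r_inner < r_outer")
    t = r_outer - r_inner
    r_mid = 0.5 * (r_inner + r_outer)
    n_phi = max(12, int(np.ceil(2 * np.pi * r_mid / resolution)))
    n_j = max(6, int(np.ceil(np.pi * r_mid / resolution)))
    n_t = max(2, int(round(t / resolution)))

    n_ring = n_j * n_phi
    n_layer = n_ring + 2  # + two poles

    def nid(tt, j, i):
        return tt * n_layer + j * n_phi + (i % n_phi)

    def pole_n(tt):  # north, theta=0
        return tt * n_layer + n_ring

    def pole_s(tt):
        return tt * n_layer + n_ring + 1

    nodes = np.empty(((n_t + 1) * n_layer, 3))
    layer_of = np.empty(len(nodes))
    phis = 2 * np.pi * np.arange(n_phi) / n_phi
    for tt in range(n_t + 1):
        r = r_inner + (tt / n_t) * t
        thetas = np.linspace(0.0, np.pi, n_j + 2)[1:-1]
        for j, th in enumerate(thetas):
            base = tt * n_layer + j * n_phi
            nodes[base:base + n_phi, 0] = r * np.sin(th) * np.cos(phis)
            nodes[base:base + n_phi, 1] = r * np.sin(th) * np.sin(phis)
            nodes[base:base + n_phi, 2] = r * np.cos(th)
        nodes[pole_n(tt)] = (0.0, 0.0, r)
        nodes[pole_s(tt)] = (0.0, 0.0, -r)
        layer_of[tt * n_layer:(tt + 1) * n_layer] = tt

    hexes = []
    for tt in range(n_t):
        for j in range(-1, n_j):
            for i in range(n_phi):
                corner = {}
                for (ia, ij, it) in [(a, b, c) for a in (0, 1) for b in (0, 1)
                                     for c in (0, 1)]:
                    jj = j + ij
                    if jj == -1:
                        corner[(ia, ij, it)] = pole_n(tt + it)
                    elif jj == n_j:
                        corner[(ia, ij, it)] = pole_s(tt + it)
                    else:
                        corner[(ia, ij, it)] = nid(tt + it, jj, i + ia)
                hexes.append(corner)
    tets, nodes, layer_of = _split_hex_grid(hexes, nodes, layer_of, split)
    tets = _finalize_tets(tets, nodes)

    mesh = Mesh(nodes, tets,
                f0=np.zeros((len(tets), 3)), s0=np.zeros((len(tets), 3)),
                n0=np.zeros((len(tets), 3)))
    faces = mesh.boundary_faces()
    lay = layer_of[faces]
    is_endo = np.all(lay == 0, axis=1)
    is_epi = np.all(lay == n_t, axis=1)
    if not np.all(is_endo | is_epi):
        raise MeshValidationError("sphere shell boundary facet unclassified")
    mesh.surfaces = {"endocardium": faces[is_endo], "epicardium": faces[is_epi],
                     "basal_rim": np.zeros((0, 3), dtype=int),
                     "apex_patch": np.zeros((0, 3), dtype=int)}
    # radial frame (isotropic use); s0 radial, f0/n0 tangential
    cent = (nodes[tets[:, 0]] + nodes[tets[:, 1]] + nodes[tets[:, 2]]
            + nodes[tets[:, 3]]) / 4.0
    er = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    helper = np.where(np.abs(er[:, 2:3]) < 0.9,
                      np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0]))
    f0 = np.cross(helper, er)
    f0 /= np.linalg.norm(f0, axis=1, keepdims=True)
    mesh.f0, mesh.s0 = f0, er
    mesh.n0 = np.cross(f0, er)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# transmural coordinate + rule-based fibers
# ---------------------------------------------------------------------------

def transmural_coordinate(mesh: Mesh) -> np.ndarray:
    """Nodal transmural coordinate from a P1 Laplace solve (endo=1, epi=0)."""
    grads, vols = mesh.shape_gradients()
    ke = np.einsum("e,eai,ebi->eab", vols, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(mesh.node_count, mesh.node_count)).tocsr()
    xi = np.zeros(mesh.node_count)
    endo = np.unique(mesh.surfaces["endocardium"])
    epi = np.unique(mesh.surfaces["epicardium"])
    fixed = np.zeros(mesh.node_count, dtype=bool)
    fixed[endo] = True
    fixed[epi] = True
    xi[endo] = 1.0
    free = ~fixed
    rhs = -K[:, fixed][free] @ xi[fixed]
    xi[free] = spla.spsolve(K[free][:, free].tocsc(), rhs)
    return np.clip(xi, 0.0, 1.0)


def _assign_fibers(mesh: Mesh, alpha_epi: float, alpha_endo: float) -> None:
    xi_node = transmural_coordinate(mesh)
    grads, _ = mesh.shape_gradients()
    gxi = np.einsum("eai,ea->ei", grads, xi_node[mesh.tets])
    nrm = np.linalg.norm(gxi, axis=1, keepdims=True)
    nrm[nrm < 1e-12] = 1.0
    et = gxi / nrm                                    # transmural, endo-ward
    zhat = np.array([0.0, 0.0, 1.0])
    ec = np.cross(np.broadcast_to(zhat, et.shape), et)
    n_ec = np.linalg.norm(ec, axis=1, keepdims=True)
    # near the apex the circumferential direction degenerates; fall back to
    # any tangential direction
    bad = (n_ec[:, 0] < 1e-6)
    if np.any(bad):
        helper = np.where(np.abs(et[bad, 0:1]) < 0.9,
                          np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0]))
        ec[bad] = np.cross(helper, et[bad])
        n_ec[bad] = np.linalg.norm(ec[bad], axis=1, keepdims=True)
    ec /= n_ec
    el = np.cross(et, ec)
    xi_e = xi_node[mesh.tets].mean(axis=1)
    alpha = np.deg2rad(alpha_epi + (alpha_endo - alpha_epi) * xi_e)
    f0 = np.cos(alpha)[:, None] * ec + np.sin(alpha)[:, None] * el
    f0 /= np.linalg.norm(f0, axis=1, keepdims=True)
    s0 = et - np.einsum("ei,ei->e", et, f0)[:, None] * f0
    s0 /= np.linalg.norm(s0, axis=1, keepdims=True)
    mesh.f0, mesh.s0, mesh.n0 = f0, s0, np.cross(f0, s0)


def helix_angles(mesh: Mesh) -> np.ndarray:
    """Per-element fiber helix angle (deg) w.r.t. the local circumferential
    direction, for inspection/testing of the rule-based architecture."""
    xi_node = transmural_coordinate(mesh)
    grads, _ = mesh.shape_gradients()
    gxi = np.einsum("eai,ea->ei", grads, xi_node[mesh.tets])
    et = gxi / np.maximum(np.linalg.norm(gxi, axis=1, keepdims=True), 1e-12)
    zhat = np.array([0.0, 0.0, 1.0])
    ec = np.cross(np.broadcast_to(zhat, et.shape), et)
    ec /= np.maximum(np.linalg.norm(ec, axis=1, keepdims=True), 1e-12)
    el = np.cross(et, ec)
    return np.rad2deg(np.arctan2(np.einsum("ei,ei->e", mesh.f0, el),
                                 np.einsum("ei,ei->e", mesh.f0, ec)))


# ---------------------------------------------------------------------------
# cavity volume
# ---------------------------------------------------------------------------

def cavity_volume(mesh: Mesh, displacements: Optional[np.ndarray] = None) -> float:
    """Volume (mL) of the cavity enclosed by the (displaced) endocardium.

    The open basal rim is closed by a triangulated planar cap anchored at
    the centroid of the rim nodes (which lies on their least-squares plane);
    the enclosed volume is evaluated with the divergence theorem.  Raises a
    ``ValueError`` if the signed volume is non-positive (inverted surface).
    """
    x = mesh.nodes
    if displacements is not None:
        displacements = np.asarray(displacements, float)
        if not np.all(np.isfinite(displacements)):
            raise ValueError("displacements must be finite")
        x = x + displacements
    endo = mesh.surfaces["endocardium"]
    rim = mesh.rim_nodes()
    o = x[rim].mean(axis=0) if rim.size else x[np.unique(endo)].mean(axis=0)
    tri = x[endo] - o
    signed = np.einsum("fi,fi->f",
                       tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    vol = -signed  # endocardial normals point into the cavity
    if vol <= 0:
        raise ValueError("non-positive cavity volume: inverted or "
                         "self-intersecting endocardial surface")
    return mm3_to_ml(vol)


# ---------------------------------------------------------------------------
# I/O: VTK legacy unstructured grid and CARP .pts/.elem/.lon(+.surf)
# ---------------------------------------------------------------------------

_SURF_IDS = {name: i + 1 for i, name in enumerate(SURFACE_NAMES)}


def write_mesh(mesh: Mesh, path, fmt: str = "vtk") -> None:
    """Write a mesh as VTK legacy ASCII (``vtk``) or CARP triplet (``carp``).

    VTK files carry the tets plus the labeled surface facets as triangle
    cells with a ``surface_id`` cell field and the fiber/sheet vectors as
    cell data.  CARP writes ``<base>.pts``, ``<base>.elem``, ``<base>.lon``
    (fiber and sheet per element) and ``<base>.surf`` with the labels.
    """
    path = Path(path)
    if fmt == "vtk":
        _write_vtk(mesh, path)
    elif fmt == "carp":
        _write_carp(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")


def read_mesh(path, fmt: str = "vtk") -> Mesh:
    path = Path(path)
    if fmt == "vtk":
        return _read_vtk(path)
    if fmt == "carp":
        return _read_carp(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def _write_vtk(mesh: Mesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("cardio-unload LV mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.node_count} double\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        surf_cells = [(name, f) for name in SURFACE_NAMES
                      for f in mesh.surfaces.get(name, [])]
        ncell = mesh.elem_count + len(surf_cells)
        size = mesh.elem_count * 5 + len(surf_cells) * 4
        fh.write(f"CELLS {ncell} {size}\n")
        for tet in mesh.tets:
            fh.write("4 " + " ".join(map(str, tet)) + "\n")
        for _, f in surf_cells:
            fh.write("3 " + " ".join(map(str, f)) + "\n")
        fh.write(f"CELL_TYPES {ncell}\n")
        fh.write("\n".join(["10"] * mesh.elem_count
                           + ["5"] * len(surf_cells)) + "\n")
        fh.write(f"CELL_DATA {ncell}\n")
        fh.write("SCALARS surface_id int 1\nLOOKUP_TABLE default\n")
        ids = [0] * mesh.elem_count + [_SURF_IDS[name] for name, _ in surf_cells]
        fh.write("\n".join(map(str, ids)) + "\n")
        for label, arr in (("fiber", mesh.f0), ("sheet", mesh.s0)):
            fh.write(f"VECTORS {label} double\n")
            for v in arr:
                fh.write(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
            for _ in surf_cells:
                fh.write("0 0 0\n")


def _read_vtk(path: Path) -> Mesh:
    lines = Path(path).read_text().splitlines()
    idx = 0

    def fail(msg):
        raise MeshParseError(path, idx + 1, msg)

    def next_line():
        nonlocal idx
        while idx < len(lines) and not lines[idx].strip():
            idx += 1
        if idx >= len(lines):
            fail("unexpected end of file")
        line = lines[idx]
        idx += 1
        return line

    if not next_line().startswith("# vtk DataFile"):
        fail("missing VTK header")
    next_line()  # title
    if next_line().strip() != "ASCII":
        fail("only ASCII VTK supported")
    if "UNSTRUCTURED_GRID" not in next_line():
        fail("expected DATASET UNSTRUCTURED_GRID")
    tok = next_line().split()
    if tok[0] != "POINTS":
        fail("expected POINTS")
    npts = int(tok[1])
    pts = np.empty((npts, 3))
    for i in range(npts):
        vals = next_line().split()
        if len(vals) != 3:
            fail("expected 3 coordinates per line")
        pts[i] = [float(v) for v in vals]
    tok = next_line().split()
    if tok[0] != "CELLS":
        fail("expected CELLS")
    ncell = int(tok[1])
    cells = []
    for _ in range(ncell):
        vals = [int(v) for v in next_line().split()]
        if vals[0] != len(vals) - 1:
            fail("cell size mismatch")
        cells.append(vals[1:])
    tok = next_line().split()
    if tok[0] != "CELL_TYPES":
        fail("expected CELL_TYPES")
    types = [int(next_line()) for _ in range(ncell)]
    tets = np.array([c for c, t in zip(cells, types) if t == 10], dtype=int)
    tris = [(i, c) for i, (c, t) in enumerate(zip(cells, types)) if t == 5]
    surf_ids = None
    fiber = sheet = None
    while idx < len(lines):
        line = lines[idx].strip()
        idx += 1
        if not line:
            continue
        tok = line.split()
        if tok[0] == "SCALARS" and tok[1] == "surface_id":
            next_line()  # LOOKUP_TABLE
            vals = []
            while len(vals) < ncell:
                vals.extend(int(v) for v in next_line().split())
            surf_ids = vals
        elif tok[0] == "VECTORS" and tok[1] in ("fiber", "sheet"):
            arr = np.empty((ncell, 3))
            for i in range(ncell):
                arr[i] = [float(v) for v in next_line().split()]
            if tok[1] == "fiber":
                fiber = arr
            else:
                sheet = arr
    ntet = len(tets)
    if fiber is None or sheet is None:
        fail("missing fiber/sheet cell data")
    f0 = fiber[:ntet]
    s0 = sheet[:ntet]
    surfaces = {name: [] for name in SURFACE_NAMES}
    if surf_ids is not None:
        id2name = {v: k for k, v in _SURF_IDS.items()}
        for i, c in tris:
            name = id2name.get(surf_ids[i])
            if name:
                surfaces[name].append(c)
    surfaces = {k: np.array(v, dtype=int).reshape(-1, 3) for k, v in surfaces.items()}
    return Mesh(pts, tets, f0, s0, np.cross(f0, s0), surfaces)


def _write_carp(mesh: Mesh, base: Path) -> None:
    base = base.with_suffix("")
    with open(base.with_suffix(".pts"), "w") as fh:
        fh.write(f"{mesh.node_count}\n")
        for p in mesh.nodes:
            fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    with open(base.with_suffix(".elem"), "w") as fh:
        fh.write(f"{mesh.elem_count}\n")
        for tet in mesh.tets:
            fh.write("Tt " + " ".join(map(str, tet)) + " 1\n")
    with open(base.with_suffix(".lon"), "w") as fh:
        fh.write("2\n")
        for f, s in zip(mesh.f0, mesh.s0):
            fh.write(" ".join(f"{v:.17g}" for v in (*f, *s)) + "\n")
    with open(base.with_suffix(".surf"), "w") as fh:
        for name in SURFACE_NAMES:
            faces = mesh.surfaces.get(name, np.zeros((0, 3), int))
            fh.write(f"{len(faces)} {name}\n")
            for f in faces:
                fh.write("Tr " + " ".join(map(str, f)) + "\n")


def _read_carp(base: Path) -> Mesh:
    base = Path(base).with_suffix("")
    pts_path = base.with_suffix(".pts")
    lines = pts_path.read_text().splitlines()
    try:
        npts = int(lines[0])
    except (ValueError, IndexError):
        raise MeshParseError(pts_path, 1, "expected node count header")
    if len(lines) - 1 < npts:
        raise MeshParseError(pts_path, len(lines),
                             f"header promises {npts} nodes, file has fewer")
    pts = np.empty((npts, 3))
    for i in range(npts):
        vals = lines[1 + i].split()
        if len(vals) != 3:
            raise MeshParseError(pts_path, i + 2, "expected 3 coordinates")
        pts[i] = [float(v) for v in vals]
    if len(lines) - 1 > npts and any(l.strip() for l in lines[1 + npts:]):
        raise MeshParseError(pts_path, npts + 2,
                             "more coordinate lines than the header promises")

    elem_path = base.with_suffix(".elem")
    lines = elem_path.read_text().splitlines()
    nel = int(lines[0])
    tets = np.empty((nel, 4), dtype=int)
    for i in range(nel):
        tok = lines[1 + i].split()
        if tok[0] != "Tt" or len(tok) < 5:
            raise MeshParseError(elem_path, i + 2, "expected 'Tt a b c d tag'")
        tets[i] = [int(v) for v in tok[1:5]]

    lon_path = base.with_suffix(".lon")
    lines = lon_path.read_text().splitlines()
    if int(lines[0]) != 2:
        raise MeshParseError(lon_path, 1, "expected 2 direction vectors per element")
    f0 = np.empty((nel, 3))
    s0 = np.empty((nel, 3))
    for i in range(nel):
        vals = [float(v) for v in lines[1 + i].split()]
        if len(vals) != 6:
            raise MeshParseError(lon_path, i + 2, "expected 6 components")
        f0[i], s0[i] = vals[:3], vals[3:]

    surfaces = {}
    surf_path = base.with_suffix(".surf")
    if surf_path.exists():
        lines = surf_path.read_text().splitlines()
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            cnt_s, name = lines[i].split()
            cnt = int(cnt_s)
            faces = np.empty((cnt, 3), dtype=int)
            for kk in range(cnt):
                tok = lines[i + 1 + kk].split()
                if tok[0] != "Tr":
                    raise MeshParseError(surf_path, i + 2 + kk, "expected 'Tr a b c'")
                faces[kk] = [int(v) for v in tok[1:4]]
            surfaces[name] = faces
            i += 1 + cnt
    return Mesh(pts, tets, f0, s0, np.cross(f0, s0), surfaces)
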