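"""Idealized head geometries, tetrahedral meshing and mesh I/O.

The skull is modelled as a rigid ellipsoidal cavity enclosing a brain
continuum.  Craniectomy openings are patches of the cavity surface defined
by cones (circular, unilateral) or elliptical cones (bifrontal, optionally
split by a midline bar) about an opening axis.  The mesher builds a layered
tetrahedral ball mesh from a subdivided icosahedron, maps it onto the
ellipsoid, tags boundary facets (fixed skull interface vs. each opening)
and splits cells into hemispheres by the mid-sagittal plane.

Coordinate convention: origin at the cavity centroid, x = left-right
(sagittal-plane normal, left hemisphere at x > 0), y = posterior-anterior,
z = inferior-superior.  All lengths in this module are millimetres.
"""

from __future__ import annotations

import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "FIXED_INTERFACE_TAG",
    "REGION_LEFT",
    "REGION_RIGHT",
    "OpeningSpec",
    "HeadGeometry",
    "LabeledMesh",
    "build_idealized_head",
    "mesh_head",
    "read_mesh",
    "write_mesh",
    "opening_tag",
]

#: facet tag of the fixed (rigid skull) interface
FIXED_INTERFACE_TAG = 1
#: region tags of the two hemispheres (left hemisphere occupies x > 0)
REGION_LEFT = 1
REGION_RIGHT = 2

DEFAULT_SEMI_AXES = (80.0, 66.0, 59.0)


def opening_tag(k: int) -> int:
    """Facet tag of opening number ``k`` (1-based)."""
    return FIXED_INTERFACE_TAG + k


# ---------------------------------------------------------------------------
# opening specification
# ---------------------------------------------------------------------------


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length axis")
    return v / n


def _surface_scale(dirs: np.ndarray, semi_axes) -> np.ndarray:
    """Radial scale s such that s*u lies on the ellipsoid, per direction u."""
    a, b, c = semi_axes
    d = np.atleast_2d(dirs)
    s = 1.0 / np.sqrt((d[:, 0] / a) ** 2 + (d[:, 1] / b) ** 2 + (d[:, 2] / c) ** 2)
    return s


@dataclass
class OpeningSpec:
    """A craniectomy opening on the cavity surface.

    ``kind`` is one of ``unilateral_circular``, ``bifrontal`` or
    ``bifrontal_midline_bar``.  The opening is the intersection of the
    cavity surface with a (possibly elliptical) cone about ``axis``; for the
    midline-bar variant the strip |x| < bar_width_mm/2 is excluded.
    ``area_mm2`` (the true curved patch area) and, for circular openings,
    ``area_planar_mm2`` = pi*r^2 are filled in by :func:`build_idealized_head`.
    """

    kind: str
    axis: np.ndarray
    radius_mm: float | None = None
    angular_extents: tuple[float, float] | None = None
    bar_width_mm: float | None = None
    requested_area_mm2: float | None = None
    area_mm2: float | None = None
    area_planar_mm2: float | None = None

    def __post_init__(self):
        kinds = ("unilateral_circular", "bifrontal", "bifrontal_midline_bar")
        if self.kind not in kinds:
            raise ValueError(f"unknown opening kind {self.kind!r}; expected one of {kinds}")
        self.axis = _unit(self.axis)
        if self.kind == "unilateral_circular":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise ValueError("unilateral_circular opening requires radius_mm > 0")
        else:
            if self.angular_extents is None and self.requested_area_mm2 is None:
                raise ValueError(f"{self.kind} opening requires angular_extents or requested_area_mm2")
            if self.angular_extents is not None:
                t1, t2 = self.angular_extents
                if not (0 < t1 < np.pi / 2 and 0 < t2 < np.pi / 2):
                    raise ValueError("angular_extents must lie in (0, pi/2)")
        if self.kind == "bifrontal_midline_bar":
            if self.bar_width_mm is None or self.bar_width_mm <= 0:
                raise ValueError("bifrontal_midline_bar opening requires bar_width_mm > 0")

    # -- convenience constructors ------------------------------------------

    @classmethod
    def unilateral(cls, radius_mm: float, axis=(1.0, 0.0, 0.0)) -> "OpeningSpec":
        return cls(kind="unilateral_circular", axis=np.asarray(axis, float), radius_mm=radius_mm)

    @classmethod
    def bifrontal(cls, area_mm2: float | None = None, angular_extents=None,
                  axis=(0.0, 0.8, 0.6)) -> "OpeningSpec":
        return cls(kind="bifrontal", axis=np.asarray(axis, float),
                   angular_extents=angular_extents, requested_area_mm2=area_mm2)

    @classmethod
    def bifrontal_midline_bar(cls, area_mm2: float | None = None, angular_extents=None,
                              bar_width_mm: float = 25.0,
                              axis=(0.0, 0.8, 0.6)) -> "OpeningSpec":
        return cls(kind="bifrontal_midline_bar", axis=np.asarray(axis, float),
                   angular_extents=angular_extents, requested_area_mm2=area_mm2,
                   bar_width_mm=bar_width_mm)

    # -- geometry ----------------------------------------------------------

    def _transverse_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (e1, e2) spanning the plane normal to the axis.

        e1 is aligned with the lateral (x) direction where possible, so that
        the first angular extent of a bifrontal opening is its lateral
        half-width.
        """
        d = self.axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, d)) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = _unit(ref - np.dot(ref, d) * d)
        e2 = np.cross(d, e1)
        return e1, e2

    def polar_angle(self, semi_axes) -> float:
        """Cone half-angle of a circular opening on the given ellipsoid."""
        if self.kind != "unilateral_circular":
            raise ValueError("polar_angle is defined for circular openings only")
        r_axis = float(_surface_scale(self.axis[None, :], semi_axes)[0])
        if self.radius_mm >= r_axis:
            raise ValueError(
                f"opening radius {self.radius_mm} mm is not smaller than the "
                f"cavity radius {r_axis:.1f} mm along its axis")
        return float(np.arcsin(self.radius_mm / r_axis))

    def contains(self, points: np.ndarray, semi_axes) -> np.ndarray:
        """Boolean mask: which surface points lie inside the opening patch."""
        pts = np.atleast_2d(np.asarray(points, float))
        dirs = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        cosb = np.clip(dirs @ self.axis, -1.0, 1.0)
        beta = np.arccos(cosb)
        if self.kind == "unilateral_circular":
            return beta <= self.polar_angle(semi_axes)
        t1, t2 = self.angular_extents
        e1, e2 = self._transverse_basis()
        u1 = dirs @ e1
        u2 = dirs @ e2
        norm = np.sqrt(u1 ** 2 + u2 ** 2)
        norm[norm == 0] = 1.0
        bx = beta * u1 / norm
        by = beta * u2 / norm
        inside = (bx / t1) ** 2 + (by / t2) ** 2 <= 1.0
        if self.kind == "bifrontal_midline_bar":
            inside &= np.abs(pts[:, 0]) >= 0.5 * self.bar_width_mm
        return inside

    def rim_distance(self, dirs: np.ndarray, semi_axes) -> np.ndarray:
        """Signed angular 'radius' minus 1 in cone coordinates (0 on the rim).

        Used by the mesher to snap surface vertices onto the opening rim.
        """
        dirs = np.atleast_2d(dirs)
        cosb = np.clip(dirs @ self.axis, -1.0, 1.0)
        beta = np.arccos(cosb)
        if self.kind == "unilateral_circular":
            theta = self.polar_angle(semi_axes)
            return beta / theta - 1.0
        t1, t2 = self.angular_extents
        e1, e2 = self._transverse_basis()
        u1 = dirs @ e1
        u2 = dirs @ e2
        norm = np.sqrt(u1 ** 2 + u2 ** 2)
        norm[norm == 0] = 1.0
        bx = beta * u1 / norm
        by = beta * u2 / norm
        return np.sqrt((bx / t1) ** 2 + (by / t2) ** 2) - 1.0

    def snap_dirs_to_rim(self, dirs: np.ndarray, which: np.ndarray,
                         semi_axes) -> np.ndarray:
        """Pull the selected unit directions exactly onto the cone boundary
        (rescaling their polar angle about the opening axis)."""
        dirs = np.array(dirs, float)
        rho = self.rim_distance(dirs[which], semi_axes) + 1.0
        d = self.axis
        cosb = np.clip(dirs[which] @ d, -1.0, 1.0)
        beta = np.arccos(cosb)
        tang = dirs[which] - cosb[:, None] * d
        tnorm = np.linalg.norm(tang, axis=1)
        ok = (tnorm > 1e-12) & (beta > 1e-12) & (rho > 1e-12)
        tang[~ok] = 0.0
        tnorm[~ok] = 1.0
        tang = tang / tnorm[:, None]
        beta_new = beta / rho
        snapped = np.cos(beta_new)[:, None] * d + np.sin(beta_new)[:, None] * tang
        snapped[~ok] = dirs[which][~ok]
        out = dirs
        out[which] = snapped
        return out


# ---------------------------------------------------------------------------
# head geometry
# ---------------------------------------------------------------------------


@dataclass
class HeadGeometry:
    """An ellipsoidal cranial cavity with zero or more craniectomy openings."""

    semi_axes: tuple[float, float, float]
    openings: list[OpeningSpec] = field(default_factory=list)
    sagittal_normal: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))

    @property
    def cavity_volume_ml(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0  # mm^3 -> ml

    @property
    def mean_radius_mm(self) -> float:
        a, b, c = self.semi_axes
        return float((a * b * c) ** (1.0 / 3.0))

    def surface_point(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        return _surface_scale(dirs, self.semi_axes)[:, None] * dirs

    def project_to_surface(self, points: np.ndarray) -> np.ndarray:
        """Radially project points onto the cavity surface."""
        pts = np.atleast_2d(np.asarray(points, float))
        n = np.linalg.norm(pts, axis=1, keepdims=True)
        dirs = pts / n
        return self.surface_point(dirs)


def _patch_area(opening: OpeningSpec, semi_axes, n_beta=256, n_psi=512) -> float:
    """Curved area of an opening patch by quadrature in cone coordinates."""
    d = opening.axis
    e1, e2 = opening._transverse_basis()
    psi = (np.arange(n_psi) + 0.5) / n_psi * 2 * np.pi
    dpsi = 2 * np.pi / n_psi
    if opening.kind == "unilateral_circular":
        beta_max = np.full(n_psi, opening.polar_angle(semi_axes))
    else:
        t1, t2 = opening.angular_extents
        beta_max = 1.0 / np.sqrt((np.cos(psi) / t1) ** 2 + (np.sin(psi) / t2) ** 2)
    t = (np.arange(n_beta) + 0.5) / n_beta  # beta = t * beta_max(psi)
    dt = 1.0 / n_beta
    B = t[:, None] * beta_max[None, :]           # (n_beta, n_psi)
    P = np.cos(psi)[None, :] * np.ones_like(B)
    # direction u(beta, psi) and its partials
    tangent = np.cos(psi)[None, :, None] * e1 + np.sin(psi)[None, :, None] * e2
    dtangent = (-np.sin(psi))[None, :, None] * e1 + np.cos(psi)[None, :, None] * e2
    u = np.cos(B)[:, :, None] * d + np.sin(B)[:, :, None] * tangent
    du_db = -np.sin(B)[:, :, None] * d + np.cos(B)[:, :, None] * tangent
    du_dpsi = np.sin(B)[:, :, None] * dtangent
    a, b, c = semi_axes
    inv2 = np.array([1.0 / a ** 2, 1.0 / b ** 2, 1.0 / c ** 2])
    q = np.einsum("ijk,k,ijk->ij", u, inv2, u)
    s = 1.0 / np.sqrt(q)                          # surface scale
    dq_db = 2 * np.einsum("ijk,k,ijk->ij", du_db, inv2, u)
    dq_dpsi = 2 * np.einsum("ijk,k,ijk->ij", du_dpsi, inv2, u)
    ds_db = -0.5 * s / q * dq_db
    ds_dpsi = -0.5 * s / q * dq_dpsi
    # P = s*u ; partials include the beta = t*beta_max(psi) chain rule
    Pb = ds_db[:, :, None] * u + s[:, :, None] * du_db
    dbeta_dpsi = t[:, None] * np.gradient(beta_max, psi)[None, :]
    Ppsi = (ds_dpsi[:, :, None] * u + s[:, :, None] * du_dpsi
            + dbeta_dpsi[:, :, None] * Pb)
    cross = np.cross(Pb, Ppsi)
    dA = np.linalg.norm(cross, axis=2) * beta_max[None, :] * dt * dpsi
    if opening.kind == "bifrontal_midline_bar":
        X = s[:, :, None] * u
        dA = dA * (np.abs(X[:, :, 0]) >= 0.5 * opening.bar_width_mm)
    return float(np.sum(dA))


def _solve_bifrontal_extents(opening: OpeningSpec, semi_axes) -> None:
    """Choose angular extents so the curved patch area matches the request
    within 0.5% (1D root-find on a uniform scaling of both extents)."""
    target = opening.requested_area_mm2
    base = opening.angular_extents or (0.9, 0.35)
    cap1, cap2 = 1.50, 1.45   # keep cones clear of the antipode

    def extents(scale):
        return (min(base[0] * scale, cap1), min(base[1] * scale, cap2))

    def area_of(scale):
        trial = OpeningSpec(kind=opening.kind, axis=opening.axis.copy(),
                            angular_extents=extents(scale),
                            bar_width_mm=opening.bar_width_mm,
                            requested_area_mm2=target)
        return _patch_area(trial, semi_axes, n_beta=96, n_psi=192)

    lo, hi = 0.05, max(cap1 / base[0], cap2 / base[1])
    f = lambda s: area_of(s) - target
    if f(hi) < 0:
        raise ValueError(
            f"requested bifrontal area {target} mm^2 exceeds what fits on the cavity")
    scale = brentq(f, lo, hi, xtol=1e-4)
    opening.angular_extents = extents(scale)


def build_idealized_head(semi_axes=DEFAULT_SEMI_AXES, openings=()) -> HeadGeometry:
    """Build an idealized ellipsoidal head geometry with craniectomy openings.

    Parameters
    ----------
    semi_axes : (a, b, c) in mm, all positive.  The default 80 x 66 x 59 mm
        cavity has an adult-scale volume of ~1.3 l.
    openings : sequence of :class:`OpeningSpec`.

    Opening areas are computed on the curved cavity surface and stored in
    ``area_mm2``; circular openings additionally report the planar disc area
    pi*r^2 in ``area_planar_mm2`` (the convention used when quoting
    craniectomy sizes clinically).
    """
    semi_axes = tuple(float(s) for s in semi_axes)
    if len(semi_axes) != 3 or any(s <= 0 for s in semi_axes):
        raise ValueError("semi_axes must be three positive lengths (mm)")
    geom = HeadGeometry(semi_axes=semi_axes, openings=list(openings))
    for op in geom.openings:
        if op.kind != "unilateral_circular" and op.angular_extents is None:
            _solve_bifrontal_extents(op, semi_axes)
        op.area_mm2 = _patch_area(op, semi_axes)
        if op.kind == "unilateral_circular":
            op.area_planar_mm2 = float(np.pi * op.radius_mm ** 2)
            # unilateral openings must stay clear of the mid-sagittal plane
            theta = op.polar_angle(semi_axes)
            plane_angle = np.arcsin(min(1.0, abs(op.axis[0])))
            if plane_angle <= theta + 1e-9:
                raise ValueError(
                    "unilateral opening intersects the mid-sagittal plane "
                    f"(axis angle to plane {np.degrees(plane_angle):.1f} deg, "
                    f"cone half-angle {np.degrees(theta):.1f} deg)")
        else:
            op.area_planar_mm2 = op.area_mm2
    _check_overlaps(geom)
    return geom


def _check_overlaps(geom: HeadGeometry) -> None:
    if len(geom.openings) < 2:
        return
    dirs, _ = _icosphere(4)
    pts = geom.surface_point(dirs)
    masks = [op.contains(pts, geom.semi_axes) for op in geom.openings]
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if np.any(masks[i] & masks[j]):
                raise ValueError(f"openings {i} and {j} overlap on the cavity surface")


# ---------------------------------------------------------------------------
# icosphere and layered ball meshing
# ---------------------------------------------------------------------------

def _icosahedron():
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
        (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
        (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ], dtype=np.int64)
    return verts, faces


def _icosphere(nsub: int):
    """Unit-sphere triangulation: subdivided icosahedron, outward-oriented."""
    verts, faces = _icosahedron()
    for _ in range(nsub):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for (i, j, k) in faces:
            a = midpoint(i, j)
            b = midpoint(j, k)
            c = midpoint(k, i)
            new_faces += [(i, a, c), (j, b, a), (k, c, b), (a, b, c)]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=np.int64)
    return verts, faces


_PRISM_ROT = {
    0: (0, 1, 2, 3, 4, 5),
    1: (1, 2, 0, 4, 5, 3),
    2: (2, 0, 1, 5, 3, 4),
    3: (3, 5, 4, 0, 2, 1),
    4: (4, 3, 5, 1, 0, 2),
    5: (5, 4, 3, 2, 1, 0),
}


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split prisms (n, 6) with bottom (0,1,2) / top (3,4,5) into 3 tets each,
    choosing quad-face diagonals through the globally smallest vertex index so
    neighbouring prisms triangulate shared faces identically."""
    n = prisms.shape[0]
    tets = np.empty((3 * n, 4), dtype=np.int64)
    argmin = np.argmin(prisms, axis=1)
    for loc, perm in _PRISM_ROT.items():
        sel = argmin == loc
        if not np.any(sel):
            continue
        p = prisms[sel][:, perm]
        # diagonal choice on the quad face opposite vertex 0
        first = np.minimum(p[:, 1], p[:, 5]) < np.minimum(p[:, 2], p[:, 4])
        idx = np.nonzero(sel)[0]
        t = np.empty((sel.sum(), 3, 4), dtype=np.int64)
        f = first
        t[f, 0] = p[f][:, (0, 1, 2, 5)]
        t[f, 1] = p[f][:, (0, 1, 5, 4)]
        t[f, 2] = p[f][:, (0, 4, 5, 3)]
        g = ~first
        t[g, 0] = p[g][:, (0, 1, 2, 4)]
        t[g, 1] = p[g][:, (0, 4, 2, 5)]
        t[g, 2] = p[g][:, (0, 4, 5, 3)]
        tets[3 * idx[:, None] + np.arange(3)[None, :]] = t
    return tets.reshape(-1, 4)


# ---------------------------------------------------------------------------
# labeled mesh
# ---------------------------------------------------------------------------


@dataclass
class LabeledMesh:
    """Tetrahedral mesh with tagged boundary facets and hemisphere regions.

    ``nodes`` are vertex coordinates in mm; ``cells`` the tet connectivity
    (positive orientation); ``facets``/``facet_tags`` the boundary triangles
    and their tags (:data:`FIXED_INTERFACE_TAG` or ``opening_tag(k)``);
    ``region_tags`` assigns each cell to a hemisphere.  ``geometry`` is kept
    (when the mesh was generated) so that higher-order boundary nodes can be
    snapped onto the curved cavity surface.
    """

    nodes: np.ndarray
    cells: np.ndarray
    facets: np.ndarray
    facet_tags: np.ndarray
    region_tags: np.ndarray
    characteristic_h_mm: float
    geometry: HeadGeometry | None = None

    # -- measures ----------------------------------------------------------

    def cell_volumes(self) -> np.ndarray:
        """Signed tetrahedron volumes in mm^3."""
        x = self.nodes[self.cells]
        return np.einsum(
            "ij,ij->i",
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]),
            x[:, 3] - x[:, 0]) / 6.0

    def volume_ml(self) -> float:
        return float(self.cell_volumes().sum() / 1000.0)

    def facet_areas(self) -> np.ndarray:
        x = self.nodes[self.facets]
        return 0.5 * np.linalg.norm(np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)

    def opening_area_mm2(self, k: int) -> float:
        """Discrete area of opening ``k`` (1-based) from its tagged facets."""
        return float(self.facet_areas()[self.facet_tags == opening_tag(k)].sum())

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        vols = self.cell_volumes()
        if np.any(vols <= 0):
            bad = int(np.argmin(vols))
            raise ValueError(
                f"mesh contains non-positive tetrahedra (first: cell {bad}, "
                f"volume {vols[bad]:.3g} mm^3)")
        faces = _tet_faces(self.cells)
        key = np.sort(faces.reshape(-1, 3), axis=1)
        uniq, counts = np.unique(key, axis=0, return_counts=True)
        boundary = uniq[counts == 1]
        if np.any(counts > 2):
            raise ValueError("mesh is not a manifold (a face is shared by >2 cells)")
        tagged = np.sort(self.facets, axis=1)
        if boundary.shape != tagged.shape or not np.array_equal(
                boundary, tagged[np.lexsort(tagged.T[::-1])]):
            raise ValueError("facet_tags do not exactly partition the mesh boundary")
        if len(self.region_tags) != len(self.cells):
            raise ValueError("region_tags must tag every cell")

    def edge_lengths(self) -> np.ndarray:
        e = np.vstack([self.cells[:, p] for p in
                       [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]])
        e = np.unique(np.sort(e, axis=1), axis=0)
        return np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)


def _tet_faces(cells: np.ndarray) -> np.ndarray:
    """The four outward-oriented faces of each tet, shape (ncells, 4, 3)."""
    c = cells
    return np.stack([
        c[:, (1, 2, 3)], c[:, (0, 3, 2)], c[:, (0, 1, 3)], c[:, (0, 2, 1)],
    ], axis=1)


def mesh_head(geom: HeadGeometry, h: float = 8.0,
              nsub: int | None = None, n_layers: int | None = None) -> LabeledMesh:
    """Mesh a head geometry with tetrahedra of target size ``h`` (mm).

    The mesh is a layered icosphere ball mapped radially onto the ellipsoid.
    Surface vertices near an opening rim are snapped onto the rim so the
    tagged patch has a clean polygonal boundary.  Facets on opening ``k``
    are tagged ``opening_tag(k)``, all other boundary facets
    :data:`FIXED_INTERFACE_TAG`; cells are tagged by hemisphere.

    ``nsub`` (icosphere subdivisions, angular resolution) and ``n_layers``
    (radial shells) default to an isotropic choice for ``h`` but can be
    overridden, e.g. for radially-graded verification meshes.
    """
    if h <= 0:
        raise ValueError("element size h must be positive")
    for op in geom.openings:
        if op.kind == "unilateral_circular" and h >= op.radius_mm:
            raise ValueError(
                f"element size h={h} mm must be smaller than the smallest "
                f"opening radius ({op.radius_mm} mm)")
    rbar = geom.mean_radius_mm
    if nsub is None:
        nsub = int(np.clip(round(np.log2(1.0515 * rbar / h)), 1, 5))
    if n_layers is None:
        n_layers = int(np.clip(round(rbar / h), 2, 64))

    sverts, sfaces = _icosphere(nsub)
    # snap surface directions onto opening rims before layering so the whole
    # radial column conforms and the tagged patch has a clean boundary
    sedges = np.unique(np.sort(np.vstack(
        [sfaces[:, (0, 1)], sfaces[:, (1, 2)], sfaces[:, (2, 0)]]), axis=1), axis=0)
    for op in geom.openings:
        rho = op.rim_distance(sverts, geom.semi_axes) + 1.0
        crossing = (rho[sedges[:, 0]] - 1.0) * (rho[sedges[:, 1]] - 1.0) < 0
        ce = sedges[crossing]
        closer = np.where(np.abs(rho[ce[:, 0]] - 1) <= np.abs(rho[ce[:, 1]] - 1),
                          ce[:, 0], ce[:, 1])
        which = np.zeros(len(sverts), bool)
        which[np.unique(closer)] = True
        sverts = op.snap_dirs_to_rim(sverts, which, geom.semi_axes)
        sverts /= np.linalg.norm(sverts, axis=1, keepdims=True)
        if op.kind == "bifrontal_midline_bar":
            sverts = _snap_bar_edges(sverts, sedges, op, geom)

    nodes_unit, tets, boundary = _ball_mesh_from_surface(sverts, sfaces, n_layers)
    radius = np.linalg.norm(nodes_unit[1:], axis=1)  # node 0 is the center
    dirs = nodes_unit[1:] / radius[:, None]
    scale = _surface_scale(dirs, geom.semi_axes)
    nodes = np.zeros_like(nodes_unit)
    nodes[1:] = dirs * (radius * scale)[:, None]

    mesh = LabeledMesh(
        nodes=nodes, cells=tets,
        facets=boundary, facet_tags=np.full(len(boundary), FIXED_INTERFACE_TAG, np.int64),
        region_tags=np.ones(len(tets), np.int64),
        characteristic_h_mm=float(h), geometry=geom)

    # facet tags: a boundary facet belongs to an opening iff all three of its
    # (rim-snapped) vertices lie inside or on the rim -- the tagged patch is
    # the polygon inscribed in the opening boundary
    surf_dirs = sverts
    vert_of_facet = (boundary - boundary.min())  # surface-local vertex ids
    bary = nodes[boundary].mean(axis=1)
    for k, op in enumerate(geom.openings, start=1):
        rho = op.rim_distance(surf_dirs, geom.semi_axes) + 1.0
        vin = rho <= 1.0 + 1e-6
        if op.kind == "bifrontal_midline_bar":
            x = geom.surface_point(surf_dirs)[:, 0]
            vin &= np.abs(x) >= 0.5 * op.bar_width_mm - 1e-6 * rbar
            inside = vin[vert_of_facet].all(axis=1) \
                & (np.abs(bary[:, 0]) > 0.5 * op.bar_width_mm)
        else:
            inside = vin[vert_of_facet].all(axis=1)
        mesh.facet_tags[inside] = opening_tag(k)
    # hemisphere region tags from cell barycenters
    cbary = nodes[tets].mean(axis=1)
    mesh.region_tags = np.where(cbary[:, 0] > 0, REGION_LEFT, REGION_RIGHT).astype(np.int64)

    try:
        mesh.validate()
    except ValueError as err:
        raise ValueError(f"meshing failed for h={h} mm: {err}") from err
    return mesh


def _snap_bar_edges(sverts, sedges, op, geom):
    """Move, for every surface edge crossing a midline-bar boundary plane
    x = +-w/2 inside the opening cone, the endpoint closer to the plane onto
    it (then re-project to the unit sphere of directions)."""
    w2 = 0.5 * op.bar_width_mm
    inside_cone = op.rim_distance(sverts, geom.semi_axes) < 0.1
    for sgn in (+1.0, -1.0):
        pts = geom.surface_point(sverts)
        dist = pts[:, 0] - sgn * w2
        crossing = (dist[sedges[:, 0]] * dist[sedges[:, 1]] < 0) \
            & inside_cone[sedges[:, 0]] & inside_cone[sedges[:, 1]]
        ce = sedges[crossing]
        if len(ce) == 0:
            continue
        closer = np.where(np.abs(dist[ce[:, 0]]) <= np.abs(dist[ce[:, 1]]),
                          ce[:, 0], ce[:, 1])
        which = np.unique(closer)
        moved = pts[which].copy()
        moved[:, 0] = sgn * w2
        proj = geom.project_to_surface(moved)
        sverts[which] = proj / np.linalg.norm(proj, axis=1, keepdims=True)
    return sverts


def _ball_mesh_from_surface(sverts, sfaces, n_layers):
    nv = len(sverts)
    nodes = [np.zeros((1, 3))]
    for j in range(1, n_layers + 1):
        nodes.append(sverts * (j / n_layers))
    nodes = np.vstack(nodes)

    def shell(j):
        return 1 + (j - 1) * nv

    tets = [np.hstack([np.zeros((len(sfaces), 1), np.int64), shell(1) + sfaces])]
    for j in range(1, n_layers):
        prisms = np.hstack([shell(j) + sfaces, shell(j + 1) + sfaces])
        tets.append(_split_prisms(prisms))
    tets = np.vstack(tets)
    boundary = shell(n_layers) + sfaces
    return nodes, tets, boundary


# ---------------------------------------------------------------------------
# mesh I/O: Gmsh MSH 4.1 (ASCII), VTU (ASCII XML), XDMF + HDF5
# ---------------------------------------------------------------------------

_FORMATS = ("gmsh_msh", "vtu", "xdmf")
_SUFFIX_FORMAT = {".msh": "gmsh_msh", ".vtu": "vtu", ".xdmf": "xdmf"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown mesh format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer mesh format from suffix {path.suffix!r}; "
                         f"pass format= explicitly") from None


def write_mesh(mesh: LabeledMesh, path, format: str | None = None) -> None:
    """Write a labeled mesh to Gmsh MSH 4.1 ASCII, VTU or XDMF+HDF5.

    Facet and region tags are stored as integer data fields named
    ``facet_tag`` and ``region_tag`` (VTU/XDMF) or as entity tags (MSH).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gmsh_msh":
        _write_msh(mesh, path)
    elif fmt == "vtu":
        _write_vtu_mesh(mesh, path)
    else:
        _write_xdmf(mesh, path)


def read_mesh(path, format: str | None = None) -> LabeledMesh:
    """Read a labeled tetrahedral mesh written by :func:`write_mesh` (or a
    compatible external file).  Non-tetrahedral volume cells are rejected;
    missing tag data raises an error naming the required fields."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "gmsh_msh":
        mesh = _read_msh(path)
    elif fmt == "vtu":
        mesh = _read_vtu(path)
    else:
        mesh = _read_xdmf(path)
    if len(mesh.cells) == 0:
        raise ValueError(f"{path}: no tetrahedral cells found")
    mesh.characteristic_h_mm = float(np.mean(mesh.edge_lengths()))
    return mesh


# -- Gmsh MSH 4.1 -----------------------------------------------------------


def _write_msh(mesh: LabeledMesh, path: Path) -> None:
    ftags = np.unique(mesh.facet_tags)
    rtags = np.unique(mesh.region_tags)
    out = io.StringIO()
    out.write("$MeshFormat\n4.1 0 8\n$EndMeshFormat\n")
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bbox = f"{lo[0]:.17g} {lo[1]:.17g} {lo[2]:.17g} {hi[0]:.17g} {hi[1]:.17g} {hi[2]:.17g}"
    out.write("$Entities\n")
    out.write(f"0 0 {len(ftags)} {len(rtags)}\n")
    for t in ftags:
        out.write(f"{t} {bbox} 1 {t} 0\n")
    for t in rtags:
        out.write(f"{t} {bbox} 1 {t} 0\n")
    out.write("$EndEntities\n")
    n = len(mesh.nodes)
    out.write("$Nodes\n")
    out.write(f"1 {n} 1 {n}\n")
    out.write(f"3 {rtags[0]} 0 {n}\n")
    out.write("\n".join(str(i + 1) for i in range(n)))
    out.write("\n")
    out.write("\n".join(f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.nodes))
    out.write("\n$EndNodes\n")
    nelem = len(mesh.facets) + len(mesh.cells)
    blocks = []
    eid = 1

    def runs(tags):
        # contiguous runs of equal tag, preserving element order exactly
        cut = np.nonzero(np.diff(tags))[0] + 1
        return np.split(np.arange(len(tags)), cut)

    for idx in runs(mesh.facet_tags):
        tri = mesh.facets[idx]
        rows = [f"{eid + i} " + " ".join(str(v + 1) for v in row)
                for i, row in enumerate(tri)]
        blocks.append((2, mesh.facet_tags[idx[0]], 2, rows))
        eid += len(tri)
    for idx in runs(mesh.region_tags):
        tet = mesh.cells[idx]
        rows = [f"{eid + i} " + " ".join(str(v + 1) for v in row)
                for i, row in enumerate(tet)]
        blocks.append((3, mesh.region_tags[idx[0]], 4, rows))
        eid += len(tet)
    out.write("$Elements\n")
    out.write(f"{len(blocks)} {nelem} 1 {nelem}\n")
    for dim, tag, etype, rows in blocks:
        out.write(f"{dim} {tag} {etype} {len(rows)}\n")
        out.write("\n".join(rows))
        out.write("\n")
    out.write("$EndElements\n")
    path.write_text(out.getvalue())


def _read_msh(path: Path) -> LabeledMesh:
    text = path.read_text().split("\n")
    sections: dict[str, list[str]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                body.append(text[j])
                j += 1
            sections[name] = body
            i = j
        i += 1
    if "Nodes" not in sections or "Elements" not in sections:
        raise ValueError(f"{path}: missing $Nodes/$Elements sections")
    # nodes
    body = sections["Nodes"]
    nblocks, nnodes, _, _ = (int(v) for v in body[0].split())
    tags = np.empty(nnodes, np.int64)
    coords = np.empty((nnodes, 3))
    pos = 1
    filled = 0
    for _ in range(nblocks):
        _, _, _, nb = (int(v) for v in body[pos].split())
        pos += 1
        tags[filled:filled + nb] = [int(body[pos + i].split()[0]) for i in range(nb)]
        pos += nb
        for i in range(nb):
            coords[filled + i] = [float(v) for v in body[pos + i].split()[:3]]
        pos += nb
        filled += nb
    remap = {t: i for i, t in enumerate(tags)}
    # elements
    body = sections["Elements"]
    nblocks = int(body[0].split()[0])
    pos = 1
    tris, tri_tags, tets, tet_tags = [], [], [], []
    for _ in range(nblocks):
        dim, etag, etype, nb = (int(v) for v in body[pos].split())
        pos += 1
        rows = [body[pos + i].split()[1:] for i in range(nb)]
        pos += nb
        if etype == 2:
            tris += [[remap[int(v)] for v in r] for r in rows]
            tri_tags += [etag] * nb
        elif etype == 4:
            tets += [[remap[int(v)] for v in r] for r in rows]
            tet_tags += [etag] * nb
        elif dim == 3:
            raise ValueError(
                f"{path}: non-tetrahedral volume elements (gmsh type {etype}) "
                "are not supported")
        # lower-dimensional elements other than triangles are ignored
    if not tris:
        raise ValueError(f"{path}: no tagged boundary triangles; required tag "
                         "fields: facet_tag (surface entities), region_tag "
                         "(volume entities)")
    return LabeledMesh(
        nodes=coords, cells=np.asarray(tets, np.int64),
        facets=np.asarray(tris, np.int64), facet_tags=np.asarray(tri_tags, np.int64),
        region_tags=np.asarray(tet_tags, np.int64), characteristic_h_mm=0.0)


# -- VTU --------------------------------------------------------------------


def _vtu_data_array(name, data, dtype):
    arr = np.asarray(data)
    ncomp = 1 if arr.ndim == 1 else arr.shape[1]
    flat = arr.reshape(-1)
    if dtype.startswith("Float"):
        body = " ".join(f"{v:.17g}" for v in flat)
    else:
        body = " ".join(str(int(v)) for v in flat)
    nm = f' Name="{name}"' if name else ""
    return (f'<DataArray type="{dtype}"{nm} NumberOfComponents="{ncomp}" '
            f'format="ascii">\n{body}\n</DataArray>\n')


def write_vtu(path, nodes, tets, point_data=None, cell_data=None,
              extra_cells=None, extra_cell_types=None):
    """Minimal ASCII VTU writer.  ``tets`` may be 4-node (VTK type 10) or
    10-node (VTK type 24) tetrahedra; ``extra_cells`` appends further cells
    (e.g. boundary triangles, type 5)."""
    tets = np.asarray(tets, np.int64)
    vtk_type = 10 if tets.shape[1] == 4 else 24
    cells = [(tets, vtk_type)]
    if extra_cells is not None:
        cells.append((np.asarray(extra_cells, np.int64), extra_cell_types))
    conn = np.concatenate([c.reshape(-1) for c, _ in cells])
    sizes = np.concatenate([[c.shape[1]] * len(c) for c, _ in cells])
    offsets = np.cumsum(sizes)
    types = np.concatenate([[t] * len(c) for c, t in cells])
    ncells = len(types)
    out = io.StringIO()
    out.write('<?xml version="1.0"?>\n'
              '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n'
              '<UnstructuredGrid>\n')
    out.write(f'<Piece NumberOfPoints="{len(nodes)}" NumberOfCells="{ncells}">\n')
    out.write("<Points>\n")
    out.write(_vtu_data_array(None, nodes, "Float64"))
    out.write("</Points>\n<Cells>\n")
    out.write(_vtu_data_array("connectivity", conn, "Int64"))
    out.write(_vtu_data_array("offsets", offsets, "Int64"))
    out.write(_vtu_data_array("types", types, "Int64"))
    out.write("</Cells>\n")
    if point_data:
        out.write("<PointData>\n")
        for name, data in point_data.items():
            out.write(_vtu_data_array(name, data, "Float64"))
        out.write("</PointData>\n")
    if cell_data:
        out.write("<CellData>\n")
        for name, data in cell_data.items():
            dtype = "Int64" if np.issubdtype(np.asarray(data).dtype, np.integer) else "Float64"
            out.write(_vtu_data_array(name, data, dtype))
        out.write("</CellData>\n")
    out.write("</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
    Path(path).write_text(out.getvalue())


def _write_vtu_mesh(mesh: LabeledMesh, path: Path) -> None:
    ntet = len(mesh.cells)
    ntri = len(mesh.facets)
    region = np.concatenate([mesh.region_tags, np.zeros(ntri, np.int64)])
    facet = np.concatenate([np.zeros(ntet, np.int64), mesh.facet_tags])
    write_vtu(path, mesh.nodes, mesh.cells,
              cell_data={"region_tag": region, "facet_tag": facet},
              extra_cells=mesh.facets, extra_cell_types=5)


def read_vtu(path):
    """Read an ASCII VTU file; returns (nodes, cells_by_type, cell_data)."""
    tree = ET.parse(path)
    piece = tree.getroot().find(".//Piece")
    arrays = {}
    for da in piece.iter("DataArray"):
        name = da.get("Name")
        text = (da.text or "").split()
        if da.get("type", "").startswith("Float"):
            data = np.array([float(v) for v in text])
        else:
            data = np.array([int(v) for v in text], np.int64)
        ncomp = int(da.get("NumberOfComponents", "1"))
        if ncomp > 1:
            data = data.reshape(-1, ncomp)
        key = name if name else "__points__"
        arrays[key] = data
    pts = piece.find("Points/DataArray")
    text = pts.text.split()
    nodes = np.array([float(v) for v in text]).reshape(-1, 3)
    conn = arrays["connectivity"]
    offsets = arrays["offsets"]
    types = arrays["types"]
    starts = np.concatenate([[0], offsets[:-1]])
    cells_by_type: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for t in np.unique(types):
        sel = types == t
        size = int(offsets[sel][0] - starts[sel][0])
        rows = np.array([conn[s:s + size] for s in starts[sel]], np.int64)
        cells_by_type[int(t)] = (rows, np.nonzero(sel)[0])
    cell_data = {k: v for k, v in arrays.items()
                 if k not in ("connectivity", "offsets", "types", "__points__")
                 and len(np.atleast_1d(v)) == len(types)}
    return nodes, cells_by_type, cell_data


def _read_vtu(path: Path) -> LabeledMesh:
    nodes, cells_by_type, cell_data = read_vtu(path)
    bad = [t for t in cells_by_type if t not in (5, 10)]
    if bad:
        raise ValueError(f"{path}: unsupported VTK cell types {bad}; only "
                         "tetrahedra (10) and boundary triangles (5) are read")
    if 10 not in cells_by_type:
        raise ValueError(f"{path}: no tetrahedral cells")
    for name in ("region_tag", "facet_tag"):
        if name not in cell_data:
            raise ValueError(f"{path}: missing required cell data fields: "
                             "region_tag, facet_tag")
    tets, tet_idx = cells_by_type[10]
    tris, tri_idx = cells_by_type.get(5, (np.empty((0, 3), np.int64), np.empty(0, np.int64)))
    return LabeledMesh(
        nodes=nodes, cells=tets, facets=tris,
        facet_tags=np.asarray(cell_data["facet_tag"], np.int64)[tri_idx],
        region_tags=np.asarray(cell_data["region_tag"], np.int64)[tet_idx],
        characteristic_h_mm=0.0)


# -- XDMF + HDF5 ------------------------------------------------------------


def _write_xdmf(mesh: LabeledMesh, path: Path) -> None:
    import h5py

    h5path = path.with_suffix(".h5")
    with h5py.File(h5path, "w") as h5:
        h5["/mesh/nodes"] = mesh.nodes
        h5["/mesh/tets"] = mesh.cells
        h5["/mesh/tris"] = mesh.facets
        h5["/mesh/region_tag"] = mesh.region_tags
        h5["/mesh/facet_tag"] = mesh.facet_tags
    hname = h5path.name
    xml = f"""<?xml version="1.0"?>
<Xdmf Version="3.0">
  <Domain>
    <Grid Name="brain">
      <Topology TopologyType="Tetrahedron" NumberOfElements="{len(mesh.cells)}">
        <DataItem Dimensions="{len(mesh.cells)} 4" NumberType="Int" Format="HDF">{hname}:/mesh/tets</DataItem>
      </Topology>
      <Geometry GeometryType="XYZ">
        <DataItem Dimensions="{len(mesh.nodes)} 3" Format="HDF">{hname}:/mesh/nodes</DataItem>
      </Geometry>
      <Attribute Name="region_tag" Center="Cell">
        <DataItem Dimensions="{len(mesh.cells)}" NumberType="Int" Format="HDF">{hname}:/mesh/region_tag</DataItem>
      </Attribute>
    </Grid>
    <Grid Name="boundary">
      <Topology TopologyType="Triangle" NumberOfElements="{len(mesh.facets)}">
        <DataItem Dimensions="{len(mesh.facets)} 3" NumberType="Int" Format="HDF">{hname}:/mesh/tris</DataItem>
      </Topology>
      <Geometry GeometryType="XYZ">
        <DataItem Dimensions="{len(mesh.nodes)} 3" Format="HDF">{hname}:/mesh/nodes</DataItem>
      </Geometry>
      <Attribute Name="facet_tag" Center="Cell">
        <DataItem Dimensions="{len(mesh.facets)}" NumberType="Int" Format="HDF">{hname}:/mesh/facet_tag</DataItem>
      </Attribute>
    </Grid>
  </Domain>
</Xdmf>
"""
    path.write_text(xml)


def _read_xdmf(path: Path) -> LabeledMesh:
    import h5py

    tree = ET.parse(path)
    items: dict[str, str] = {}

    def dataitem_path(elem):
        ref = elem.find("DataItem").text.strip()
        fname, dset = ref.split(":")
        return (path.parent / fname, dset)

    grids = tree.getroot().findall(".//Grid")
    nodes = cells = tris = rtag = ftag = None
    for grid in grids:
        topo = grid.find("Topology")
        ttype = topo.get("TopologyType", "")
        fname, dset = dataitem_path(topo)
        with h5py.File(fname, "r") as h5:
            conn = np.asarray(h5[dset], np.int64)
            gname, gdset = dataitem_path(grid.find("Geometry"))
            nodes = np.asarray(h5[gdset], float) if gname == fname else nodes
            for attr in grid.findall("Attribute"):
                aname, adset = dataitem_path(attr)
                data = np.asarray(h5[adset], np.int64)
                if attr.get("Name") == "region_tag":
                    rtag = data
                elif attr.get("Name") == "facet_tag":
                    ftag = data
        if ttype == "Tetrahedron":
            cells = conn
        elif ttype == "Triangle":
            tris = conn
        else:
            raise ValueError(f"{path}: unsupported topology {ttype!r}; only "
                             "Tetrahedron volumes (plus Triangle boundaries) are read")
    missing = [n for n, v in [("region_tag", rtag), ("facet_tag", ftag)] if v is None]
    if cells is None:
        raise ValueError(f"{path}: no Tetrahedron grid")
    if missing:
        raise ValueError(f"{path}: missing required tag fields: {', '.join(missing)}")
    return LabeledMesh(nodes=nodes, cells=cells,
                       facets=tris if tris is not None else np.empty((0, 3), np.int64),
                       facet_tags=ftag, region_tags=rtag, characteristic_h_mm=0.0)
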