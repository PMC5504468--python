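"""Coordinate frames, triangle-mesh primitives, surface arcs and projections.

All coordinates are millimetres in the AC-PC frame: the origin sits at the
midpoint of the anterior and posterior commissures, +x runs left to right,
+y posterior to anterior along the AC-PC line, and +z inferior to superior
within the midsagittal plane.

Surface "arcs" here are plane-section polylines on a triangulated surface,
not true geodesics: a curve between two anchor points is obtained by cutting
the mesh with the plane through the anchors and a third point, then keeping
the sub-arc that passes nearest the third point.  This is the construction
used by virtual scalp-positioning methods and is exact on spheres.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("scalpmap")

#: default point-on-surface tolerance, mm
DEFAULT_MESH_TOL = 0.5

LANDMARK_NAMES = {
    1: "vertex",
    2: "frontal pole",
    3: "temporal pole",
    4: "base of the brain",
    5: "occipital pole",
    6: "lateral extreme",
    7: "upper end of the central sulcus",
    8: "junction of superior frontal and precentral sulci",
    9: "junction of inferior frontal and precentral sulci",
    10: "root of the ascending ramus of the Sylvian fissure",
    11: "inferior termination of the central sulcus (CS tip)",
    12: "junction of postcentral and intraparietal sulci",
    13: "preoccipital notch",
    14: "calcarine fissure (lateral aspect)",
    15: "parieto-occipital sulcus",
    16: "Sylvian fissure on the CS-tip coronal slice",
    17: "superior temporal sulcus on the CS-tip coronal slice",
    18: "inferior temporal sulcus on the CS-tip coronal slice",
    19: "most ventral lateral temporal point on the CS-tip coronal slice",
    20: "root of the posterior ascending branch of the Sylvian fissure",
}

FIDUCIAL_NAMES = ("Nz", "Iz", "AL", "AR")


class DegenerateFrameError(ValueError):
    """Raised when AC, PC and the midsagittal point do not define a frame."""


class NoArcError(RuntimeError):
    """Raised when a plane section does not yield an arc between the anchors."""


class RayMissError(RuntimeError):
    """Raised when a ray does not intersect the mesh."""


# ---------------------------------------------------------------------------
# rigid transforms and the AC-PC frame
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        return RigidTransform(rot, -rot @ self.translation)


def acpc_align(points, ac, pc, mid_sagittal):
    """Align coordinates to the AC-PC frame.

    Returns ``(transform, aligned_points)`` where the transform maps input
    coordinates into the frame with the AC-PC midpoint at the origin, AC on
    the +y axis and the midsagittal point in the x=0 half-plane with z > 0.
    """
    ac = np.asarray(ac, dtype=float)
    pc = np.asarray(pc, dtype=float)
    mid = np.asarray(mid_sagittal, dtype=float)
    if not (np.all(np.isfinite(ac)) and np.all(np.isfinite(pc)) and np.all(np.isfinite(mid))):
        raise ValueError("non-finite frame points")
    origin = 0.5 * (ac + pc)
    y = ac - origin
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise DegenerateFrameError("AC and PC coincide")
    y = y / ny
    m = mid - origin
    z = m - (m @ y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-9 * max(1.0, np.linalg.norm(m)):
        raise DegenerateFrameError("midsagittal point lies on the AC-PC line")
    z = z / nz
    x = np.cross(y, z)
    basis = np.column_stack([x, y, z])  # orthonormal, det +1 by construction
    transform = RigidTransform(basis.T, -basis.T @ origin)
    return transform, transform.apply(np.asarray(points, dtype=float))


def project(point, plane: str):
    """Project onto the sagittal (x := 0) or coronal (y := 0) plane."""
    p = np.array(point, dtype=float)
    if plane == "sagittal":
        p[..., 0] = 0.0
    elif plane == "coronal":
        p[..., 1] = 0.0
    else:
        raise ValueError(f"unknown plane {plane!r}")
    return p


# ---------------------------------------------------------------------------
# triangle meshes
# ---------------------------------------------------------------------------

class TriangleMesh:
    """Triangulated surface with vertices in mm; faces are 0-based index triples."""

    def __init__(self, vertices, faces, drop_degenerate: bool = True):
        self.vertices = np.ascontiguousarray(vertices, dtype=float)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if faces.size and (faces.min() < 0 or faces.max() >= len(self.vertices)):
            raise ValueError("face index out of range")
        if drop_degenerate and faces.size:
            v = self.vertices
            areas = 0.5 * np.linalg.norm(
                np.cross(v[faces[:, 1]] - v[faces[:, 0]], v[faces[:, 2]] - v[faces[:, 0]]),
                axis=1,
            )
            bad = areas < 1e-12
            if bad.any():
                logger.warning("dropping %d degenerate faces", int(bad.sum()))
                faces = faces[~bad]
        self.faces = faces
        self._median_edge = None
        self._watertight = None

    def __repr__(self):  # pragma: no cover
        return f"TriangleMesh({len(self.vertices)} vertices, {len(self.faces)} faces)"

    @property
    def median_edge_length(self) -> float:
        if self._median_edge is None:
            e = self._edges()
            self._median_edge = float(
                np.median(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1))
            )
        return self._median_edge

    def _edges(self) -> np.ndarray:
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def boundary_edge_count(self) -> int:
        f = self.faces
        e = np.sort(np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return int(np.sum(counts != 2))

    @property
    def is_watertight(self) -> bool:
        if self._watertight is None:
            self._watertight = self.boundary_edge_count() == 0
        return self._watertight

    def nearest_vertex(self, point) -> np.ndarray:
        d = np.linalg.norm(self.vertices - np.asarray(point, dtype=float), axis=1)
        return self.vertices[int(np.argmin(d))].copy()

    def transformed(self, transform: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(transform.apply(self.vertices), self.faces, drop_degenerate=False)

    def scaled(self, factor: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * float(factor), self.faces, drop_degenerate=False)


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Geodesic sphere from a subdivided icosahedron (watertight)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            (-1, phi, 0), (1, phi, 0), (-1, -phi, 0), (1, -phi, 0),
            (0, -1, phi), (0, 1, phi), (0, -1, -phi), (0, 1, -phi),
            (phi, 0, -1), (phi, 0, 1), (-phi, 0, -1), (-phi, 0, 1),
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [tuple(v) for v in verts]
    for _ in range(subdivisions):
        cache: dict[tuple[int, int], int] = {}

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in cache:
                m = np.array(verts[i]) + np.array(verts[j])
                m /= np.linalg.norm(m)
                verts.append(tuple(m))
                cache[key] = len(verts) - 1
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [(a, ab, ca), (b, bc, ab), (c, ca, bc), (ab, bc, ca)]
        faces = new_faces
    v = np.array(verts) * radius + np.asarray(center, dtype=float)
    return TriangleMesh(v, np.array(faces))


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def ray_intersections(mesh: TriangleMesh, origin, direction) -> np.ndarray:
    """All positive ray parameters of mesh intersections (sorted ascending)."""
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if n < 1e-12:
        raise ValueError("zero direction")
    d = direction / n
    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    h = np.cross(np.broadcast_to(d, e2.shape), e2)
    a = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(a) > 1e-12
    f = np.zeros_like(a)
    f[ok] = 1.0 / a[ok]
    s = origin - v0
    u = f * np.einsum("ij,ij->i", s, h)
    q = np.cross(s, e1)
    v = f * (q @ d)
    t = f * np.einsum("ij,ij->i", e2, q)
    eps = 1e-9
    hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > 1e-7)
    return np.sort(t[hit])


def ray_surface_intersection(mesh: TriangleMesh, origin, direction) -> np.ndarray:
    """Outermost (largest positive parameter) intersection of a ray with the mesh."""
    t = ray_intersections(mesh, origin, direction)
    if t.size == 0:
        raise RayMissError("ray does not intersect the mesh")
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    return np.asarray(origin, dtype=float) + t[-1] * d


# ---------------------------------------------------------------------------
# plane sections and surface arcs
# ---------------------------------------------------------------------------

@dataclass
class SurfaceArc:
    """Ordered polyline on a mesh with cumulative arc length."""

    points: np.ndarray
    cumulative_length: np.ndarray = field(init=False)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
            raise ValueError("polyline needs at least two 3-D points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 1e-12])
        pts = pts[keep]
        if len(pts) < 2:
            raise NoArcError("zero-length arc")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.points = pts
        self.cumulative_length = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.cumulative_length[-1])

    @property
    def endpoints(self):
        return self.points[0].copy(), self.points[-1].copy()

    def point_at_fraction(self, f: float) -> np.ndarray:
        return point_at_fraction(self, f)

    def point_at_length(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length))
        cum = self.cumulative_length
        i = int(np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(cum) - 2))
        seg = cum[i + 1] - cum[i]
        t = 0.0 if seg == 0 else (s - cum[i]) / seg
        return (1 - t) * self.points[i] + t * self.points[i + 1]

    def locate(self, point) -> float:
        """Arc length of the nearest point on the polyline to ``point``."""
        s, _, _ = _project_to_polyline(self.points, np.asarray(point, dtype=float), closed=False)
        return s

    def min_distance(self, point) -> float:
        _, d, _ = _project_to_polyline(self.points, np.asarray(point, dtype=float), closed=False)
        return d


def point_at_fraction(arc: SurfaceArc, f: float) -> np.ndarray:
    """Point at arc-length fraction ``f`` in [0, 1] from the arc start."""
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction {f} outside [0, 1]")
    return arc.point_at_length(f * arc.length)


def _project_to_polyline(points: np.ndarray, q: np.ndarray, closed: bool):
    """Nearest location on a polyline: returns (arclength, distance, foot point)."""
    a = points
    b = np.roll(points, -1, axis=0) if closed else points[1:]
    if closed:
        a = points
    else:
        a = points[:-1]
    d = b - a
    L2 = np.einsum("ij,ij->i", d, d)
    L2 = np.where(L2 < 1e-18, 1e-18, L2)
    t = np.clip(np.einsum("ij,ij->i", q - a, d) / L2, 0.0, 1.0)
    foot = a + t[:, None] * d
    dist = np.linalg.norm(foot - q, axis=1)
    i = int(np.argmin(dist))
    seglen = np.sqrt(L2)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    return float(cum[i] + t[i] * seglen[i]), float(dist[i]), foot[i]


def plane_section(mesh: TriangleMesh, plane_point, normal):
    """Intersect a mesh with a plane.

    Returns a list of ``(points, closed)`` polyline components.  Intersection
    points are computed per crossing edge and chained through shared edges, so
    the result needs no tolerance-based stitching.
    """
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    d = (mesh.vertices - np.asarray(plane_point, dtype=float)) @ n
    # nudge exact-zero vertices off the plane so every crossing is transversal
    d = np.where(np.abs(d) < 1e-12, 1e-9, d)
    f = mesh.faces
    df = d[f]
    crossing = ~(np.all(df > 0, axis=1) | np.all(df < 0, axis=1))
    idx = np.nonzero(crossing)[0]
    if idx.size == 0:
        return []
    face_edges: dict[int, tuple] = {}
    edge_points: dict[tuple, np.ndarray] = {}
    edge_faces: dict[tuple, list] = {}
    for fi in idx:
        tri = f[fi]
        ekeys = []
        for k in range(3):
            i, j = int(tri[k]), int(tri[(k + 1) % 3])
            if d[i] * d[j] < 0:
                key = (min(i, j), max(i, j))
                if key not in edge_points:
                    t = d[i] / (d[i] - d[j])
                    edge_points[key] = (1 - t) * mesh.vertices[i] + t * mesh.vertices[j]
                ekeys.append(key)
        if len(ekeys) == 2:
            fi = int(fi)
            face_edges[fi] = (ekeys[0], ekeys[1])
            edge_faces.setdefault(ekeys[0], []).append(fi)
            edge_faces.setdefault(ekeys[1], []).append(fi)
    unvisited = set(face_edges)
    components = []
    for start in sorted(face_edges):
        if start not in unvisited:
            continue
        unvisited.discard(start)
        e_first, e_last = face_edges[start]
        chain = [e_first, e_last]
        closed = False
        # walk forward from e_last
        cur_face, cur_edge = start, e_last
        while True:
            nxt = [g for g in edge_faces[cur_edge] if g != cur_face]
            if not nxt:
                break
            g = nxt[0]
            if g == start:
                closed = True
                break
            if g not in unvisited:
                break
            unvisited.discard(g)
            e1, e2 = face_edges[g]
            cur_edge = e2 if e1 == cur_edge else e1
            chain.append(cur_edge)
            cur_face = g
        if not closed:
            # walk backward from e_first and prepend
            cur_face, cur_edge = start, e_first
            while True:
                nxt = [g for g in edge_faces[cur_edge] if g != cur_face]
                if not nxt:
                    break
                g = nxt[0]
                if g not in unvisited:
                    break
                unvisited.discard(g)
                e1, e2 = face_edges[g]
                cur_edge = e2 if e1 == cur_edge else e1
                chain.insert(0, cur_edge)
                cur_face = g
        pts = np.array([edge_points[e] for e in chain])
        components.append((pts, closed))
    return components


def plane_section_arc(mesh: TriangleMesh, a, b, third, snap_tol: float | None = None) -> SurfaceArc:
    """Arc of the mesh/plane(a, b, third) section from ``a`` to ``b``.

    Of the two sub-arcs between the anchors on the section component, the one
    passing nearest ``third`` is returned (this reproduces over-the-top scalp
    curves unambiguously).  Endpoints are the projections of ``a`` and ``b``
    onto the section polyline; the snap distance must stay within tolerance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    third = np.asarray(third, dtype=float)
    if np.linalg.norm(a - b) < 1e-9:
        raise NoArcError("arc endpoints coincide")
    normal = np.cross(b - a, third - a)
    if np.linalg.norm(normal) < 1e-9:
        raise NoArcError("anchors are collinear; the section plane is undefined")
    components = plane_section(mesh, a, normal)
    if not components:
        raise NoArcError("plane does not intersect the mesh")
    if snap_tol is None:
        snap_tol = max(DEFAULT_MESH_TOL, 0.75 * mesh.median_edge_length)
    best = None
    for pts, closed in components:
        sa, da, pa = _project_to_polyline(pts, a, closed)
        sb, db, pb = _project_to_polyline(pts, b, closed)
        score = max(da, db)
        if best is None or score < best[0]:
            best = (score, pts, closed, sa, pa, sb, pb)
    score, pts, closed, sa, pa, sb, pb = best
    if score > snap_tol:
        raise NoArcError(
            f"anchors are {score:.3f} mm from the section (tolerance {snap_tol:.3f} mm); "
            "they may lie on different components"
        )
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if closed:
        seg = np.append(seg, np.linalg.norm(pts[0] - pts[-1]))
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    svals = cum[:-1]

    def forward(s_from, p_from, s_to, p_to):
        span = (s_to - s_from) % total if closed else s_to - s_from
        rel = (svals - s_from) % total if closed else svals - s_from
        mask = (rel > 1e-12) & (rel < span - 1e-12)
        order = np.argsort(rel[mask])
        mid = pts[mask][order]
        return np.vstack([p_from[None], mid, p_to[None]])

    if closed:
        cand1 = forward(sa, pa, sb, pb)
        cand2 = forward(sb, pb, sa, pa)[::-1]  # reversed: runs a -> b the other way
        arcs = []
        for cand in (cand1, cand2):
            try:
                arcs.append(SurfaceArc(cand))
            except NoArcError:
                arcs.append(None)
        dists = [np.inf if arc is None else arc.min_distance(third) for arc in arcs]
        arc = arcs[int(np.argmin(dists))]
        if arc is None:
            raise NoArcError("degenerate section arc")
        return arc
    lo, hi = (sa, sb) if sa <= sb else (sb, sa)
    p_lo, p_hi = (pa, pb) if sa <= sb else (pb, pa)
    cand = forward(lo, p_lo, hi, p_hi)
    if sa > sb:
        cand = cand[::-1]
    return SurfaceArc(cand)


# ---------------------------------------------------------------------------
# landmark sets
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """One subject's named cortical landmarks plus cranial fiducials (AC-PC mm)."""

    subject_id: str
    age_months: float
    points: dict  # (label:int, hemisphere:str) -> (3,) ndarray
    fiducials: dict  # name -> (3,) ndarray
    space: str = "acpc"

    def get(self, label: int, hemisphere: str) -> np.ndarray:
        return self.points[(int(label), hemisphere)]

    def labels(self):
        return sorted(self.points.keys())

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(
            self.subject_id,
            self.age_months,
            {k: v.copy() for k, v in self.points.items()},
            {k: v.copy() for k, v in self.fiducials.items()},
            self.space,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (label, hemi), p in sorted(self.points.items()):
            rows.append((self.subject_id, self.age_months, str(label), hemi, *p, self.space))
        for name in FIDUCIAL_NAMES:
            if name in self.fiducials:
                rows.append((self.subject_id, self.age_months, name, "M", *self.fiducials[name], self.space))
        return pd.DataFrame(
            rows,
            columns=["subject_id", "age_months", "label", "hemisphere", "x_mm", "y_mm", "z_mm", "space"],
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LandmarkSet":
        sid = str(df["subject_id"].iloc[0])
        age = float(df["age_months"].iloc[0])
        space = str(df["space"].iloc[0]) if "space" in df else "acpc"
        points, fiducials = {}, {}
        for _, row in df.iterrows():
            p = np.array([row["x_mm"], row["y_mm"], row["z_mm"]], dtype=float)
            label = str(row["label"])
            if row["hemisphere"] == "M" and not label.isdigit():
                fiducials[label] = p
            else:
                points[(int(label), str(row["hemisphere"]))] = p
        return cls(sid, age, points, fiducials, space)


def write_landmark_table(landmark_sets, path) -> None:
    df = pd.concat([ls.to_frame() for ls in landmark_sets], ignore_index=True)
    for c in ("x_mm", "y_mm", "z_mm"):
        df[c] = df[c].map(lambda v: f"{v:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_landmark_table(path) -> list[LandmarkSet]:
    df = pd.read_csv(path, sep="\t", dtype={"label": str})
    return [
        LandmarkSet.from_frame(g)
        for _, g in df.groupby("subject_id", sort=True)
    ]


# ---------------------------------------------------------------------------
# mesh I/O (ASCII OBJ and PLY)
# ---------------------------------------------------------------------------

def write_obj(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("# triangulated surface, mm units, no baked transform\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_obj(path) -> TriangleMesh:
    verts, faces = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(x) for x in parts[1:4]])
            elif parts[0] == "f":
                ids = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                for k in range(1, len(ids) - 1):  # fan-triangulate polygons
                    faces.append([ids[0], ids[k], ids[k + 1]])
    return TriangleMesh(np.array(verts), np.array(faces))


def write_ply(mesh: TriangleMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ply\nformat ascii 1.0\ncomment mm units\n"
            f"element vertex {len(mesh.vertices)}\n"
            "property float x\nproperty float y\nproperty float z\n"
            f"element face {len(mesh.faces)}\n"
            "property list uchar int vertex_indices\nend_header\n"
        )
        for v in mesh.vertices:
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_ply(path) -> TriangleMesh:
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError("not a PLY file")
        n_vert = n_face = 0
        element = None
        counts = {}
        while True:
            line = fh.readline()
            if not line:
                raise ValueError("unexpected end of PLY header")
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "format" and parts[1] != "ascii":
                raise ValueError("only ASCII PLY is supported")
            if parts[0] == "element":
                element = parts[1]
                counts[element] = int(parts[2])
            if parts[0] == "end_header":
                break
        n_vert = counts.get("vertex", 0)
        n_face = counts.get("face", 0)
        verts = np.array([[float(x) for x in fh.readline().split()[:3]] for _ in range(n_vert)])
        faces = []
        for _ in range(n_face):
            parts = fh.readline().split()
            ids = [int(x) for x in parts[1 : 1 + int(parts[0])]]
            for k in range(1, len(ids) - 1):
                faces.append([ids[0], ids[k], ids[k + 1]])
    return TriangleMesh(verts, np.array(faces))


def load_mesh(path) -> TriangleMesh:
    suffix = Path(path).suffix.lower()
    if suffix == ".obj":
        return read_obj(path)
    if suffix == ".ply":
        return read_ply(path)
    raise ValueError(f"unsupported mesh format {suffix!r}")


def save_mesh(mesh: TriangleMesh, path) -> None:
    suffix = Path(path).suffix.lower()
    if suffix == ".obj":
        write_obj(mesh, path)
    elif suffix == ".ply":
        write_ply(mesh, path)
    else:
        raise ValueError(f"unsupported mesh format {suffix!r}")
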