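"""Geometric primitives: AC-PC frame, plane-section arcs, ray casting, I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import scalpmap as sm
from scalpmap.geometry import _project_to_polyline
from scalpmap.synthetic import superellipsoid_mesh

from helpers import random_rotation


# ---------------------------------------------------------------------------
# AC-PC alignment
# ---------------------------------------------------------------------------

class TestAcpcAlign:
    def test_already_aligned_is_identity(self):
        pts = np.array([[1.0, 2.0, 3.0], [-4.0, 0.0, 7.0]])
        tr, out = sm.acpc_align(pts, ac=[0, 10, 0], pc=[0, -10, 0], mid_sagittal=[0, 0, 50])
        assert np.allclose(out, pts, atol=1e-12)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-12)

    def test_gram_schmidt_oracle(self):
        # explicit frame construction: origin (0,0,0), y = AC direction = +x,
        # z = rejection of mid, so the input AC (10,0,0) must map to (0,10,0)
        tr, out = sm.acpc_align(
            np.array([[10.0, 0.0, 0.0]]), ac=[10, 0, 0], pc=[-10, 0, 0], mid_sagittal=[0, 0, 50]
        )
        origin = np.zeros(3)
        y = np.array([1.0, 0.0, 0.0])
        m = np.array([0.0, 0.0, 50.0]) - origin
        z = m - (m @ y) * y
        z /= np.linalg.norm(z)
        x = np.cross(y, z)
        expected = np.array([10.0, 0.0, 0.0]) @ np.column_stack([x, y, z])
        assert np.allclose(out[0], expected, atol=1e-12)
        assert np.allclose(out[0], [0, 10, 0], atol=1e-12)
        assert np.isclose(np.linalg.det(tr.rotation), 1.0)

    @given(st.integers(0, 10_000))
    def test_rigid_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ac, pc, mid = rng.normal(size=3), rng.normal(size=3), rng.normal(size=3)
        mid = mid + np.array([0, 0, 5.0])  # keep off the AC-PC line
        if np.linalg.norm(ac - pc) < 0.5:
            pc = pc + np.array([3.0, 0, 0])
        pts = rng.normal(size=(5, 3)) * 20
        _, base = sm.acpc_align(pts, ac, pc, mid)
        rot = random_rotation(rng)
        t = rng.normal(size=3) * 50
        _, moved = sm.acpc_align(pts @ rot.T + t, ac @ rot.T + t, pc @ rot.T + t, mid @ rot.T + t)
        assert np.allclose(base, moved, atol=1e-9)

    @pytest.mark.parametrize(
        "ac,pc,mid",
        [
            ([0, 0, 0], [0, 0, 0], [0, 0, 50]),         # AC == PC
            ([0, 10, 0], [0, -10, 0], [0, 5, 0]),       # mid on the AC-PC line
        ],
    )
    def test_degenerate_frames_raise(self, ac, pc, mid):
        with pytest.raises(sm.DegenerateFrameError):
            sm.acpc_align(np.zeros((1, 3)), ac, pc, mid)


# ---------------------------------------------------------------------------
# plane sections
# ---------------------------------------------------------------------------

class TestPlaneSectionArc:
    def test_great_circle_length(self, sphere100):
        arc = sm.plane_section_arc(sphere100, [0, 0, 100.0], [0, 0, -100.0], [100.0, 0, 0])
        assert arc.length == pytest.approx(np.pi * 100.0, rel=0.01)
        # symmetry: midpoint at the equator on the +x side
        apex = arc.point_at_fraction(0.5)
        assert np.linalg.norm(apex - [100.0, 0, 0]) < sphere100.median_edge_length

    def test_coincident_endpoints_raise(self, sphere100):
        with pytest.raises(sm.NoArcError):
            sm.plane_section_arc(sphere100, [0, 0, 100.0], [0, 0, 100.0], [100.0, 0, 0])

    def test_arc_lengths_match_triangle_slicing_oracle(self):
        """Both complementary sub-arcs together must reproduce the exhaustive
        per-triangle section length (independent of any chaining)."""
        # generic tilted plane so no mesh vertex lies exactly on it
        from scalpmap.synthetic import superellipsoid_point

        mesh = superellipsoid_mesh((60.0, 80.0, 55.0), 2.0, 3)
        axes, p = (60.0, 80.0, 55.0), 2.0
        a = superellipsoid_point(np.array([0.11, 0.23, 0.97]), axes, p)
        b = superellipsoid_point(np.array([-0.07, -0.19, -0.98]), axes, p)
        third = superellipsoid_point(np.array([0.95, 0.13, 0.05]), axes, p)
        arc1 = sm.plane_section_arc(mesh, a, b, third)
        # a + b - third lies in the same plane but on the opposite side of
        # the a-b chord, selecting the complementary sub-arc
        arc2 = sm.plane_section_arc(mesh, a, b, a + b - third)
        # oracle: slice every triangle by the plane x-normal through a
        normal = np.cross(b - a, third - a)
        normal = normal / np.linalg.norm(normal)
        d = (mesh.vertices - a) @ normal
        total = 0.0
        for tri in mesh.faces:
            pts = []
            for i in range(3):
                vi, vj = tri[i], tri[(i + 1) % 3]
                if d[vi] * d[vj] < 0:
                    t = d[vi] / (d[vi] - d[vj])
                    pts.append((1 - t) * mesh.vertices[vi] + t * mesh.vertices[vj])
            if len(pts) == 2:
                total += np.linalg.norm(pts[0] - pts[1])
        assert arc1.length + arc2.length == pytest.approx(total, rel=1e-6)

    def test_resolution_convergence(self):
        """Observed great-circle length error shrinks when edges shrink."""
        errs = []
        for sub in (3, 4):
            sph = sm.icosphere(100.0, sub)
            arc = sm.plane_section_arc(sph, [0, 0, 100.0], [0, 0, -100.0], [100.0, 0, 0])
            errs.append(abs(arc.length - np.pi * 100.0))
        assert errs[1] < 0.5 * errs[0]

    def test_sub_arc_selection_by_third_point(self, sphere100):
        a, b = np.array([0, 0, 100.0]), np.array([0, 100.0, 0])
        near = sm.plane_section_arc(sphere100, a, b, np.array([0, 70.0, 70.0]))
        far = sm.plane_section_arc(sphere100, a, b, np.array([0, -70.0, -70.0]))
        assert near.length == pytest.approx(np.pi * 50.0, rel=0.02)       # quarter circle
        assert far.length == pytest.approx(3 * np.pi * 50.0, rel=0.02)    # the long way round


class TestPointAtFraction:
    def test_endpoints_and_apex(self, sphere100):
        arc = sm.plane_section_arc(sphere100, [0, 0, 100.0], [0, 0, -100.0], [100.0, 0, 0])
        start, end = arc.endpoints
        assert np.allclose(sm.point_at_fraction(arc, 0.0), start)
        assert np.allclose(sm.point_at_fraction(arc, 1.0), end)

    def test_cumulative_length_oracle(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(size=(40, 3)), axis=0)
        arc = sm.SurfaceArc(pts)
        f = 0.37
        p = sm.point_at_fraction(arc, f)
        # oracle: walk segments accumulating length until f * total
        seg = np.linalg.norm(np.diff(arc.points, axis=0), axis=1)
        target = f * seg.sum()
        acc = 0.0
        for i, L in enumerate(seg):
            if acc + L >= target:
                t = (target - acc) / L
                expected = (1 - t) * arc.points[i] + t * arc.points[i + 1]
                break
            acc += L
        assert np.allclose(p, expected, atol=1e-9)
        # prefix length property
        s = arc.locate(p)
        assert s == pytest.approx(f * arc.length, abs=1e-9)

    @pytest.mark.parametrize("f", [-0.1, 1.1])
    def test_fraction_bounds(self, f):
        arc = sm.SurfaceArc(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(ValueError):
            sm.point_at_fraction(arc, f)

    def test_strictly_increasing_cumlen(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        arc = sm.SurfaceArc(pts)  # duplicate vertex dropped
        assert np.all(np.diff(arc.cumulative_length) > 0)
        assert arc.cumulative_length[0] == 0.0


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

class TestRaySurfaceIntersection:
    def test_sphere_radius(self, sphere100):
        p = sm.ray_surface_intersection(sphere100, [0, 0, 0], [1.0, 2.0, 3.0])
        assert np.linalg.norm(p) == pytest.approx(100.0, abs=0.2)

    def test_miss_raises(self, sphere100):
        with pytest.raises(sm.RayMissError):
            sm.ray_surface_intersection(sphere100, [200.0, 0, 0], [1.0, 0, 0])

    def test_matches_exhaustive_triangle_oracle(self):
        mesh = superellipsoid_mesh((60.0, 80.0, 55.0), 2.5, 2)
        rng = np.random.default_rng(11)
        for _ in range(20):
            origin = rng.uniform(-20, 20, 3)
            direction = rng.normal(size=3)
            p = sm.ray_surface_intersection(mesh, origin, direction)
            # oracle: scalar Moller-Trumbore over every triangle
            d = direction / np.linalg.norm(direction)
            best_t = -np.inf
            for tri in mesh.faces:
                v0, v1, v2 = mesh.vertices[tri]
                e1, e2 = v1 - v0, v2 - v0
                h = np.cross(d, e2)
                a = e1 @ h
                if abs(a) < 1e-12:
                    continue
                f = 1.0 / a
                s = origin - v0
                u = f * (s @ h)
                q = np.cross(s, e1)
                v = f * (d @ q)
                t = f * (e2 @ q)
                if u >= -1e-9 and v >= -1e-9 and u + v <= 1 + 1e-9 and t > 1e-7:
                    best_t = max(best_t, t)
            expected = np.asarray(origin) + best_t * d
            assert np.allclose(p, expected, atol=1e-9)

    def test_zero_direction_rejected(self, sphere100):
        with pytest.raises(ValueError):
            sm.ray_surface_intersection(sphere100, [0, 0, 0], [0, 0, 0])


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "plane,point,expected",
    [
        ("sagittal", (3, 4, 5), (0, 4, 5)),
        ("coronal", (3, 4, 5), (3, 0, 5)),
    ],
)
def test_project(plane, point, expected):
    assert np.allclose(sm.project(point, plane), expected)


def test_projected_distance_collapses_x():
    a, b = np.array([3.0, 4, 5]), np.array([-2.0, 4, 5])
    assert np.linalg.norm(sm.project(a, "sagittal") - sm.project(b, "sagittal")) == 0.0


def test_project_unknown_plane():
    with pytest.raises(ValueError):
        sm.project((1, 2, 3), "axial")


# ---------------------------------------------------------------------------
# meshes and I/O
# ---------------------------------------------------------------------------

class TestMeshIO:
    @pytest.mark.parametrize("fmt", ["obj", "ply"])
    def test_roundtrip(self, tmp_path, fmt):
        mesh = sm.icosphere(42.0, 1)
        path = tmp_path / f"m.{fmt}"
        sm.save_mesh(mesh, path)
        back = sm.load_mesh(path)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-5)
        assert np.array_equal(back.faces, mesh.faces)
        assert back.is_watertight

    def test_landmark_table_roundtrip(self, tmp_path, default_model):
        subj = sm.make_subject(default_model, 10.0, 3, with_meshes=False)
        path = tmp_path / "landmarks.tsv"
        sm.write_landmark_table([subj.landmarks], path)
        (back,) = sm.read_landmark_table(path)
        assert back.subject_id == subj.landmarks.subject_id
        assert back.age_months == pytest.approx(subj.age_months)
        for key, p in subj.landmarks.points.items():
            assert np.allclose(back.points[key], p, atol=1e-6)
        for name, p in subj.landmarks.fiducials.items():
            assert np.allclose(back.fiducials[name], p, atol=1e-6)

    def test_invalid_faces_rejected(self):
        with pytest.raises(ValueError):
            sm.TriangleMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))

    def test_degenerate_faces_dropped(self):
        verts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 1, 1], [0, 2, 3]])  # middle face has zero area
        mesh = sm.TriangleMesh(verts, faces)
        assert len(mesh.faces) == 2

    def test_watertight_flag(self, sphere100):
        assert sphere100.is_watertight
        open_mesh = sm.TriangleMesh(sphere100.vertices, sphere100.faces[:-3])
        assert not open_mesh.is_watertight
        assert open_mesh.boundary_edge_count() > 0


def test_project_to_polyline_closed_wraps():
    square = np.array([[0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0], [0.0, 1, 0]])
    s, dist, foot = _project_to_polyline(square, np.array([-0.2, 0.5, 0.0]), closed=True)
    assert dist == pytest.approx(0.2)
    assert foot == pytest.approx([0.0, 0.5, 0.0])
    assert s == pytest.approx(3.5)
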