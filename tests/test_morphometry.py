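"""Geometric measurement operations: distances, axis, angles, facet areas."""

import math

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import calcmorph as cm
from calcmorph.errors import BoundaryError, DataError, GeometryError
from conftest import random_vectors


def rigid(seed):
    rng = np.random.default_rng(seed)
    return Rotation.random(random_state=rng).as_matrix(), rng.normal(0, 50, 3)


class TestDistance:
    def test_zero_and_pythagoras(self):
        assert cm.distance((1, 2, 3), (1, 2, 3)) == 0.0
        assert cm.distance((0, 0, 0), (3, 4, 0)) == 5.0

    def test_componentwise_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p, q = rng.normal(0, 30, (2, 3))
            oracle = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))
            assert cm.distance(p, q) == pytest.approx(oracle, abs=1e-12)
            assert cm.distance(q, p) == cm.distance(p, q)


class TestAxisAndHeight:
    def test_point_on_axis_gives_zero_height(self):
        # A on the line through G=(0.5(C+D)) and E
        C, D, E = np.array([2.0, 0, 0]), np.array([4.0, 0, 0]), np.array([9.0, 0, 0])
        A = np.array([5.0, 0, 0])
        G, H, lca, hpf = cm.axis_and_height(A, C, D, E)
        assert np.allclose(G, [3, 0, 0])
        assert hpf == 0.0
        assert np.allclose(H, A)
        assert lca == 6.0

    def test_unit_perpendicular(self):
        G, H, lca, hpf = cm.axis_and_height(
            A=(0, 1, 0), C=(0, 0, 0), D=(0, 0, 0.0), E=(1, 0, 0))
        # C=D makes G the origin
        assert np.allclose(H, [0, 0, 0])
        assert hpf == pytest.approx(1.0, abs=1e-15)

    def test_cross_product_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            A, C, D, E = rng.normal(0, 20, (4, 3))
            G = 0.5 * (C + D)
            if np.linalg.norm(E - G) < 1e-6:
                continue
            u = (E - G) / np.linalg.norm(E - G)
            oracle = np.linalg.norm(np.cross(A - G, u))
            _, H, _, hpf = cm.axis_and_height(A, C, D, E)
            assert hpf == pytest.approx(oracle, abs=1e-12)
            assert abs(np.dot(A - H, E - G)) < 1e-9 * np.linalg.norm(E - G)

    def test_degenerate_axis_rejected(self):
        with pytest.raises(GeometryError, match="axis"):
            cm.axis_and_height((0, 1, 0), (1, 0, 0), (3, 0, 0), (2, 0, 0))


class TestAngles:
    def test_gissane_right_angle_and_collinear(self):
        assert cm.gissane_angle((0, 1, 0), (0, 0, 0), (1, 0, 0)) == pytest.approx(90.0)
        assert cm.gissane_angle((-1, 0, 0), (0, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_gissane_coincident_rejected(self):
        with pytest.raises(GeometryError):
            cm.gissane_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    def test_bohler_complement(self):
        # construct ∠CAF = 140° in the plane -> BA = 40°
        A = np.zeros(3)
        C = np.array([1.0, 0, 0])
        ang = math.radians(140)
        F = np.array([math.cos(ang), math.sin(ang), 0.0])
        assert cm.bohler_angle(A, C, F) == pytest.approx(40.0, abs=1e-12)

    def test_bohler_collinear_gives_zero(self):
        assert cm.bohler_angle((0, 0, 0), (1, 0, 0), (-2, 0, 0)) == pytest.approx(0.0)

    @pytest.mark.parametrize("param,value", [("GA", 125.4), ("BA", 39.6)])
    def test_realized_angle_round_trip(self, param, value, male_means):
        v = cm.ParameterVector(**{**male_means.as_dict(), param: value})
        rec = cm.measure_all(cm.realize_landmarks(v))
        assert getattr(rec, param) == pytest.approx(value, abs=1e-9)


class TestMeasureAll:
    def test_round_trip_random_vectors(self):
        for v in random_vectors(100, seed=5):
            rec = cm.measure_all(cm.realize_landmarks(v))
            for p in cm.LANDMARK_PARAMETERS:
                assert getattr(rec, p) == pytest.approx(
                    getattr(v, p), rel=1e-9, abs=1e-9), p

    def test_rigid_invariance(self, mean_landmarks):
        base = cm.measure_all(mean_landmarks)
        for s in range(100):
            R, t = rigid(s)
            rec = cm.measure_all(mean_landmarks.transformed(R, t))
            for p in cm.LANDMARK_PARAMETERS:
                assert getattr(rec, p) == pytest.approx(
                    getattr(base, p), abs=1e-9), p

    def test_similarity_scaling(self, mean_landmarks):
        base = cm.measure_all(mean_landmarks)
        rec = cm.measure_all(mean_landmarks.transformed(scale=2.0))
        for p in cm.LENGTH_PARAMETERS:
            assert getattr(rec, p) == pytest.approx(2 * getattr(base, p), rel=1e-12)
        for p in cm.ANGLE_PARAMETERS:
            assert getattr(rec, p) == pytest.approx(getattr(base, p), abs=1e-9)

    def test_law_of_cosines_identity(self):
        for v in random_vectors(20, seed=9):
            lms = cm.realize_landmarks(v)
            rec = cm.measure_all(lms)
            ac2 = cm.distance(lms.A, lms.C) ** 2
            expected = (rec.LPF ** 2 + rec.LAP ** 2 -
                        2 * rec.LPF * rec.LAP * math.cos(math.radians(rec.GA)))
            assert ac2 == pytest.approx(expected, rel=1e-9)

    def test_areas_absent_without_mesh(self, mean_landmarks):
        rec = cm.measure_all(mean_landmarks)
        assert rec.APF is None and rec.AMF is None

    @given(ga=st.floats(100, 150), ba=st.floats(25, 45))
    def test_angle_round_trip_property(self, male_means, ga, ba):
        v = cm.ParameterVector(**{**male_means.as_dict(), "GA": ga, "BA": ba})
        rec = cm.measure_all(cm.realize_landmarks(v))
        assert rec.GA == pytest.approx(ga, abs=1e-9)
        assert rec.BA == pytest.approx(ba, abs=1e-9)


def square_mesh(n=10, side=10.0):
    """Planar grid of 2n² triangles covering a side × side mm square."""
    ax = np.linspace(0, side, n + 1)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    verts = np.c_[xx.ravel(), yy.ravel(), np.zeros((n + 1) ** 2)]
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b, c, d = a + 1, a + n + 1, a + n + 2
            faces += [[a, b, d], [a, d, c]]
    return trimesh.Trimesh(verts, np.array(faces), process=False)


class TestFacetArea:
    def test_planar_square_full_rim(self):
        mesh = square_mesh()
        side = 10.0
        rim = np.array([[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]],
                       dtype=float)
        b = cm.FacetBoundary(points=rim, seed=(side / 2, side / 2, 0.0),
                             label="posterior")
        assert cm.facet_area(mesh, b) == pytest.approx(1.0, rel=1e-9)  # 1 cm²

    def test_planar_subregion_matches_enumeration_oracle(self):
        mesh = square_mesh(n=8, side=8.0)
        # boundary along the x = 4 grid line plus three outer edges
        loop = np.array([[0, 0, 0], [4, 0, 0], [4, 8, 0], [0, 8, 0]], dtype=float)
        b = cm.FacetBoundary(points=loop, seed=(1.0, 4.0, 0.0), label="middle")
        got = cm.facet_area(mesh, b)
        centroids = mesh.triangles_center
        oracle = mesh.area_faces[centroids[:, 0] < 4.0].sum() / 100.0
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_cap_area_against_closed_form(self, sphere_phantom, sphere_mesh):
        # spherical cap R=10, h=2: analytic area 2πRh = 125.66 mm²
        a_cm2 = cm.facet_area(sphere_mesh, sphere_phantom.facet_boundary)
        true = sphere_phantom.facet_area_mm2 / 100.0
        assert a_cm2 == pytest.approx(true, rel=0.03)

    def test_region_plus_complement_partition(self, sphere_phantom, sphere_mesh):
        b = sphere_phantom.facet_boundary
        cap = cm.facet_area(sphere_mesh, b)
        flipped = cm.FacetBoundary(points=b.points,
                                   seed=-b.seed,  # antipode
                                   label="middle")
        rest = cm.facet_area(sphere_mesh, flipped)
        assert cap + rest == pytest.approx(sphere_mesh.area / 100.0, rel=1e-9)

    def test_far_boundary_point_rejected(self, sphere_mesh):
        loop = np.array([[50, 0, 0], [0, 50, 0], [-50, 0, 0]], dtype=float)
        b = cm.FacetBoundary(points=loop, seed=(0, 0, 60.0), label="posterior")
        with pytest.raises(BoundaryError, match="tolerance"):
            cm.facet_area(sphere_mesh, b)

    def test_measure_all_with_facets(self, sphere_phantom, sphere_mesh,
                                     mean_landmarks):
        rec = cm.measure_all(mean_landmarks, mesh=sphere_mesh,
                             boundaries=[sphere_phantom.facet_boundary])
        assert rec.APF == pytest.approx(sphere_phantom.facet_area_mm2 / 100.0,
                                        rel=0.03)
        assert rec.AMF is None


class TestLandmarkIO:
    def test_round_trip(self, mean_landmarks, tmp_path):
        path = tmp_path / "lms.csv"
        cm.write_landmarks(mean_landmarks, path)
        back = cm.read_landmarks(path)
        for name, p in mean_landmarks.as_dict().items():
            assert np.allclose(getattr(back, name), p)

    def test_missing_landmark_flagged(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("name,x_mm,y_mm,z_mm\nA,0,0,0\nB,1,0,0\n")
        with pytest.raises(cm.MissingLandmarkError, match="missing"):
            cm.read_landmarks(path)

    def test_boundary_round_trip(self, sphere_phantom, tmp_path):
        path = tmp_path / "b.csv"
        cm.write_boundaries([sphere_phantom.facet_boundary], path)
        back = cm.read_boundaries(path)
        assert len(back) == 1
        assert np.allclose(back[0].points, sphere_phantom.facet_boundary.points)
        assert back[0].label == "posterior"

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(GeometryError, match="coincide"):
            cm.LandmarkSet(A=(0, 0, 0), B=(0, 0, 0), C=(1, 0, 0),
                           D=(2, 0, 0), E=(3, 0, 0), F=(4, 0, 0))

    def test_short_boundary_rejected(self):
        with pytest.raises(DataError, match="3 distinct"):
            cm.FacetBoundary(points=[[0, 0, 0], [1, 0, 0]], seed=(5, 5, 0),
                             label="posterior")
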