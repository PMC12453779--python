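"""Curvature pipeline: PDB reading, Delaunay tetrahedra, circumradius
formulas and the mean-curvature estimate against plain-scalar oracles."""

import math

import numpy as np
import pytest

from dtafusion.exceptions import (
    DegenerateGeometryError,
    InsufficientGeometryError,
    NoValidTetrahedraError,
    PDBParseError,
)
from dtafusion.geometry import (
    AtomCloud,
    circum_radius,
    delaunay_tetrahedra,
    mean_curvature,
    read_structure,
    tetra_quantity_V,
    write_point_cloud_pdb,
)

RIGHT_CORNER = (2.0, 3.0, 5.0, math.sqrt(13), math.sqrt(29), math.sqrt(34))


def scalar_curvature_oracle(points: np.ndarray, sign: str = "abs"):
    """Independent loop-based re-implementation: tessellate, then apply the
    edge-length / V / R / k formulas one tetrahedron at a time in plain
    scalar arithmetic."""
    from scipy.spatial import Delaunay

    tri = Delaunay(points)
    ks = []
    n_zero = 0
    for simplex in tri.simplices:
        p1, p2, p3, p4 = (points[i] for i in sorted(simplex))
        a = math.dist(p1, p2)
        b = math.dist(p1, p3)
        c = math.dist(p1, p4)
        d = math.dist(p2, p3)
        e = math.dist(p2, p4)
        f = math.dist(p3, p4)
        V = a * d * f + b * e * f + c * d * e - a * e**2 - b * d**2 - c * f**2
        mean_edge = (a + b + c + d + e + f) / 6.0
        if abs(V) <= 1e-12 * mean_edge**3:
            n_zero += 1
            continue
        num = (a**2 * (e**2 + f**2 - d**2) + b**2 * (d**2 + f**2 - e**2)
               + c**2 * (d**2 + e**2 - f**2))
        R = num / (16.0 * V)
        ks.append(1.0 / abs(R) if sign == "abs" else 1.0 / R)
    return (sum(ks) / len(ks) if ks else None), len(ks), n_zero, len(tri.simplices)


class TestReadStructure:
    def test_reads_atom_coordinates_in_file_order(self, tiny_pdb):
        cloud = read_structure(tiny_pdb)
        assert len(cloud) == 4
        np.testing.assert_allclose(
            cloud.coords,
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], atol=1e-6)

    def test_hetatm_records_are_dropped(self, tiny_pdb):
        cloud = read_structure(tiny_pdb)
        assert not np.any(np.all(cloud.coords == [9, 9, 9], axis=1))

    def test_c_alpha_level_keeps_only_ca(self, tiny_pdb):
        with pytest.raises(InsufficientGeometryError):
            read_structure(tiny_pdb, level="c_alpha")  # only 2 CAs present

    def test_empty_stream_raises_parse_error(self):
        with pytest.raises(PDBParseError):
            read_structure("")

    def test_too_few_atoms_raises(self):
        three = "\n".join(TINY := [
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      2  CA  GLY A   2       1.000   0.000   0.000  1.00  0.00           C",
            "ATOM      3  CA  GLY A   3       0.000   1.000   0.000  1.00  0.00           C",
            "END"]) + "\n"
        with pytest.raises(InsufficientGeometryError):
            read_structure(three)

    def test_point_cloud_pdb_round_trip(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        text = write_point_cloud_pdb(pts)
        cloud = read_structure(text)
        np.testing.assert_allclose(cloud.coords, np.round(pts, 3), atol=5e-4)


class TestDelaunay:
    def test_four_points_give_one_tetrahedron(self):
        cloud = AtomCloud(np.eye(4, 3) * 2.0 + [[0, 0, 0]] * 4)
        cloud = AtomCloud(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.]]))
        tets = delaunay_tetrahedra(cloud)
        assert len(tets) == 1
        assert sorted(tets[0].vertex_indices) == [0, 1, 2, 3]

    def test_coplanar_points_raise(self):
        pts = np.zeros((5, 3))
        pts[:, :2] = np.random.default_rng(0).normal(size=(5, 2))
        with pytest.raises(DegenerateGeometryError):
            delaunay_tetrahedra(AtomCloud(pts))

    def test_empty_circumsphere_property(self, rng):
        """Every returned tetrahedron's true circumsphere (explicit
        circumcenter solve) contains no other point in its interior."""
        pts = rng.uniform(size=(20, 3))
        tets = delaunay_tetrahedra(AtomCloud(pts))
        for tet in tets:
            p = pts[list(tet.vertex_indices)]
            # circumcenter x solves 2(p_i - p_0) . x = |p_i|^2 - |p_0|^2
            A = 2.0 * (p[1:] - p[0])
            b = (p[1:] ** 2).sum(1) - (p[0] ** 2).sum()
            center = np.linalg.solve(A, b)
            radius = np.linalg.norm(p[0] - center)
            dists = np.linalg.norm(pts - center, axis=1)
            inside = dists < radius - 1e-9
            inside[list(tet.vertex_indices)] = False
            assert not inside.any()


class TestEdgeFormulas:
    def test_regular_tetrahedron_V_is_zero(self):
        assert tetra_quantity_V(1, 1, 1, 1, 1, 1) == 0.0

    def test_right_corner_value(self):
        # legs 2, 3, 5 at one vertex; direct arithmetic of the definition
        a, b, c, d, e, f = RIGHT_CORNER
        expected = (a * d * f + b * e * f + c * d * e
                    - a * e**2 - b * d**2 - c * f**2)
        assert tetra_quantity_V(*RIGHT_CORNER) == pytest.approx(expected)
        assert expected == pytest.approx(-33.668, abs=5e-4)

    def test_zero_lengths_give_zero(self):
        assert tetra_quantity_V(0, 0, 0, 0, 0, 0) == 0.0

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            tetra_quantity_V(-1, 1, 1, 1, 1, 1)

    def test_invalid_marker_for_zero_V(self):
        assert math.isnan(circum_radius(1, 1, 1, 1, 1, 1, 0.0))

    def test_right_corner_radius(self):
        V = tetra_quantity_V(*RIGHT_CORNER)
        R = circum_radius(*RIGHT_CORNER, V)
        a, b, c, d, e, f = RIGHT_CORNER
        num = (a**2 * (e**2 + f**2 - d**2) + b**2 * (d**2 + f**2 - e**2)
               + c**2 * (d**2 + e**2 - f**2))
        assert num == pytest.approx(562.0)
        assert R == pytest.approx(562.0 / (16.0 * V))
        assert R == pytest.approx(-1.043, abs=5e-4)

    def test_homogeneity_doubling_lengths_doubles_R(self):
        V1 = tetra_quantity_V(*RIGHT_CORNER)
        R1 = circum_radius(*RIGHT_CORNER, V1)
        doubled = tuple(2 * x for x in RIGHT_CORNER)
        V2 = tetra_quantity_V(*doubled)
        R2 = circum_radius(*doubled, V2)
        assert R2 == pytest.approx(2 * R1, rel=1e-12)


class TestMeanCurvature:
    def test_matches_scalar_oracle(self, rng):
        pts = rng.normal(size=(30, 3)) * 4.0
        result = mean_curvature(AtomCloud(pts))
        k_oracle, n_valid, n_zero, n_total = scalar_curvature_oracle(pts)
        assert result.n_total == n_total
        assert result.n_valid == n_valid
        assert result.mean_curvature == pytest.approx(k_oracle, rel=1e-9)

    def test_skip_rule_conservation(self, rng):
        pts = rng.normal(size=(25, 3))
        result = mean_curvature(AtomCloud(pts), return_per_tet=True)
        _, n_valid, n_zero, n_total = scalar_curvature_oracle(pts)
        assert result.n_valid + n_zero == result.n_total
        assert len(result.per_tet) == n_total

    def test_regular_tetrahedron_cloud_has_no_valid_tetrahedra(self):
        # vertices of a regular tetrahedron: all edge lengths equal -> V = 0
        pts = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                       dtype=float)
        with pytest.raises(NoValidTetrahedraError):
            mean_curvature(AtomCloud(pts))

    def test_scaling_law(self, rng):
        pts = rng.normal(size=(30, 3)) * 3.0
        k1 = mean_curvature(AtomCloud(pts)).mean_curvature
        k2 = mean_curvature(AtomCloud(pts * 2.0)).mean_curvature
        assert k2 == pytest.approx(k1 / 2.0, rel=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(30, 3)) * 3.0
        # random rotation via QR, plus a translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] *= -1
        moved = pts @ Q.T + np.array([5.0, -3.0, 11.0])
        k1 = mean_curvature(AtomCloud(pts)).mean_curvature
        k2 = mean_curvature(AtomCloud(moved)).mean_curvature
        assert k2 == pytest.approx(k1, rel=1e-9)

    def test_raw_sign_mode_differs_when_radii_negative(self, rng):
        pts = rng.normal(size=(20, 3)) * 3.0
        res_abs = mean_curvature(AtomCloud(pts), sign="abs")
        res_raw = mean_curvature(AtomCloud(pts), sign="raw", return_per_tet=True)
        if any(np.isfinite(R) and R < 0 for _, R, _ in res_raw.per_tet):
            assert res_raw.mean_curvature != pytest.approx(
                res_abs.mean_curvature)
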