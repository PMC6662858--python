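import numpy as np
import pytest

from gsmono.errors import (ConfigurationError, DomainOverflowError)
from gsmono.grid import build_grid
from gsmono.mesh import (Circle, ImplicitRegion, LagrangianMesh, MotionModel,
                         Polygon, Rectangle, advance_motion, check_refinement,
                         element_quadrature, triangulate)


class TestElementQuadrature:
    def test_three_point_rule_on_unit_right_triangle(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        pts, w = element_quadrature(tri, rule_order=2)
        assert np.allclose(w, 1.0 / 6.0)
        assert w.sum() == pytest.approx(0.5)
        # points strictly inside the closed triangle
        assert np.all(pts >= -1e-14)
        assert np.all(pts.sum(axis=1) <= 1 + 1e-14)
        # degree-1 exactness: integral of x over the simplex is 1/6
        assert np.dot(w, pts[:, 0]) == pytest.approx(1.0 / 6.0)

    @pytest.mark.parametrize("order", [1, 2, 4])
    def test_constant_exactness_any_triangle(self, order):
        tri = np.array([[0.2, -0.1], [1.7, 0.4], [0.6, 2.0]])
        area = 0.5 * abs((1.7 - 0.2) * (2.0 + 0.1) - (0.6 - 0.2) * (0.4 + 0.1))
        _, w = element_quadrature(tri, rule_order=order)
        assert np.dot(w, np.full(len(w), 3.3)).item() == pytest.approx(3.3 * area)

    def test_degree_two_exactness(self):
        """The default rule integrates quadratics exactly (x*y over the unit
        right triangle = 1/24)."""
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        pts, w = element_quadrature(tri, rule_order=2)
        assert np.dot(w, pts[:, 0] * pts[:, 1]) == pytest.approx(1.0 / 24.0)

    def test_rejects_bad_input(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ConfigurationError):
            element_quadrature(tri, rule_order=3)
        degenerate = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ConfigurationError):
            element_quadrature(degenerate, rule_order=2)


class TestTriangulate:
    def test_unit_square_area(self):
        m = triangulate(Rectangle((0, 0), (1, 1)), 0.5)
        assert m.material_area() == pytest.approx(1.0, rel=1e-10)

    def test_benchmark_rectangle_area(self):
        m = triangulate(Rectangle((0, 0), (2.5, 2.5)), 0.1)
        assert m.material_area() == pytest.approx(6.25, rel=1e-10)
        assert m.max_edge_length() <= 0.1 * (1 + 1e-9)

    def test_circle_area_converges(self):
        m = triangulate(Circle((1.25, 1.25), 1.25), 0.02)
        assert m.material_area() == pytest.approx(np.pi * 1.25 ** 2, rel=1e-2)

    def test_polygon_region(self):
        # L-shaped polygon, area 3
        verts = ((0, 0), (2, 0), (2, 1), (1, 1), (1, 2), (0, 2))
        m = triangulate(Polygon(verts), 0.15)
        assert m.material_area() == pytest.approx(3.0, rel=2e-2)

    def test_implicit_region(self):
        ring = ImplicitRegion(
            lambda p: (np.hypot(p[:, 0], p[:, 1]) > 0.5)
            & (np.hypot(p[:, 0], p[:, 1]) < 1.0),
            (-1.0, -1.0), (1.0, 1.0))
        m = triangulate(ring, 0.08)
        # indicator-only boundary: ragged at the edge-length scale, so the
        # mesh under-covers the ring by O(edge) on each rim
        assert m.material_area() == pytest.approx(np.pi * 0.75, rel=0.25)
        assert m.material_area() < np.pi * 0.75

    def test_degenerate_region_rejected(self):
        with pytest.raises(ConfigurationError):
            triangulate(Rectangle((0, 0), (0, 1)), 0.1)
        with pytest.raises(ConfigurationError):
            triangulate(Rectangle((0, 0), (1, 1)), -0.1)

    def test_positive_areas_and_quadrature_consistency(self):
        m = triangulate(Circle((0, 0), 1.0), 0.1)
        assert np.all(m.material_element_areas() > 0)
        assert np.all(m.current_element_areas() > 0)
        assert m.quad_weights.sum() == pytest.approx(
            m.material_element_areas().sum(), rel=1e-12)

    def test_linear_basis_reproduction(self):
        """P1 interpolation of a linear function to quadrature points is
        exact."""
        m = triangulate(Rectangle((0, 0), (1, 2)), 0.3)
        f = 3.0 * m.nodes[:, 0] - 0.7 * m.nodes[:, 1] + 0.25
        fq = m.interpolate_nodal(f)
        expected = 3.0 * m.quad_material[:, 0] - 0.7 * m.quad_material[:, 1] + 0.25
        assert np.allclose(fq, expected, atol=1e-12)


class TestRefinementConstraint:
    def test_host_grid_enforces_leak_limit(self):
        g = build_grid(((0, 1), (0, 1)), 10, 10)  # dx = 0.1
        m = triangulate(Rectangle((0.2, 0.2), (0.8, 0.8)), 0.5, host_grid=g)
        assert m.max_edge_length() <= 0.5 * g.dx1 * (1 + 1e-9)

    def test_too_coarse_fails_loudly(self):
        g = build_grid(((0, 1), (0, 1)), 10, 10)
        m = triangulate(Rectangle((0.2, 0.2), (0.8, 0.8)), 0.3)
        with pytest.raises(ConfigurationError, match="too coarse"):
            check_refinement(m, g)


class TestMotion:
    def setup_method(self):
        self.motion = MotionModel(centroid=(1.25, 1.25), rate=0.4)

    def test_printed_velocity_law(self):
        # k(X) = 0.5 ||X - Xc|| / 1.25, n radial
        X = np.array([2.5, 1.25])
        assert self.motion.k(X) == pytest.approx(0.5 * 1.25 / 1.25)
        assert np.allclose(self.motion.n(X), [1.0, 0.0])

    def test_centroid_is_stationary(self):
        assert self.motion.k(np.array([1.25, 1.25])) == 0.0
        assert np.allclose(self.motion.n(np.array([1.25, 1.25])), 0.0)

    def test_node_updates(self):
        nodes = np.array([[2.5, 1.25], [1.25, 2.5], [1.25, 1.25]])
        m = LagrangianMesh(nodes, np.array([[0, 1, 2]]))
        advance_motion(m, self.motion, 0.1)
        assert np.allclose(m.current_positions[0], [2.55, 1.25])
        assert np.allclose(m.current_positions[1], [1.25, 2.55])
        assert np.allclose(m.current_positions[2], [1.25, 1.25])
        # material coordinates untouched
        assert np.allclose(m.nodes, nodes)

    def test_linear_growth_in_time(self):
        """Velocity is constant per material point, so distance from the
        centroid image grows linearly at rate k(X)."""
        nodes = np.array([[2.0, 1.25], [1.25, 2.0], [0.5, 1.25]])
        m = LagrangianMesh(nodes, np.array([[0, 1, 2]]))
        k0 = self.motion.k(nodes)
        r0 = np.linalg.norm(nodes - [1.25, 1.25], axis=1)
        for step in range(1, 6):
            advance_motion(m, self.motion, 0.1)
            r = np.linalg.norm(m.current_positions - [1.25, 1.25], axis=1)
            assert np.allclose(r, r0 + 0.1 * step * k0, atol=1e-12)

    def test_overflow_halts(self):
        nodes = np.array([[2.5, 1.25], [1.25, 2.5], [1.4, 1.4]])
        m = LagrangianMesh(nodes, np.array([[0, 1, 2]]))
        with pytest.raises(DomainOverflowError):
            for _ in range(100):
                advance_motion(m, self.motion, 0.1,
                               box_lo=(0.0, 0.0), box_hi=(2.6, 2.6))

    def test_window(self):
        mo = MotionModel(centroid=(0, 0), rate=0.4, t_start=0.0, t_stop=1.25)
        assert mo.is_active(0.0)
        assert mo.is_active(1.0)
        assert not mo.is_active(1.25)
        assert not MotionModel(centroid=(0, 0), active=False).is_active(0.0)
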