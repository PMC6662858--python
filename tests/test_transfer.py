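import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsmono.errors import DomainOverflowError
from gsmono.grid import EulerianField, build_grid
from gsmono.mesh import LagrangianMesh, Rectangle, triangulate
from gsmono.transfer import (TransferMaps, interpolate, project_to_nodes, psi,
                             spread)


class TestKernel:
    @pytest.mark.parametrize("r,expected", [
        (0.0, 1.0),          # 0.5*1*(-1)*(-2)
        (0.5, 0.5625),
        (1.5, -0.0625),
        (2.5, 0.0),
        (-2.0, 0.0),
        (1.0, 0.0),
        (2.0, 0.0),
    ])
    def test_pointwise_values(self, r, expected):
        assert psi(r) == pytest.approx(expected, abs=1e-15)

    def test_four_point_stencil_sums_to_one_at_half_offset(self):
        s = psi(-1.5) + psi(-0.5) + psi(0.5) + psi(1.5)
        assert s == pytest.approx(1.0, abs=1e-15)

    def test_partition_of_unity_dense(self):
        r = np.linspace(0.0, 1.0, 10001)[:-1]
        total = sum(psi(r - j) for j in range(-3, 4))
        assert np.abs(total - 1.0).max() < 1e-12

    @given(st.floats(-0.5, 0.5, allow_nan=False))
    @settings(deadline=None, max_examples=50)
    def test_partition_of_unity_property(self, r):
        total = sum(psi(r - j) for j in range(-3, 4))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_even_symmetry(self):
        r = np.linspace(-2.2, 2.2, 401)
        assert np.allclose(psi(r), psi(-r), atol=1e-15)


@pytest.fixture(scope="module")
def setup():
    grid = build_grid(((-0.1, 1.1), (-0.1, 1.1)), 48, 48)
    mesh = triangulate(Rectangle((0.0, 0.0), (1.0, 1.0)), 0.5 * grid.dx1)
    return grid, mesh, TransferMaps(grid, mesh)


class TestSpread:
    def test_zero_values_zero_field(self, setup):
        grid, mesh, tm = setup
        assert not np.any(tm.spread(np.zeros(mesh.n_quad)))

    def test_conserves_integral(self, setup):
        """Partition of unity makes spreading conservative:
        sum(field) * dx1 dx2 == sum over quad of value * weight."""
        grid, mesh, tm = setup
        rng = np.random.default_rng(7)
        q = rng.standard_normal(mesh.n_quad)
        f = tm.spread(q)
        lhs = f.sum() * grid.cell_area
        rhs = np.dot(q, mesh.quad_weights)
        assert lhs == pytest.approx(rhs, rel=1e-10)
        # and for the constant-density case against the region area
        f1 = tm.spread(np.ones(mesh.n_quad))
        assert f1.sum() * grid.cell_area == pytest.approx(
            mesh.material_area(), rel=1e-10)

    def test_point_mass_at_cell_center(self):
        """A quadrature point exactly on a cell center puts value*weight/
        (dx1 dx2) there and nothing elsewhere (psi(0)=1, psi(+-1)=0)."""
        grid = build_grid(((0, 1), (0, 1)), 16, 16)
        x1, x2 = grid.cell_centers()
        nodes = np.array([[0.3, 0.3], [0.7, 0.3], [0.3, 0.7]])
        mesh = LagrangianMesh(nodes, np.array([[0, 1, 2]]), rule_order=1)
        mesh.quad_current = np.array([[x1[7], x2[9]]])
        w = mesh.quad_weights[0]
        f = spread(np.array([3.0]), mesh, grid).values
        assert f[7, 9] == pytest.approx(3.0 * w / grid.cell_area)
        f[7, 9] = 0.0
        assert np.abs(f).max() < 1e-14

    def test_edge_guard(self):
        grid = build_grid(((0, 1), (0, 1)), 16, 16)
        nodes = np.array([[0.3, 0.3], [0.7, 0.3], [0.3, 0.7]])
        mesh = LagrangianMesh(nodes, np.array([[0, 1, 2]]), rule_order=1)
        mesh.quad_current = np.array([[0.01, 0.5]])  # < 2 cells from the edge
        with pytest.raises(DomainOverflowError):
            spread(np.array([1.0]), mesh, grid)


class TestInterpolate:
    def test_constant_field_reproduced(self, setup):
        grid, mesh, tm = setup
        vals = tm.interpolate(np.full(grid.shape, 4.25).ravel())
        assert np.allclose(vals, 4.25, atol=1e-12)

    def test_cell_center_coincidence(self, setup):
        grid, mesh, tm = setup
        rng = np.random.default_rng(3)
        F = rng.standard_normal(grid.shape)
        x1, x2 = grid.cell_centers()
        pos = np.array([[x1[10], x2[20]], [x1[30], x2[5]]])
        out = interpolate(EulerianField(grid, F), pos)
        assert out[0] == pytest.approx(F[10, 20], abs=1e-13)
        assert out[1] == pytest.approx(F[30, 5], abs=1e-13)

    def test_linear_field_exact(self, setup):
        """The four-point cubic kernel reproduces linear fields."""
        grid, mesh, tm = setup
        X, Y = grid.meshgrid()
        V = 2.0 * X - 0.5 * Y + 0.3
        out = tm.interpolate(V.ravel())
        expected = (2.0 * mesh.quad_current[:, 0]
                    - 0.5 * mesh.quad_current[:, 1] + 0.3)
        assert np.abs(out - expected).max() < 1e-10


class TestAdjointnessAndRoundTrip:
    def test_adjointness(self, setup):
        """<spread(q), E> dx1 dx2 == sum_Q q_Q interp(E)_Q w_Q, exactly the
        transpose identity of the kernel matrix."""
        grid, mesh, tm = setup
        rng = np.random.default_rng(11)
        for _ in range(3):
            q = rng.standard_normal(mesh.n_quad)
            E = rng.standard_normal(grid.n1 * grid.n2)
            lhs = np.dot(tm.spread(q), E) * grid.cell_area
            rhs = np.dot(q * mesh.quad_weights, tm.interpolate(E))
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_round_trip_constant_within_two_percent_interior(self, setup):
        grid, mesh, tm = setup
        rt = tm.interpolate(tm.spread(np.ones(mesh.n_quad)))
        qp = mesh.quad_current
        interior = np.all((qp > 0.15) & (qp < 0.85), axis=1)
        assert np.abs(rt[interior] - 1.0).max() < 0.02

    def test_cached_maps_match_direct_summation_bitwise(self, setup):
        """The assembled sparse maps are the same sums as the one-shot
        formulas, so results agree to the last bit."""
        grid, mesh, tm = setup
        rng = np.random.default_rng(5)
        q = rng.standard_normal(mesh.n_quad)
        f_direct = spread(q, mesh, grid).values.ravel()
        assert np.array_equal(tm.spread(q), f_direct)
        E = rng.standard_normal(grid.shape)
        v_direct = interpolate(EulerianField(grid, E), mesh.quad_current)
        assert np.array_equal(tm.interpolate(E.ravel()), v_direct)


class TestProjection:
    def test_constant_reproduced(self, setup):
        grid, mesh, tm = setup
        out = tm.project_to_nodes(np.full(mesh.n_quad, 2.5))
        assert np.allclose(out, 2.5, atol=1e-9)

    def test_linear_exact(self, setup):
        grid, mesh, tm = setup
        q = 1.5 * mesh.quad_material[:, 0] - 2.0 * mesh.quad_material[:, 1]
        out = tm.project_to_nodes(q)
        expected = 1.5 * mesh.nodes[:, 0] - 2.0 * mesh.nodes[:, 1]
        assert np.allclose(out, expected, atol=1e-9)

    def test_two_triangle_mesh_matches_dense_oracle(self):
        """Brute-force dense assembly and solve on a 2-triangle unit square."""
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        elements = np.array([[0, 1, 2], [0, 2, 3]])
        mesh = LagrangianMesh(nodes, elements, rule_order=2)
        rng = np.random.default_rng(2)
        q = rng.standard_normal(mesh.n_quad)
        # dense oracle: M_lm = sum_Q phi_l phi_m w, b_l = sum_Q phi_l q w
        B = mesh.basis.toarray()
        w = mesh.quad_weights
        M = B.T @ np.diag(w) @ B
        b = B.T @ (w * q)
        expected = np.linalg.solve(M, b)
        out = project_to_nodes(q, mesh)
        assert np.allclose(out, expected, atol=1e-12)

    def test_lumped_mode(self):
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        mesh = LagrangianMesh(nodes, np.array([[0, 1, 2], [0, 2, 3]]))
        out = project_to_nodes(np.full(mesh.n_quad, 3.0), mesh, lumped=True)
        assert np.allclose(out, 3.0, atol=1e-12)
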