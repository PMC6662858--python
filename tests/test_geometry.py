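import numpy as np
import pytest

from gsmono.config import load_config, preset, save_config
from gsmono.errors import ConfigurationError, ContractViolation
from gsmono.geometry import (BENCHMARK_NAMES, benchmark,
                             circle_ic, rectangle_ic, stimulus_masks,
                             ventricle_section)


class TestRectangleIC:
    @pytest.mark.parametrize("pos,expected", [
        ((0.5, 0.5), (1.0, 0.0)),
        ((2.0, 2.0), (0.0, 0.1)),
        ((0.5, 2.0), (0.0, 0.1)),
        ((2.0, 0.5), (0.0, 0.0)),
    ])
    def test_printed_branches(self, pos, expected):
        assert rectangle_ic(pos) == pytest.approx(expected)

    def test_seam_ties_first_match_wins(self):
        # x = 1.25 belongs to the left/lower branch (printed order)
        u, v = rectangle_ic((1.25, 0.5))
        assert (u, v) == (1.0, 0.0)
        u, v = rectangle_ic((0.5, 1.25))   # y = 1.25 -> upper rows
        assert (u, v) == (0.0, 0.1)

    def test_outside_rejected(self):
        with pytest.raises(ContractViolation):
            rectangle_ic((3.0, 0.5))

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0.01, 2.49, size=(100, 2))
        u, v = rectangle_ic(pts)
        for k in range(100):
            assert (u[k], v[k]) == rectangle_ic(pts[k])


class TestCircleIC:
    def test_depolarized_sector_point(self):
        # (1.0, 1.0): 1.25 - sqrt(1.25^2 - 0.25^2) ~ 0.0253 < 1.0 <= 1.25
        u, v = circle_ic((1.0, 1.0))
        assert (u, v) == (1.0, 0.0)

    def test_recovery_halfdisc_point(self):
        u, v = circle_ic((1.0, 1.5))
        assert (u, v) == (0.0, 0.1)

    def test_quiescent_point(self):
        u, v = circle_ic((2.0, 0.5))
        assert (u, v) == (0.0, 0.0)

    def test_outside_disk_rejected(self):
        with pytest.raises(ContractViolation):
            circle_ic((2.5, 2.5))

    def test_pure_and_deterministic(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.5], [2.0, 0.5], [1.25, 1.25]])
        u1, v1 = circle_ic(pts)
        u2, v2 = circle_ic(pts)
        assert np.array_equal(u1, u2) and np.array_equal(v1, v2)


class TestBenchmarkSpecs:
    def test_printed_domains_and_resolutions(self):
        s = benchmark("rect_stationary")
        assert s.extent == ((-0.1, 2.6), (-0.1, 2.6))
        assert s.n_cells == 275 and s.dt == 0.1
        m = benchmark("circle_moving")
        assert m.extent == ((-0.75, 3.25), (-0.75, 3.25))
        assert m.n_cells == 408 and m.moving

    def test_unknown_name(self):
        with pytest.raises(ConfigurationError):
            benchmark("hexagon_stationary")

    @pytest.mark.parametrize("name", BENCHMARK_NAMES)
    def test_preset_round_trips_through_yaml(self, name, tmp_path):
        cfg = preset(name, scale=0.2)
        p = tmp_path / "c.yaml"
        save_config(cfg, p)
        cfg2 = load_config(p)
        assert cfg2 == cfg


class TestICSpreadingSupport:
    def test_thresholded_spread_matches_indicator_region(self):
        """Sampling the depolarized-quadrant indicator at quadrature points
        and spreading it yields an Eulerian field whose u > 0.5 support
        matches the analytic region to within one kernel width (2 cells)."""
        from gsmono.cells import fhn_model
        from gsmono.grid import build_grid
        from gsmono.mesh import Rectangle, triangulate
        from gsmono.solver import Constants, Simulation

        g = build_grid(((-0.1, 2.6), (-0.1, 2.6)), 56, 56)
        mesh = triangulate(Rectangle((0.0, 0.0), (2.5, 2.5)), 0.5 * g.dx1)
        sim = Simulation(g, mesh, fhn_model(), Constants(), 0.1)
        sim.set_initial_potential(lambda p: rectangle_ic(p)[0])
        X, Y = g.meshgrid()
        inside = (X > 0) & (X <= 1.25) & (Y > 0) & (Y < 1.25)
        margin = 2.0 * g.dx1
        deep_in = (X > margin) & (X <= 1.25 - margin) & (Y > margin) & (Y < 1.25 - margin)
        far_out = ~((X > -margin) & (X <= 1.25 + margin)
                    & (Y > -margin) & (Y < 1.25 + margin))
        exc = sim.state.V > 0.5
        assert np.all(exc[deep_in])
        assert not np.any(exc[far_out])
        assert inside.sum() > 0  # sanity: the region intersects the grid


@pytest.fixture(scope="module")
def transverse():
    return ventricle_section("transverse", target_edge_length=2.0)


class TestVentricleSections:
    def test_masks_positive_and_disjoint(self, transverse):
        mesh, masks, probes, bbox = transverse
        q = mesh.quad_material
        areas = {}
        sel = {}
        for name, fn in masks.items():
            m = fn(q)
            sel[name] = m
            areas[name] = mesh.quad_weights[m].sum()
            assert areas[name] > 0.0
        assert not np.any(sel["septum"] & sel["lv_endo"])
        assert not np.any(sel["septum"] & sel["rv_endo"])
        assert not np.any(sel["lv_endo"] & sel["rv_endo"])

    def test_fits_printed_box(self, transverse):
        mesh, masks, probes, bbox = transverse
        assert bbox == ((0.0, 130.0), (0.0, 110.0))
        assert mesh.nodes[:, 0].min() >= 0 and mesh.nodes[:, 0].max() <= 130
        assert mesh.nodes[:, 1].min() >= 0 and mesh.nodes[:, 1].max() <= 110

    def test_probes_inside_tissue(self, transverse):
        mesh, masks, probes, bbox = transverse
        for name, p in probes.items():
            d = np.linalg.norm(mesh.nodes - np.asarray(p), axis=1).min()
            assert d < 2.0, name

    def test_healthy_mask_is_septum_plus_both_endo(self, transverse):
        mesh, masks, probes, bbox = transverse
        q = mesh.quad_material
        healthy = stimulus_masks(mesh, masks, "healthy")
        union = masks["septum"](q) | masks["lv_endo"](q) | masks["rv_endo"](q)
        assert np.array_equal(healthy, union)

    def test_lbbb_mask_is_rv_endo_only(self, transverse):
        mesh, masks, probes, bbox = transverse
        lbbb = stimulus_masks(mesh, masks, "lbbb")
        assert np.array_equal(lbbb, np.asarray(masks["rv_endo"](mesh.quad_material)))
        healthy = stimulus_masks(mesh, masks, "healthy")
        assert lbbb.sum() < healthy.sum()
        with pytest.raises(ConfigurationError):
            stimulus_masks(mesh, masks, "rbbb")

    def test_longitudinal_builds(self):
        mesh, masks, probes, bbox = ventricle_section("longitudinal",
                                                      target_edge_length=2.0)
        assert bbox == ((0.0, 140.0), (0.0, 140.0))
        assert mesh.material_area() > 1000.0
        for fn in masks.values():
            assert fn(mesh.quad_material).sum() > 0

    def test_unknown_kind(self):
        with pytest.raises(ConfigurationError):
            ventricle_section("sagittal")
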