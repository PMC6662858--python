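import numpy as np
import pytest

from gsmono.analysis import (ProbeTrace, activation_times, arm_point_near,
                             crossing_times, front_speed_at_point,
                             front_speed_from_patches, rotation_sense,
                             spiral_arm_width, SENTINEL)
from gsmono.errors import ContractViolation, InsufficientDataError
from gsmono.grid import build_grid


def plane_wave_snapshots(grid, c, normal, times, width=np.inf):
    """u = 1 behind a front moving at speed c along `normal` (unit), with an
    optional finite band width (analytic indicator)."""
    X, Y = grid.meshgrid()
    s = X * normal[0] + Y * normal[1]
    snaps = []
    for t in times:
        phase = c * t - s
        snaps.append(((phase >= 0) & (phase <= width)).astype(float))
    return np.asarray(snaps)


class TestActivationTimes:
    def test_plane_wave_exact_at_cell_centers(self):
        g = build_grid(((0, 1), (0, 1)), 40, 40)
        times = np.linspace(0, 6, 301)
        snaps = plane_wave_snapshots(g, 0.2, (1.0, 0.0), times)
        act = activation_times(snaps, times, 0.5)
        X, _ = g.meshgrid()
        ok = np.isfinite(act)
        # indicator front: crossing bracketed within one frame interval
        assert np.abs(act[ok] - X[ok] / 0.2).max() < (times[1] - times[0])

    def test_constant_subthreshold_all_sentinel(self):
        g = build_grid(((0, 1), (0, 1)), 8, 8)
        snaps = np.full((5, 8, 8), 0.2)
        act = activation_times(snaps, np.arange(5.0), 0.5)
        assert np.all(act == SENTINEL)

    def test_linear_interpolation_between_frames(self):
        g = build_grid(((0, 1), (0, 1)), 4, 4)
        snaps = np.zeros((3, 4, 4))
        snaps[1] = 0.2
        snaps[2] = 1.0
        act = activation_times(snaps, [0.0, 1.0, 2.0], 0.5)
        # 0.2 -> 1.0 crossing of 0.5 at fraction 3/8
        assert np.allclose(act, 1.0 + 3.0 / 8.0)

    def test_requires_two_frames(self):
        with pytest.raises(ContractViolation):
            activation_times(np.zeros((1, 4, 4)), [0.0], 0.5)


class TestCrossingTimes:
    def test_multiple_passes_interpolated(self):
        t = np.arange(0.0, 10.0, 1.0)
        s = np.array([0, 1, 0, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        c = crossing_times(t, s, 0.5)
        assert np.allclose(c, [0.5, 3.5, 7.5])

    def test_probe_trace_activation(self):
        tr = ProbeTrace((0, 0), np.arange(5.0), np.array([0, 0, 1, 1, 0.0]), {})
        assert tr.activation_time(0.5) == pytest.approx(1.5)
        with pytest.raises(ContractViolation):
            ProbeTrace((0, 0), np.array([0.0, 1.0, 1.5]), np.zeros(3), {})


class TestFrontSpeed:
    @pytest.mark.parametrize("normal", [(1.0, 0.0), (0.0, 1.0),
                                        (0.6, 0.8), (-0.707, 0.707)])
    def test_plane_wave_speed_recovered(self, normal):
        """1/|grad T| of the upstroke-time map recovers the normal speed to
        < 1% for plane waves of any orientation (two passes)."""
        g = build_grid(((0, 1), (0, 1)), 50, 50)
        c = 0.2
        times = np.arange(0.0, 22.0, 0.02)
        X, Y = g.meshgrid()
        s = X * normal[0] + Y * normal[1]
        # two passes: the same front sweeps twice, 10 t.u. apart
        snaps = None  # assembled per-cell below via patches
        i, j = 24, 24
        patch = np.zeros((len(times), 4, 4))
        for a in range(4):
            for b in range(4):
                ss = s[i - 1 + a, j - 1 + b]
                for kpass in range(2):
                    # first pass reaches the probe around t = 3, second at 13
                    phase = c * (times - 3.0 - 10.0 * kpass) - (ss - 0.5)
                    patch[:, a, b] += ((phase >= 0) & (phase <= 1.2)).astype(float)
        point = (X[i, j] + g.dx1 / 2, Y[i, j] + g.dx2 / 2)
        speed = front_speed_from_patches(times, patch, g, threshold=0.5,
                                         t_min=0.0)
        assert speed == pytest.approx(c, rel=0.01)

    def test_axis_aligned_wave_symmetric_estimators(self):
        """A wave along x gives the same answer whether y is the second
        straddling axis or the grid is transposed (90-degree rotation)."""
        g = build_grid(((0, 1), (0, 1)), 50, 50)
        times = np.arange(0.0, 18.0, 0.02)
        X, Y = g.meshgrid()
        snaps = []
        for t in times:   # the same front sweeps twice, 10 t.u. apart
            u = np.zeros(g.shape)
            for k in (0, 1):
                phase = 0.2 * (t - 10.0 * k) - X
                u += ((phase >= 0) & (phase <= 0.5)).astype(float)
            snaps.append(u)
        snaps = np.asarray(snaps)
        v1 = front_speed_at_point(snaps, times, g, (0.5, 0.5))
        v2 = front_speed_at_point(np.transpose(snaps, (0, 2, 1)), times, g,
                                  (0.5, 0.5))
        assert v1 == pytest.approx(v2, rel=1e-9)
        assert v1 == pytest.approx(0.2, rel=0.01)

    def test_insufficient_passes(self):
        g = build_grid(((0, 1), (0, 1)), 20, 20)
        times = np.arange(0.0, 8.0, 0.1)
        snaps = plane_wave_snapshots(g, 0.2, (1.0, 0.0), times, width=0.4)
        with pytest.raises(InsufficientDataError):
            front_speed_at_point(snaps, times, g, (0.5, 0.5),
                                 window=(7.0, 8.0))


class TestSpiralArmWidth:
    def test_synthetic_band_width_recovered(self):
        """An analytic band of width 0.3 is recovered within one grid
        spacing, regardless of orientation."""
        for normal in ((1.0, 0.0), (0.6, 0.8)):
            g = build_grid(((0, 1), (0, 1)), 80, 80)
            X, Y = g.meshgrid()
            s = X * normal[0] + Y * normal[1]
            snap = ((s >= 0.4) & (s <= 0.7)).astype(float)
            pt = arm_point_near(snap, g, (0.55 * normal[0], 0.55 * normal[1]),
                                0.5)
            w = spiral_arm_width(snap, g, pt, threshold=0.5)
            assert w == pytest.approx(0.3, abs=g.dx1)

    def test_whole_domain_superthreshold_degenerates_to_extent(self):
        g = build_grid(((0, 1), (0, 1)), 40, 40)
        X, _ = g.meshgrid()
        snap = 1.0 + 0.1 * X   # everywhere excited, mild tilt fixes the normal
        w = spiral_arm_width(snap, g, (0.5, 0.5), threshold=0.5,
                             max_halflength=2.0)
        assert w > 0.9    # fills the probe line across the domain

    def test_no_excited_cells(self):
        g = build_grid(((0, 1), (0, 1)), 20, 20)
        with pytest.raises(InsufficientDataError):
            arm_point_near(np.zeros(g.shape), g, (0.5, 0.5), 0.5)

    def test_rotation_invariance(self):
        """Width estimate is invariant under a 90-degree rotation of the
        snapshot and probe point."""
        g = build_grid(((0, 1), (0, 1)), 80, 80)
        X, Y = g.meshgrid()
        snap = ((X >= 0.4) & (X <= 0.7)).astype(float)
        w1 = spiral_arm_width(snap, g, (0.55, 0.5), threshold=0.5)
        # rotate 90 deg: [i,j] -> [j, n-1-i] maps x-band to y-band
        snap_rot = snap.T[:, ::-1].copy()
        w2 = spiral_arm_width(snap_rot, g, (0.5, 1 - 0.55), threshold=0.5)
        assert w1 == pytest.approx(w2, rel=1e-6)


class TestRotationSense:
    def test_synthetic_rotor(self):
        t = np.linspace(0, 10, 200)
        cw = np.c_[np.cos(-0.8 * t), np.sin(-0.8 * t)]
        ccw = np.c_[np.cos(0.8 * t), np.sin(0.8 * t)]
        assert rotation_sense(t, cw, (0.0, 0.0)) == "clockwise"
        assert rotation_sense(t, ccw, (0.0, 0.0)) == "counterclockwise"

    def test_wrap_robust(self):
        t = np.linspace(0, 200, 400)
        th = -0.3 * t
        c = np.c_[2 * np.cos(th), 2 * np.sin(th)] + 0.05 * np.sin(7 * t)[:, None]
        assert rotation_sense(t, c, (0.0, 0.0)) == "clockwise"

    def test_needs_enough_points(self):
        with pytest.raises(InsufficientDataError):
            rotation_sense([0, 1], np.full((2, 2), np.nan), (0, 0))
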