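"""Post-processing: activation-time maps, front speeds, spiral-arm widths,
rotation sense, and probe traces.

All estimators work on plain snapshot arrays (cell-centered fields indexed
[i, j] with axis 0 along x) plus their times, or on the per-step probe
patches recorded by the solver.  Upstroke times are linearly interpolated
between frames; front speed at a point is recovered from the gradient of
the local upstroke-time map (for a plane wave with speed c and normal n,
the apparent axis-wise time delays give grad T = n / c exactly, so
c = 1 / |grad T|).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ContractViolation, InsufficientDataError
from .grid import CartesianGrid

__all__ = [
    "ProbeTrace", "activation_times", "crossing_times",
    "front_speed_at_point", "front_speed_from_patches",
    "spiral_arm_width", "arm_point_near", "rotation_sense",
]

SENTINEL = np.inf   # activation time of never-activated cells


@dataclass
class ProbeTrace:
    """Uniformly sampled time series of V (and named observables) at a point."""

    position: tuple[float, float]
    times: np.ndarray
    V: np.ndarray
    observables: dict

    def __post_init__(self):
        dt = np.diff(self.times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-8)):
            raise ContractViolation("probe sampling times must be uniform and increasing")

    def activation_time(self, threshold: float) -> float:
        t = crossing_times(self.times, self.V, threshold)
        return t[0] if len(t) else SENTINEL


def crossing_times(times: np.ndarray, series: np.ndarray,
                   threshold: float) -> np.ndarray:
    """All upward threshold crossings of a time series, linearly interpolated."""
    s = np.asarray(series, dtype=float)
    below = s[:-1] < threshold
    above = s[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if len(idx) == 0:
        return np.empty(0)
    frac = (threshold - s[idx]) / (s[idx + 1] - s[idx])
    t = np.asarray(times)
    return t[idx] + frac * (t[idx + 1] - t[idx])


def activation_times(snapshots, times, threshold: float) -> np.ndarray:
    """Per-cell first upward-crossing time map (SENTINEL where never activated).

    ``snapshots`` is (n_frames, n1, n2); crossing times are linearly
    interpolated between the two straddling frames.
    """
    snaps = np.asarray(snapshots, dtype=float)
    t = np.asarray(times, dtype=float)
    if snaps.ndim != 3 or len(t) != len(snaps) or len(snaps) < 2:
        raise ContractViolation("need >= 2 snapshots with matching times")
    act = np.full(snaps.shape[1:], SENTINEL)
    done = np.zeros(snaps.shape[1:], dtype=bool)
    for k in range(len(t) - 1):
        a, b = snaps[k], snaps[k + 1]
        cross = (~done) & (a < threshold) & (b >= threshold)
        if np.any(cross):
            frac = (threshold - a[cross]) / (b[cross] - a[cross])
            act[cross] = t[k] + frac * (t[k + 1] - t[k])
            done |= cross
    return act


# ---------------------------------------------------------------------------
# Front speed
# ---------------------------------------------------------------------------

def _pass_speeds(times, patch, grid: CartesianGrid, threshold: float,
                 pair_window: float):
    """Speeds of individual front passes from a (nt, 4, 4) cell patch.

    Uses the 2x2 block at patch indices 1..2 (the cells straddling the
    probe): per pass, axis-wise upstroke delays give grad T and the speed
    is 1/|grad T|.
    """
    t00 = crossing_times(times, patch[:, 1, 1], threshold)
    t10 = crossing_times(times, patch[:, 2, 1], threshold)
    t01 = crossing_times(times, patch[:, 1, 2], threshold)
    speeds, tpass = [], []
    for t0 in t00:
        dx_t = _nearest(t10, t0, pair_window)
        dy_t = _nearest(t01, t0, pair_window)
        if dx_t is None or dy_t is None:
            continue
        gx = (dx_t - t0) / grid.dx1
        gy = (dy_t - t0) / grid.dx2
        g = np.hypot(gx, gy)
        if g > 0:
            speeds.append(1.0 / g)
            tpass.append(t0)
    return np.asarray(speeds), np.asarray(tpass)


def _nearest(arr, t0, window):
    if len(arr) == 0:
        return None
    i = np.argmin(np.abs(arr - t0))
    return arr[i] if abs(arr[i] - t0) <= window else None


def front_speed_from_patches(times, patch, grid: CartesianGrid, *,
                             threshold: float = 0.5, t_min: float = 0.0,
                             pair_window: float = 5.0) -> float:
    """Mean front speed at a probe from its per-step 4x4 patch trace,
    averaged over passes with upstroke time >= t_min."""
    speeds, tpass = _pass_speeds(np.asarray(times), np.asarray(patch),
                                 grid, threshold, pair_window)
    sel = tpass >= t_min
    if sel.sum() < 2:
        raise InsufficientDataError(
            f"front passed the probe {int(sel.sum())} time(s) after t={t_min}; "
            "need at least 2")
    return float(speeds[sel].mean())


def front_speed_at_point(snapshots, times, grid: CartesianGrid, point, *,
                         threshold: float = 0.5, window=None) -> float:
    """Mean front speed at a point from a snapshot series.

    Works frame-to-frame, so the snapshot cadence must resolve the upstroke
    (the solver's per-step patch recording is the preferred input; this
    variant supports stored snapshot series).  ``window`` is an optional
    (t_lo, t_hi) restriction on pass times.
    """
    snaps = np.asarray(snapshots)
    t = np.asarray(times)
    x1, x2 = grid.cell_centers()
    i = int(np.clip(np.searchsorted(x1, point[0]) - 1, 1, grid.n1 - 3))
    j = int(np.clip(np.searchsorted(x2, point[1]) - 1, 1, grid.n2 - 3))
    patch = snaps[:, i - 1:i + 3, j - 1:j + 3]
    t_min = window[0] if window is not None else 0.0
    t_hi = window[1] if window is not None else np.inf
    speeds, tpass = _pass_speeds(t, patch, grid, threshold,
                                 pair_window=max(5.0, 5 * (t[1] - t[0])))
    sel = (tpass >= t_min) & (tpass <= t_hi)
    if sel.sum() < 2:
        raise InsufficientDataError("front passed the point fewer than 2 times in window")
    return float(speeds[sel].mean())


# ---------------------------------------------------------------------------
# Spiral arm width
# ---------------------------------------------------------------------------

def arm_point_near(snapshot, grid: CartesianGrid, point, threshold: float,
                   min_distance: float = 0.0):
    """Nearest super-threshold cell center to ``point`` (at least
    ``min_distance`` away), used to pick the arm crossing nearest the
    domain centroid."""
    X, Y = grid.meshgrid()
    exc = np.asarray(snapshot) >= threshold
    if not np.any(exc):
        raise InsufficientDataError("no super-threshold cells in snapshot")
    d = np.hypot(X - point[0], Y - point[1])
    d[~exc] = np.inf
    d[d < min_distance] = np.inf
    i, j = np.unravel_index(np.argmin(d), d.shape)
    if not np.isfinite(d[i, j]):
        raise InsufficientDataError("no super-threshold cell beyond min_distance")
    return float(X[i, j]), float(Y[i, j])


def spiral_arm_width(snapshot, grid: CartesianGrid, point, *,
                     threshold: float = 0.5, smooth_sigma: float = 2.0,
                     max_halflength: float = 1.0) -> float:
    """Width of the excited arm through ``point``, measured along the local
    front normal.

    The normal is the dominant gradient direction near the point — the
    principal eigenvector of the locally averaged structure tensor
    grad(u) grad(u)^T, which stays well-defined in the middle of the excited
    band where the raw gradient itself vanishes.  The width is the length of
    the maximal super-threshold segment along that line, with sub-cell
    endpoints by linear interpolation of the bilinearly sampled profile.
    """
    snap = np.asarray(snapshot, dtype=float)
    x1, x2 = grid.cell_centers()

    def sample(pts):
        ci = (pts[:, 0] - x1[0]) / grid.dx1
        cj = (pts[:, 1] - x2[0]) / grid.dx2
        return ndimage.map_coordinates(snap, [ci, cj], order=1, mode="nearest")

    sm = ndimage.gaussian_filter(snap, smooth_sigma)
    gi = np.gradient(sm, grid.dx1, axis=0)
    gj = np.gradient(sm, grid.dx2, axis=1)
    # structure tensor, averaged over ~the arm half-width
    win = 3.0 * smooth_sigma
    Jxx = ndimage.gaussian_filter(gi * gi, win)
    Jxy = ndimage.gaussian_filter(gi * gj, win)
    Jyy = ndimage.gaussian_filter(gj * gj, win)
    i = int(np.clip(round((point[0] - x1[0]) / grid.dx1), 0, grid.n1 - 1))
    j = int(np.clip(round((point[1] - x2[0]) / grid.dx2), 0, grid.n2 - 1))
    J = np.array([[Jxx[i, j], Jxy[i, j]], [Jxy[i, j], Jyy[i, j]]])
    evals, evecs = np.linalg.eigh(J)
    if evals[-1] <= 0:
        raise InsufficientDataError("flat field at the probe point; no front normal")
    nvec = evecs[:, -1]

    h = 0.25 * min(grid.dx1, grid.dx2)
    n_steps = int(np.ceil(max_halflength / h))
    s = np.arange(-n_steps, n_steps + 1) * h
    pts = np.asarray(point)[None, :] + s[:, None] * nvec[None, :]
    # clip the probe line to the grid
    inside = ((pts[:, 0] >= x1[0]) & (pts[:, 0] <= x1[-1])
              & (pts[:, 1] >= x2[0]) & (pts[:, 1] <= x2[-1]))
    s, pts = s[inside], pts[inside]
    prof = sample(pts)
    k0 = int(np.argmin(np.abs(s)))
    if prof[k0] < threshold:
        k_exc = np.flatnonzero(prof >= threshold)
        if len(k_exc) == 0:
            raise InsufficientDataError("no super-threshold segment along the probe line")
        k0 = k_exc[np.argmin(np.abs(s[k_exc]))]
    lo = k0
    while lo > 0 and prof[lo - 1] >= threshold:
        lo -= 1
    hi = k0
    while hi < len(s) - 1 and prof[hi + 1] >= threshold:
        hi += 1
    s_lo = s[lo] if lo == 0 else _edge(s[lo - 1], s[lo], prof[lo - 1], prof[lo], threshold)
    s_hi = s[hi] if hi == len(s) - 1 else _edge(s[hi + 1], s[hi], prof[hi + 1], prof[hi],
                                               threshold)
    return float(s_hi - s_lo)


def _edge(s_out, s_in, v_out, v_in, threshold):
    frac = (threshold - v_in) / (v_out - v_in)
    return s_in + frac * (s_out - s_in)


# ---------------------------------------------------------------------------
# Rotation sense
# ---------------------------------------------------------------------------

def rotation_sense(times, centroids, center) -> str:
    """'clockwise' or 'counterclockwise' from the drift of the excited
    region's centroid around ``center`` (y-up orientation).

    The centroid of the thresholded excitation pattern co-rotates with the
    spiral arm; the sign of the average unwrapped angular velocity gives the
    rotation sense.
    """
    c = np.asarray(centroids, dtype=float)
    ok = np.all(np.isfinite(c), axis=1)
    c = c[ok]
    if len(c) < 3:
        raise InsufficientDataError("need >= 3 finite centroids")
    th = np.arctan2(c[:, 1] - center[1], c[:, 0] - center[0])
    # wrap-robust per-sample increments; their sum gives the net rotation
    dth = np.angle(np.exp(1j * np.diff(th)))
    return "clockwise" if dth.sum() < 0 else "counterclockwise"
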