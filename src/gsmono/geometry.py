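"""Benchmark geometries, initial conditions, and synthetic ventricular
sections with healthy / left-bundle-branch-block stimulus masks.

The spiral-wave benchmarks use the classic broken-front initial data: a
depolarized quadrant in the potential and an elevated recovery variable in
the upper half of the domain, whose interaction curls the front into a
single rotating spiral.  The piecewise branches of the printed case tables
overlap on the seam lines x = 1.25 / y = 1.25; branches are evaluated in
printed order, first match wins (a measure-zero choice, but determinism
needs a rule).

The ventricular sections are *synthetic idealized* stand-ins for real
patient cross-sections: two overlapping disks with carved cavities
(transverse) or two clipped ellipses (longitudinal).  They preserve the
topology that matters for activation-order experiments — a thick-walled LV,
a thin-walled RV, a shared septum — not any patient anatomy, so activation
experiments on them are qualitative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ContractViolation
from .grid import build_grid
from .mesh import Circle, ImplicitRegion, MotionModel, Rectangle, triangulate

__all__ = [
    "rectangle_ic", "circle_ic", "BenchmarkSpec", "benchmark",
    "BENCHMARK_NAMES", "VentricleParams", "ventricle_section",
    "stimulus_masks",
]

_RECT_LO, _RECT_HI = 0.0, 2.5
_MID = 1.25
_CIRCLE_C = np.array([1.25, 1.25])
_CIRCLE_R = 1.25


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo benchmark initial conditions
# ---------------------------------------------------------------------------

def rectangle_ic(position) -> tuple[np.ndarray, np.ndarray]:
    """(u0, v0) of the rectangular benchmark: u = 1 on the lower-left
    quadrant, v = 0.1 on the upper half.  Vectorized over (n, 2) positions."""
    p = np.atleast_2d(np.asarray(position, dtype=float))
    x, y = p[:, 0], p[:, 1]
    eps = 1e-12
    if np.any((x < _RECT_LO - eps) | (x > _RECT_HI + eps)
              | (y < _RECT_LO - eps) | (y > _RECT_HI + eps)):
        raise ContractViolation("rectangle_ic position outside [0, 2.5]^2")
    lower = y < _MID          # branches 1-2 (printed order: lower rows first)
    left = x <= _MID
    u0 = np.where(lower & left, 1.0, 0.0)
    v0 = np.where(lower, 0.0, 0.1)
    if np.ndim(position) == 1:
        return float(u0[0]), float(v0[0])
    return u0, v0


def _arc(s):
    """sqrt(R^2 - (R - s)^2), clipped to the disk."""
    return np.sqrt(np.maximum(_CIRCLE_R ** 2 - (_CIRCLE_R - s) ** 2, 0.0))


def circle_ic(position) -> tuple[np.ndarray, np.ndarray]:
    """(u0, v0) of the circular benchmark: arc-bounded lower-left sector of
    depolarization and upper half-disc of elevated recovery."""
    p = np.atleast_2d(np.asarray(position, dtype=float))
    x, y = p[:, 0], p[:, 1]
    r2 = (x - _CIRCLE_C[0]) ** 2 + (y - _CIRCLE_C[1]) ** 2
    if np.any(r2 > _CIRCLE_R ** 2 * (1 + 1e-9)):
        raise ContractViolation("circle_ic position outside the benchmark disk")
    ax, ay = _arc(x), _arc(y)
    u_sel = (_MID - ay < x) & (x <= _MID) & (_MID - ax < y) & (y <= _MID)
    v_sel = (_MID - ay < x) & (x < _MID + ay) & (_MID <= y) & (y < _MID + ax)
    u0 = np.where(u_sel, 1.0, 0.0)
    v0 = np.where(v_sel, 0.1, 0.0)
    if np.ndim(position) == 1:
        return float(u0[0]), float(v0[0])
    return u0, v0


# ---------------------------------------------------------------------------
# Named benchmark specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkSpec:
    """A named, fully-determined benchmark configuration.

    The stationary FHN benchmarks use the ghost box [-0.1, 2.6]^2 at
    275 x 275 with dt = 0.1; the moving ones [-0.75, 3.25]^2 at 408 x 408.
    ``scale`` < 1 coarsens grid and time step together (cells ~ scale,
    dt ~ 1/scale) for desk-scale runs; scale = 1 is the printed resolution.
    """

    name: str
    extent: tuple
    n_cells: int
    dt: float
    region: object
    ic: object            # callable position -> (u0, v0), or None
    moving: bool = False
    motion_t_stop: float = 1.25

    def grid(self, scale: float = 1.0):
        n = max(int(round(self.n_cells * scale)), 8)
        return build_grid(self.extent, n, n)

    def time_step(self, scale: float = 1.0) -> float:
        return self.dt / scale

    def mesh(self, scale: float = 1.0, rule_order: int = 2,
             refinement_factor: float = 0.5):
        g = self.grid(scale)
        # moving structures dilate by (1 + 0.4 t_stop); keep the *final*
        # edge lengths under the leak limit
        dilation = 1.0 + 0.4 * self.motion_t_stop if self.moving else 1.0
        target = refinement_factor * min(g.dx1, g.dx2) / dilation
        return triangulate(self.region, target, rule_order=rule_order)

    def motion(self):
        if not self.moving:
            return None
        if isinstance(self.region, Rectangle):
            c = tuple((np.asarray(self.region.lo) + np.asarray(self.region.hi)) / 2)
        elif isinstance(self.region, Circle):
            c = self.region.center
        else:
            raise ConfigurationError("motion presets exist for rectangle/circle only")
        return MotionModel(centroid=c, rate=0.4, t_stop=self.motion_t_stop)


_STATIONARY_EXTENT = ((-0.1, 2.6), (-0.1, 2.6))
_MOVING_EXTENT = ((-0.75, 3.25), (-0.75, 3.25))

_BENCHMARKS = {
    "rect_stationary": BenchmarkSpec(
        "rect_stationary", _STATIONARY_EXTENT, 275, 0.1,
        Rectangle((0.0, 0.0), (2.5, 2.5)), rectangle_ic),
    "circle_stationary": BenchmarkSpec(
        "circle_stationary", _STATIONARY_EXTENT, 275, 0.1,
        Circle((1.25, 1.25), 1.25), circle_ic),
    "rect_moving": BenchmarkSpec(
        "rect_moving", _MOVING_EXTENT, 408, 0.1,
        Rectangle((0.0, 0.0), (2.5, 2.5)), rectangle_ic, moving=True),
    "circle_moving": BenchmarkSpec(
        "circle_moving", _MOVING_EXTENT, 408, 0.1,
        Circle((1.25, 1.25), 1.25), circle_ic, moving=True),
}

BENCHMARK_NAMES = tuple(_BENCHMARKS)


def benchmark(name: str) -> BenchmarkSpec:
    try:
        return _BENCHMARKS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown benchmark {name!r}; available: {', '.join(_BENCHMARKS)}") from None


# ---------------------------------------------------------------------------
# Synthetic ventricular sections
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VentricleParams:
    """Parameters of the synthetic biventricular cross-sections (mm).

    Transverse: tissue = (disk(c_lv, lv_outer) U disk(c_rv, rv_outer))
    minus the LV cavity disk(c_lv, lv_inner) and the crescent RV cavity
    {|x - c_rv| < rv_inner} \\ {|x - c_lv| < lv_inner + septum}.  Fits a
    130 x 110 mm box.  Longitudinal: the same construction with ellipses
    clipped at a basal plane, fitting 140 x 140 mm.
    """

    lv_center: tuple = (85.0, 55.0)
    lv_outer: float = 33.0
    lv_inner: float = 17.0
    rv_center: tuple = (47.0, 55.0)
    rv_outer: float = 36.0
    rv_inner: float = 30.0
    septum_width: float = 8.0
    endo_depth: float = 3.5      # stimulated endocardial shell thickness
    # longitudinal section
    long_lv_center: tuple = (88.0, 72.0)
    long_lv_semi: tuple = (34.0, 58.0)
    long_lv_wall: float = 13.0
    long_rv_center: tuple = (50.0, 78.0)
    long_rv_semi: tuple = (36.0, 50.0)
    long_rv_wall: float = 7.0
    long_base_y: float = 122.0


def _d(p, c):
    p = np.atleast_2d(p)
    return np.hypot(p[:, 0] - c[0], p[:, 1] - c[1])


def _transverse_masks(params: VentricleParams):
    q = params
    rs = q.lv_inner + q.septum_width     # radius of the LV circle bounding the RV cavity

    def tissue(p):
        dl, dr = _d(p, q.lv_center), _d(p, q.rv_center)
        outer = (dl <= q.lv_outer) | (dr <= q.rv_outer)
        lv_cav = dl < q.lv_inner
        rv_cav = (dr < q.rv_inner) & (dl > rs)
        return outer & ~lv_cav & ~rv_cav

    y_c = q.lv_center[1]

    def lower_two_thirds(p):
        # septum/endocardium segments below the upper third of the chambers
        return np.atleast_2d(p)[:, 1] <= y_c + q.lv_outer / 3.0

    def lower_third(p):
        return np.atleast_2d(p)[:, 1] <= y_c - q.lv_outer / 3.0

    def septum(p):
        # wall between the cavities, minus the RV-side endocardial shell so
        # the named masks stay disjoint (the shell belongs to rv_endo)
        dl, dr = _d(p, q.lv_center), _d(p, q.rv_center)
        return tissue(p) & (dl <= rs - q.endo_depth) & (dr <= q.rv_inner)

    def lv_endo(p):
        dl = _d(p, q.lv_center)
        return tissue(p) & (dl >= q.lv_inner) & (dl <= q.lv_inner + q.endo_depth)

    def rv_endo(p):
        # shell around the crescent cavity: free-wall side plus septal side
        dl, dr = _d(p, q.lv_center), _d(p, q.rv_center)
        free = (dr >= q.rv_inner) & (dr <= q.rv_inner + q.endo_depth) & (dl > rs)
        septal = (dl <= rs) & (dl >= rs - q.endo_depth) & (dr < q.rv_inner)
        return tissue(p) & (free | septal)

    masks = {
        "septum": lambda p: septum(p) & lower_two_thirds(p),
        "lv_endo": lambda p: lv_endo(p) & lower_third(p) & ~septum(p),
        "rv_endo": lambda p: rv_endo(p) & lower_third(p),
    }
    probes = {
        # on the RV-facing septal surface, lower third (stimulated in both modes)
        "septal": (q.lv_center[0] - (rs - 1.0) * np.cos(np.deg2rad(40.0)),
                   q.lv_center[1] - (rs - 1.0) * np.sin(np.deg2rad(40.0))),
        # mid LV lateral wall, far side from the septum
        "lv_lateral": (q.lv_center[0] + q.lv_inner + (q.lv_outer - q.lv_inner) / 2,
                       q.lv_center[1]),
        "rv_free_wall": (q.rv_center[0] - q.rv_inner - 2.5, q.rv_center[1]),
        "lv_apexward": (q.lv_center[0], q.lv_center[1] - q.lv_inner
                        - (q.lv_outer - q.lv_inner) / 2),
    }
    bbox = ((0.0, 130.0), (0.0, 110.0))
    return tissue, masks, probes, bbox


def _longitudinal_masks(params: VentricleParams):
    q = params

    def ell(p, c, semi):
        p = np.atleast_2d(p)
        return np.hypot((p[:, 0] - c[0]) / semi[0], (p[:, 1] - c[1]) / semi[1])

    def inner(p, c, semi, w):
        return np.hypot(
            (np.atleast_2d(p)[:, 0] - c[0]) / (semi[0] - w),
            (np.atleast_2d(p)[:, 1] - c[1] - w / 2) / (semi[1] - w))

    def below_base(p):
        return np.atleast_2d(p)[:, 1] <= q.long_base_y

    def tissue(p):
        lv = ell(p, q.long_lv_center, q.long_lv_semi) <= 1.0
        rv = ell(p, q.long_rv_center, q.long_rv_semi) <= 1.0
        lv_cav = inner(p, q.long_lv_center, q.long_lv_semi, q.long_lv_wall) < 1.0
        lv_shield = ell(p, q.long_lv_center,
                        (q.long_lv_semi[0] - q.long_lv_wall + q.septum_width,
                         q.long_lv_semi[1] - q.long_lv_wall + q.septum_width)) < 1.0
        rv_cav = (inner(p, q.long_rv_center, q.long_rv_semi, q.long_rv_wall) < 1.0) \
            & ~lv_shield
        return (lv | rv) & ~lv_cav & ~rv_cav & below_base(p)

    y_apex = q.long_lv_center[1] - q.long_lv_semi[1]
    span = q.long_base_y - y_apex

    def lower_two_thirds(p):
        return np.atleast_2d(p)[:, 1] <= y_apex + 2 * span / 3

    def lower_third(p):
        return np.atleast_2d(p)[:, 1] <= y_apex + span / 3

    def septum(p):
        lv_shield = ell(p, q.long_lv_center,
                        (q.long_lv_semi[0] - q.long_lv_wall + q.septum_width,
                         q.long_lv_semi[1] - q.long_lv_wall + q.septum_width)) < 1.0
        rv = ell(p, q.long_rv_center, q.long_rv_semi) <= 1.0
        return tissue(p) & lv_shield & rv

    def lv_endo(p):
        # endocardial shell just outside the cavity (smaller w = larger ellipse)
        e = inner(p, q.long_lv_center, q.long_lv_semi, q.long_lv_wall)
        shell = (e >= 1.0) & (inner(p, q.long_lv_center, q.long_lv_semi,
                                    q.long_lv_wall - q.endo_depth) < 1.0)
        return tissue(p) & shell & ~septum(p)

    def rv_endo(p):
        e = inner(p, q.long_rv_center, q.long_rv_semi, q.long_rv_wall)
        shell = (e >= 1.0) & (inner(p, q.long_rv_center, q.long_rv_semi,
                                    q.long_rv_wall - q.endo_depth) < 1.0)
        near_sept = septum(np.atleast_2d(p))
        return tissue(p) & (shell | (near_sept & lower_third(p)))

    masks = {
        "septum": lambda p: septum(p) & lower_two_thirds(p),
        "lv_endo": lambda p: lv_endo(p) & lower_two_thirds(p),
        "rv_endo": lambda p: rv_endo(p) & lower_two_thirds(p),
    }
    probes = {
        "septal": (q.long_lv_center[0] - q.long_lv_semi[0] + q.long_lv_wall / 2,
                   q.long_lv_center[1]),
        "lv_lateral": (q.long_lv_center[0] + q.long_lv_semi[0] - q.long_lv_wall / 2,
                       q.long_lv_center[1] + 20.0),
        "rv_free_wall": (q.long_rv_center[0] - q.long_rv_semi[0] + q.long_rv_wall / 2,
                         q.long_rv_center[1]),
        "lv_apexward": (q.long_lv_center[0], y_apex + q.long_lv_wall / 2),
    }
    bbox = ((0.0, 140.0), (0.0, 140.0))
    return tissue, masks, probes, bbox


def ventricle_section(kind: str, params: VentricleParams = VentricleParams(),
                      target_edge_length: float = 1.0, rule_order: int = 2):
    """Build the synthetic ventricular section mesh and its region masks.

    Returns ``(mesh, masks, probes, bbox)`` where ``masks`` maps region
    names ('septum', 'lv_endo', 'rv_endo') to vectorized point indicators
    and ``probes`` maps probe names to (x, y) positions.
    """
    if kind == "transverse":
        tissue, masks, probes, bbox = _transverse_masks(params)
    elif kind == "longitudinal":
        tissue, masks, probes, bbox = _longitudinal_masks(params)
    else:
        raise ConfigurationError(f"kind must be 'transverse' or 'longitudinal', got {kind!r}")
    region = ImplicitRegion(tissue, (bbox[0][0], bbox[1][0]),
                            (bbox[0][1], bbox[1][1]))
    mesh = triangulate(region, target_edge_length, rule_order=rule_order)
    if not np.any(tissue(mesh.nodes)):
        raise ConfigurationError("ventricle section produced an empty mesh")
    return mesh, masks, probes, bbox


def stimulus_masks(mesh, masks, mode: str):
    """Quadrature-point stimulus mask for 'healthy' (septum + both
    lower-third endocardial regions) or 'lbbb' (RV endocardium only)."""
    q = mesh.quad_material
    if mode == "healthy":
        m = masks["septum"](q) | masks["lv_endo"](q) | masks["rv_endo"](q)
    elif mode == "lbbb":
        m = masks["rv_endo"](q)
    else:
        raise ConfigurationError(f"stimulus mode must be 'healthy' or 'lbbb', got {mode!r}")
    return np.asarray(m, dtype=bool)
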