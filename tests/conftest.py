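import numpy as np
import pytest

from gsmono.grid import build_grid
from gsmono.mesh import Rectangle, triangulate


@pytest.fixture(scope="session")
def small_grid():
    return build_grid(((-0.1, 2.6), (-0.1, 2.6)), 64, 64)


@pytest.fixture(scope="session")
def small_rect_mesh(small_grid):
    return triangulate(Rectangle((0.0, 0.0), (2.5, 2.5)),
                       0.5 * small_grid.dx1, host_grid=small_grid)


def direct_fhn_solve(n, dt, t_end, K=1e-4, a=0.1, eps=0.01, beta=0.5, gam=1.0,
                     L=2.5, ic=None):
    """Independent conforming-grid FD solver for the FHN monodomain on
    [0, L]^2 with zero Dirichlet boundaries (SSPRK3 in its textbook convex
    form, plain 5-point Laplacian).  Oracle only; shares no code with the
    ghost-structure path."""
    dx = L / n
    x = (np.arange(n) + 0.5) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    if ic is None:
        u = np.where((X <= 1.25) & (Y < 1.25), 1.0, 0.0)
        v = np.where(Y >= 1.25, 0.1, 0.0)
    else:
        u, v = ic(X, Y)

    def lap(w):
        p = np.pad(w, 1)
        return (p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2]
                - 4.0 * w) / dx ** 2

    def F(s):
        uu, vv = s
        return np.array([K * lap(uu) + uu * (1 - uu) * (uu - a) - vv,
                         eps * (beta * uu - gam * vv)])

    s = np.array([u, v])
    for _ in range(int(round(t_end / dt))):
        s1 = s + dt * F(s)
        s2 = 0.75 * s + 0.25 * (s1 + dt * F(s1))
        s = s / 3.0 + (2.0 / 3.0) * (s2 + dt * F(s2))
    return s[0], s[1], X, Y, dx
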