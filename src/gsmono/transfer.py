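"""Delta-kernel coupling between the Lagrangian structure and the Eulerian
ghost-box grid.

The 1-D four-point smooth kernel is the piecewise cubic

    psi(r) =  (1/2)(|r|+1)(|r|-1)(|r|-2)   for |r| <= 1
           = -(1/6)(|r|-1)(|r|-2)(|r|-3)   for 1 <= |r| <= 2
           =  0                            otherwise,

a partition of unity on the integer lattice that reproduces linear functions.
The 2-D smoothed delta is the tensor product normalized by the cell area,

    delta_h(x) = psi(x1/dx1) psi(x2/dx2) / (dx1 dx2),

which makes spreading (Lagrangian -> Eulerian, quadrature-weighted) and
interpolation (Eulerian -> Lagrangian, cell-area-weighted) exact adjoints of
one another and makes spreading conserve the integral of the spread quantity.
Nodal recovery from quadrature values is an L^2 projection through the P1
mass matrix.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import DomainOverflowError, NumericalError
from .grid import CartesianGrid, EulerianField
from .mesh import LagrangianMesh

__all__ = ["psi", "TransferMaps", "spread", "interpolate", "project_to_nodes"]

SUPPORT_RADIUS = 2  # grid cells, each side


def psi(r):
    """1-D four-point smooth delta kernel (vectorized)."""
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r <= 1.0
    out[m1] = 0.5 * (r[m1] + 1.0) * (r[m1] - 1.0) * (r[m1] - 2.0)
    m2 = (r > 1.0) & (r < 2.0)
    out[m2] = -(1.0 / 6.0) * (r[m2] - 1.0) * (r[m2] - 2.0) * (r[m2] - 3.0)
    return out if out.ndim else float(out)


def _kernel_matrix(grid: CartesianGrid, positions: np.ndarray) -> sp.csr_matrix:
    """Sparse matrix D of shape (n_cells, n_pos) with
    D[cell, p] = psi(dx_1 offset) * psi(dx_2 offset); no area normalization.

    Raises :class:`DomainOverflowError` if any position sits within kernel
    support of the box edge (the 4x4 stencil would leave the grid).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    npos = len(positions)
    # fractional cell-center index along each axis
    f1 = (positions[:, 0] - grid.extent_lo[0]) / grid.dx1 - 0.5
    f2 = (positions[:, 1] - grid.extent_lo[1]) / grid.dx2 - 0.5
    i0 = np.floor(f1).astype(np.int64)
    j0 = np.floor(f2).astype(np.int64)
    if (np.any(i0 - 1 < 0) or np.any(i0 + 2 >= grid.n1)
            or np.any(j0 - 1 < 0) or np.any(j0 + 2 >= grid.n2)):
        raise DomainOverflowError(
            "a Lagrangian position is within kernel support of the ghost-box edge")
    offs = np.arange(-1, 3)
    ii = i0[:, None] + offs[None, :]              # (npos, 4)
    jj = j0[:, None] + offs[None, :]
    w1 = psi(ii - f1[:, None])                    # (npos, 4)
    w2 = psi(jj - f2[:, None])
    w = (w1[:, :, None] * w2[:, None, :]).reshape(npos, 16)
    cells = (ii[:, :, None] * grid.n2 + jj[:, None, :]).reshape(npos, 16)
    cols = np.repeat(np.arange(npos), 16)
    D = sp.csr_matrix((w.ravel(), (cells.ravel(), cols)),
                      shape=(grid.n1 * grid.n2, npos))
    return D


class TransferMaps:
    """Cached sparse spreading/interpolation stencils for one structure
    configuration.

    For a stationary structure the maps are assembled once and reused every
    step; for a moving structure :meth:`rebuild` is called after each motion
    update.  Using the assembled sparse maps is bit-identical to direct
    summation of the defining formulas (it *is* the same sum, reordered by
    CSR row).
    """

    def __init__(self, grid: CartesianGrid, mesh: LagrangianMesh,
                 lumped_mass: bool = False):
        self.grid = grid
        self.mesh = mesh
        self.lumped_mass = lumped_mass
        self.rebuild()

    def rebuild(self) -> None:
        """Reassemble the kernel stencils (and the mass solve) at the
        current configuration.  Quadrature weights are current-configuration
        weights so spreading preserves densities pointwise under motion;
        they coincide with the material weights while the structure is
        undeformed."""
        self.weights = self.mesh.current_quad_weights()
        M = self.mesh.mass_matrix(lumped=self.lumped_mass,
                                  weights=self.weights).tocsc()
        try:
            self._mass_lu = spla.splu(M)
        except RuntimeError as exc:
            raise NumericalError(f"singular Lagrangian mass matrix: {exc}") from exc
        D = _kernel_matrix(self.grid, self.mesh.quad_current)
        self._kernel = D                        # (n_cells, nq) raw psi weights
        # interpolation weights: D^T * dx1dx2 * (1/dx1dx2 from delta_h) = D^T
        self._interp = sp.csr_matrix(D.T)
        self.support_cells = np.flatnonzero(
            np.diff(D.indptr) > 0)              # cells within kernel reach

    # -- operations ---------------------------------------------------------
    def spread(self, quad_values: np.ndarray) -> np.ndarray:
        """Eq.-26 spreading of quadrature values to the grid (flat values).

        Evaluated as D @ (w * q) / (dx1 dx2), the same association as the
        one-shot :func:`spread`, so cached and direct results are
        bit-identical.
        """
        q = self.weights * np.asarray(quad_values, dtype=float)
        return (self._kernel @ q) / self.grid.cell_area

    def interpolate(self, cell_values: np.ndarray) -> np.ndarray:
        """Eq.-27 interpolation of a cell-centered field to quadrature points."""
        return self._interp @ np.asarray(cell_values, dtype=float).ravel()

    def project_to_nodes(self, quad_values: np.ndarray) -> np.ndarray:
        """L^2 projection of quadrature-point values onto the P1 nodal basis."""
        b = self.mesh.basis.T @ (self.weights * np.asarray(quad_values, dtype=float))
        return self._mass_lu.solve(b)


# ---------------------------------------------------------------------------
# One-shot functional forms (assemble, apply, discard)
# ---------------------------------------------------------------------------

def spread(quad_values: np.ndarray, mesh: LagrangianMesh,
           grid: CartesianGrid) -> EulerianField:
    """Spread quadrature-point values to an Eulerian field.

    Each quadrature point contributes ``value * weight * delta_h`` to the
    <=16 surrounding cell centers.
    """
    D = _kernel_matrix(grid, mesh.quad_current)
    vals = D @ (mesh.current_quad_weights() * np.asarray(quad_values, dtype=float))
    return EulerianField(grid, (vals / grid.cell_area).reshape(grid.shape))


def interpolate(field: EulerianField, positions: np.ndarray) -> np.ndarray:
    """Interpolate a cell-centered field at arbitrary interior positions."""
    D = _kernel_matrix(field.grid, positions)
    return D.T @ field.values.ravel()


def project_to_nodes(quad_values: np.ndarray, mesh: LagrangianMesh,
                     lumped: bool = False) -> np.ndarray:
    """Solve M c = b for nodal values c, with the quadrature-consistent mass
    matrix M and b_l = sum_Q phi_l(X_Q) value_Q w_Q."""
    M = mesh.mass_matrix(lumped=lumped).tocsc()
    b = mesh.basis.T @ (mesh.quad_weights * np.asarray(quad_values, dtype=float))
    try:
        return spla.splu(M).solve(b)
    except RuntimeError as exc:
        raise NumericalError(f"singular Lagrangian mass matrix: {exc}") from exc
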