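"""Regular Cartesian ghost-box grid and staggered finite-difference operators.

The ghost-structure method embeds the (possibly irregular, possibly moving)
tissue region in a regular rectangular "ghost" box.  The transmembrane
potential lives at cell centers of this box; the anisotropic diffusion term
is discretized with the usual staggered-flux second difference, which for
constant axis-aligned conductivities collapses to the 5-point stencil

    sigma_l (V[i+1,j] - 2 V[i,j] + V[i-1,j]) / dx1^2
  + sigma_t (V[i,j+1] - 2 V[i,j] + V[i,j-1]) / dx2^2 .

The one-cell ring outside the box carries homogeneous Dirichlet values fixed
at the cell model's resting potential (0 for the normalized FitzHugh-Nagumo
benchmarks), which keeps the stencil uniform up to the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ContractViolation

__all__ = [
    "CartesianGrid",
    "EulerianField",
    "ConductivityTensor",
    "build_grid",
    "anisotropic_laplacian",
]


@dataclass(frozen=True)
class CartesianGrid:
    """Uniform cell-centered Cartesian grid on the box [lo, hi].

    Cell center (i, j) sits at ``lo + ((i + 1/2) dx1, (j + 1/2) dx2)`` for
    ``0 <= i < n1``, ``0 <= j < n2``.  Arrays indexed ``[i, j]`` with axis 0
    along x1.
    """

    extent_lo: tuple[float, float]
    extent_hi: tuple[float, float]
    n1: int
    n2: int

    @property
    def dx1(self) -> float:
        return (self.extent_hi[0] - self.extent_lo[0]) / self.n1

    @property
    def dx2(self) -> float:
        return (self.extent_hi[1] - self.extent_lo[1]) / self.n2

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n1, self.n2)

    @property
    def cell_area(self) -> float:
        return self.dx1 * self.dx2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1-D arrays of cell-center coordinates along each axis."""
        x1 = self.extent_lo[0] + (np.arange(self.n1) + 0.5) * self.dx1
        x2 = self.extent_lo[1] + (np.arange(self.n2) + 0.5) * self.dx2
        return x1, x2

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        x1, x2 = self.cell_centers()
        return np.meshgrid(x1, x2, indexing="ij")


def build_grid(extent: tuple[tuple[float, float], tuple[float, float]],
               n1: int, n2: int) -> CartesianGrid:
    """Build the ghost-box grid from a physical extent and cell counts.

    ``extent`` is per-axis ranges ``((lo1, hi1), (lo2, hi2))``.
    """
    (lo1, hi1), (lo2, hi2) = extent
    if n1 < 4 or n2 < 4:
        raise ConfigurationError(f"grid needs at least 4 cells per axis, got {n1}x{n2}")
    if not (hi1 > lo1 and hi2 > lo2):
        raise ConfigurationError(f"inverted or degenerate extent {extent}")
    return CartesianGrid((float(lo1), float(lo2)), (float(hi1), float(hi2)),
                         int(n1), int(n2))


@dataclass
class EulerianField:
    """Scalar field at cell centers of a :class:`CartesianGrid`."""

    grid: CartesianGrid
    values: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.values is None:
            self.values = np.zeros(self.grid.shape)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ContractViolation(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}")

    def copy(self) -> "EulerianField":
        return EulerianField(self.grid, self.values.copy())


@dataclass(frozen=True)
class ConductivityTensor:
    """Axis-aligned intra-/extracellular conductivities (S/m).

    The monodomain reduction uses the per-direction harmonic combination
    ``sigma_mono = sigma_i * sigma_e / (sigma_i + sigma_e)``, which reduces
    exactly to ``(lambda/(1+lambda)) * sigma_i`` under the equal-anisotropy
    assumption ``sigma_e = lambda * sigma_i``.  Human-ventricle measurements
    (e.g. the Potse values) violate equal anisotropy, so the per-direction
    combination is what actually gets used.
    """

    sigma_i_l: float
    sigma_i_t: float
    sigma_e_l: float
    sigma_e_t: float

    def __post_init__(self):
        for name in ("sigma_i_l", "sigma_i_t", "sigma_e_l", "sigma_e_t"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"conductivity {name} must be > 0")

    @classmethod
    def from_lambda(cls, sigma_i_l: float, sigma_i_t: float,
                    lambda_ratio: float) -> "ConductivityTensor":
        """Equal-anisotropy tensor with sigma_e = lambda * sigma_i."""
        return cls(sigma_i_l, sigma_i_t,
                   lambda_ratio * sigma_i_l, lambda_ratio * sigma_i_t)

    @classmethod
    def potse(cls) -> "ConductivityTensor":
        """Human-ventricle conductivities measured by Potse et al. (S/m)."""
        return cls(sigma_i_l=0.3, sigma_i_t=0.03, sigma_e_l=0.3, sigma_e_t=0.12)

    @property
    def mono_l(self) -> float:
        return self.sigma_i_l * self.sigma_e_l / (self.sigma_i_l + self.sigma_e_l)

    @property
    def mono_t(self) -> float:
        return self.sigma_i_t * self.sigma_e_t / (self.sigma_i_t + self.sigma_e_t)


def laplacian_values(values: np.ndarray, grid: CartesianGrid,
                     sigma_l: float, sigma_t: float,
                     boundary_value: float = 0.0) -> np.ndarray:
    """5-point anisotropic Laplacian on raw cell values (array fast path).

    Cells adjacent to the box boundary see a Dirichlet ghost ring fixed at
    ``boundary_value``.
    """
    p = np.pad(values, 1, constant_values=boundary_value)
    out = sigma_l * (p[2:, 1:-1] - 2.0 * values + p[:-2, 1:-1]) / grid.dx1 ** 2
    out += sigma_t * (p[1:-1, 2:] - 2.0 * values + p[1:-1, :-2]) / grid.dx2 ** 2
    return out


def anisotropic_laplacian(field: EulerianField, cond, *,
                          boundary_value: float = 0.0) -> EulerianField:
    """div(sigma grad V) with constant axis-aligned conductivities.

    ``cond`` is either a ``(sigma_l, sigma_t)`` pair of effective (monodomain)
    conductivities or a :class:`ConductivityTensor`, in which case the
    per-direction monodomain combination is applied.
    """
    if isinstance(cond, ConductivityTensor):
        sigma_l, sigma_t = cond.mono_l, cond.mono_t
    else:
        sigma_l, sigma_t = cond
    vals = laplacian_values(field.values, field.grid, sigma_l, sigma_t,
                            boundary_value=boundary_value)
    return EulerianField(field.grid, vals)
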