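"""Snapshot, trace, and mesh readers/writers.

Eulerian snapshots go out as legacy-VTK structured-points ASCII files (one
scalar per cell center) and, in parallel, as raw little-endian float64
arrays with a JSON header sidecar.  All floating-point text uses %.17g so a
write/read round trip is bit-identical at 64-bit precision.  Meshes use a
simple whitespace node/element format; Gmsh MSH v2 ASCII import is also
supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .grid import CartesianGrid, build_grid
from .mesh import LagrangianMesh

__all__ = [
    "write_vtk_structured_points", "read_vtk_structured_points",
    "write_raw_field", "read_raw_field", "write_snapshot", "read_snapshot",
    "write_probe_csv", "write_mesh_text", "read_mesh_text", "read_gmsh_msh",
]

_FMT = "%.17g"


def write_vtk_structured_points(path, values: np.ndarray, grid: CartesianGrid,
                                name: str = "V") -> None:
    """Legacy-VTK structured-points file with one cell-centered scalar.

    The data are exported as POINT_DATA on the lattice of cell centers
    (origin at the first cell center), which every VTK reader displays
    without cell/point juggling.
    """
    v = np.asarray(values)
    if v.shape != grid.shape:
        raise ConfigurationError(f"values shape {v.shape} != grid {grid.shape}")
    x1, x2 = grid.cell_centers()
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("gsmono field\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {grid.n1} {grid.n2} 1\n")
        f.write(f"ORIGIN {_FMT % x1[0]} {_FMT % x2[0]} 0\n")
        f.write(f"SPACING {_FMT % grid.dx1} {_FMT % grid.dx2} 1\n")
        f.write(f"POINT_DATA {grid.n1 * grid.n2}\n")
        f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        # VTK varies x fastest: write Fortran order of [i, j]
        np.savetxt(f, v.reshape(-1, order="F"), fmt=_FMT)


def read_vtk_structured_points(path):
    """Read back a file written by :func:`write_vtk_structured_points`.

    Returns ``(values, grid)``.
    """
    with open(path) as f:
        lines = f.read().splitlines()
    hdr = {ln.split()[0]: ln.split()[1:] for ln in lines[:9] if ln and ln[0].isalpha()}
    n1, n2, _ = (int(x) for x in hdr["DIMENSIONS"])
    ox, oy, _ = (float(x) for x in hdr["ORIGIN"])
    dx, dy, _ = (float(x) for x in hdr["SPACING"])
    start = next(i for i, ln in enumerate(lines) if ln.startswith("LOOKUP_TABLE")) + 1
    vals = np.array([float(x) for x in lines[start:start + n1 * n2]])
    grid = build_grid(((ox - dx / 2, ox - dx / 2 + n1 * dx),
                       (oy - dy / 2, oy - dy / 2 + n2 * dy)), n1, n2)
    return vals.reshape((n1, n2), order="F"), grid


def write_raw_field(path, values: np.ndarray, grid: CartesianGrid,
                    t: float = 0.0) -> None:
    """Raw little-endian float64 array plus a JSON sidecar (<path>.json)."""
    v = np.ascontiguousarray(values, dtype="<f8")
    v.tofile(path)
    meta = {"shape": list(v.shape), "dtype": "<f8", "order": "C", "t": t,
            "extent_lo": list(grid.extent_lo), "extent_hi": list(grid.extent_hi),
            "n1": grid.n1, "n2": grid.n2}
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def read_raw_field(path):
    meta = json.loads(Path(str(path) + ".json").read_text())
    v = np.fromfile(path, dtype=meta["dtype"]).reshape(meta["shape"])
    grid = build_grid(((meta["extent_lo"][0], meta["extent_hi"][0]),
                       (meta["extent_lo"][1], meta["extent_hi"][1])),
                      meta["n1"], meta["n2"])
    return v, grid, meta["t"]


def write_snapshot(values: np.ndarray, mesh: LagrangianMesh | None,
                   t: float, out_dir, grid: CartesianGrid,
                   step_index: int = 0) -> list[str]:
    """Write one time level: VTK field + raw field + mesh current positions.

    Filenames embed the zero-padded step index.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"{step_index:08d}"
    files = []
    p = out / f"V_{tag}.vtk"
    write_vtk_structured_points(p, values, grid)
    files.append(str(p))
    p = out / f"V_{tag}.bin"
    write_raw_field(p, values, grid, t=t)
    files.append(str(p))
    if mesh is not None:
        p = out / f"mesh_{tag}.txt"
        write_mesh_text(p, mesh, current=True, t=t)
        files.append(str(p))
    return files


def read_snapshot(out_dir, step_index: int):
    return read_raw_field(Path(out_dir) / f"V_{step_index:08d}.bin")


def write_probe_csv(path, times: np.ndarray, V: np.ndarray,
                    observables: dict | None = None,
                    probe_names: list[str] | None = None) -> None:
    """Per-step probe traces as CSV: time, then V (and each observable) per
    probe, with fixed repeatable formatting."""
    V = np.atleast_2d(np.asarray(V))
    if V.shape[0] != len(times):
        V = V.T
    npr = V.shape[1]
    names = probe_names or [f"p{k}" for k in range(npr)]
    cols = [f"V[{n}]" for n in names]
    data = [V]
    for oname, ov in (observables or {}).items():
        ov = np.atleast_2d(np.asarray(ov))
        if ov.shape[0] != len(times):
            ov = ov.T
        cols += [f"{oname}[{n}]" for n in names]
        data.append(ov)
    M = np.column_stack([np.asarray(times)] + [d for d in data])
    header = ",".join(["t"] + cols)
    np.savetxt(path, M, fmt=_FMT, delimiter=",", header=header, comments="")


# ---------------------------------------------------------------------------
# Mesh formats
# ---------------------------------------------------------------------------

def write_mesh_text(path, mesh: LagrangianMesh, current: bool = False,
                    t: float | None = None) -> None:
    """Whitespace node/element format::

        # gsmono mesh v1 [t=<time>]
        <n_nodes> <n_elements>
        x y          (one line per node)
        i j k        (0-based node indices per triangle)
    """
    pos = mesh.current_positions if current else mesh.nodes
    with open(path, "w") as f:
        f.write("# gsmono mesh v1" + (f" t={_FMT % t}" if t is not None else "") + "\n")
        f.write(f"{mesh.n_nodes} {len(mesh.elements)}\n")
        np.savetxt(f, pos, fmt=_FMT)
        np.savetxt(f, mesh.elements, fmt="%d")


def read_mesh_text(path, rule_order: int = 2) -> LagrangianMesh:
    with open(path) as f:
        lines = [ln for ln in f.read().splitlines() if ln and not ln.startswith("#")]
    n, e = (int(x) for x in lines[0].split())
    nodes = np.array([[float(x) for x in ln.split()] for ln in lines[1:1 + n]])
    elements = np.array([[int(x) for x in ln.split()] for ln in lines[1 + n:1 + n + e]])
    return LagrangianMesh(nodes, elements, rule_order=rule_order)


def read_gmsh_msh(path, rule_order: int = 2) -> LagrangianMesh:
    """Minimal Gmsh MSH 2.2 ASCII reader (triangles only)."""
    text = Path(path).read_text().splitlines()
    nodes, tris = None, []
    i = 0
    while i < len(text):
        ln = text[i].strip()
        if ln == "$Nodes":
            count = int(text[i + 1])
            raw = [text[i + 2 + k].split() for k in range(count)]
            ids = [int(r[0]) for r in raw]
            xy = np.array([[float(r[1]), float(r[2])] for r in raw])
            id2idx = {nid: k for k, nid in enumerate(ids)}
            nodes = xy
            i += 2 + count
        elif ln == "$Elements":
            count = int(text[i + 1])
            for k in range(count):
                r = text[i + 2 + k].split()
                etype, ntags = int(r[1]), int(r[2])
                if etype == 2:  # 3-node triangle
                    conn = [int(x) for x in r[3 + ntags:6 + ntags]]
                    tris.append([id2idx[c] for c in conn])
            i += 2 + count
        else:
            i += 1
    if nodes is None or not tris:
        raise ConfigurationError(f"{path}: no nodes/triangles found (MSH 2.2 ASCII expected)")
    used = np.unique(np.asarray(tris))
    remap = {int(u): k for k, u in enumerate(used)}
    elements = np.array([[remap[c] for c in tr] for tr in tris])
    return LagrangianMesh(nodes[used], elements, rule_order=rule_order)
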