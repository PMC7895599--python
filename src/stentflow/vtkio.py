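"""Minimal legacy-VTK (ASCII) writers and a point-cloud reader.

Covers exactly what the simulator exports: platelet point clouds with scalar
labels, cell-centered flow fields on the structured grid, and the staircase
solid surface as quads.  Files are plain text and readable by ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_polydata_points(path, points: np.ndarray, scalars: dict | None = None) -> None:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    n = points.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentflow platelet snapshot\n"
                 "ASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {n} float\n")
        for p in points:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"VERTICES {n} {2 * n}\n")
        for i in range(n):
            fh.write(f"1 {i}\n")
        if scalars:
            fh.write(f"POINT_DATA {n}\n")
            for name, arr in scalars.items():
                arr = np.asarray(arr, dtype=float)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    fh.write(f"{v:.9g}\n")


def read_polydata_points(path):
    """Parse points + scalar arrays back from :func:`write_polydata_points`."""
    lines = Path(path).read_text().splitlines()
    i = 0
    points = None
    scalars = {}
    while i < len(lines):
        tok = lines[i].split()
        if tok and tok[0] == "POINTS":
            n = int(tok[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if tok and tok[0] == "SCALARS":
            name = tok[1]
            n = points.shape[0]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n:
                vals.extend(float(x) for x in lines[i].split())
                i += 1
            scalars[name] = np.array(vals)
            continue
        i += 1
    return points, scalars


def write_structured_flow(path, flow) -> None:
    """Cell-centered velocity, pressure and solid mask on the grid."""
    g = flow.grid
    nx, ny, nz = g.shape
    uc = flow.u if nx == 1 else 0.5 * (flow.u + np.roll(flow.u, -1, axis=0))
    vc = 0.5 * (flow.v[:, :-1, :] + flow.v[:, 1:, :])
    wc = 0.5 * (flow.w[:, :, :-1] + flow.w[:, :, 1:])
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentflow flow field\nASCII\n"
                 "DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {g.x0 + g.h / 2:.9g} {g.y0 + g.h / 2:.9g} {g.z0 + g.h / 2:.9g}\n")
        fh.write(f"SPACING {g.h:.9g} {g.h:.9g} {g.h:.9g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("VECTORS velocity float\n")
        # VTK structured order: x fastest
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{uc[i, j, k]:.6g} {vc[i, j, k]:.6g} {wc[i, j, k]:.6g}\n")
        fh.write("SCALARS solid float 1\nLOOKUP_TABLE default\n")
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    fh.write(f"{float(flow.solid[i, j, k]):.0f}\n")


def write_mask_surface(path, solid: np.ndarray, grid) -> None:
    """Staircase solid/fluid interface as VTK quads (visual inspection)."""
    nx, ny, nz = solid.shape
    h = grid.h
    verts = {}
    quads = []

    def vid(i, j, k):
        key = (i, j, k)
        if key not in verts:
            verts[key] = len(verts)
        return verts[key]

    def add_quad(corners):
        quads.append([vid(*c) for c in corners])

    sol = np.pad(solid, 1, constant_values=False)
    core = sol[1:-1, 1:-1, 1:-1]
    for axis, make in ((2, "z"), (1, "y"), (0, "x")):
        lo = np.roll(sol, 1, axis=axis)[1:-1, 1:-1, 1:-1]
        hi = np.roll(sol, -1, axis=axis)[1:-1, 1:-1, 1:-1]
        for ii, jj, kk in zip(*np.nonzero(core & ~hi)):
            _emit_face(add_quad, ii, jj, kk, axis, +1)
        for ii, jj, kk in zip(*np.nonzero(core & ~lo)):
            _emit_face(add_quad, ii, jj, kk, axis, -1)
    order = sorted(verts, key=verts.get)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nstentflow solid surface\nASCII\n"
                 "DATASET POLYDATA\n")
        fh.write(f"POINTS {len(order)} float\n")
        for (i, j, k) in order:
            fh.write(f"{grid.x0 + i * h:.9g} {grid.y0 + j * h:.9g} {grid.z0 + k * h:.9g}\n")
        fh.write(f"POLYGONS {len(quads)} {5 * len(quads)}\n")
        for q in quads:
            fh.write("4 " + " ".join(str(v) for v in q) + "\n")


def _emit_face(add_quad, i, j, k, axis, sign):
    if axis == 0:
        x = i + (1 if sign > 0 else 0)
        add_quad([(x, j, k), (x, j + 1, k), (x, j + 1, k + 1), (x, j, k + 1)])
    elif axis == 1:
        y = j + (1 if sign > 0 else 0)
        add_quad([(i, y, k), (i + 1, y, k), (i + 1, y, k + 1), (i, y, k + 1)])
    else:
        z = k + (1 if sign > 0 else 0)
        add_quad([(i, j, z), (i + 1, j, z), (i + 1, j + 1, z), (i, j + 1, z)])


def write_vz_map_csv(path, y: np.ndarray, vz: np.ndarray,
                     x: np.ndarray | None = None) -> None:
    """Vz map as a CSV matrix with axis coordinate headers."""
    vz = np.atleast_2d(vz)
    with open(path, "w") as fh:
        fh.write("y_mm," + ",".join(f"{v:.6g}" for v in y) + "\n")
        if x is None:
            x = np.arange(vz.shape[0], dtype=float)
        for xi, row in zip(x, vz):
            fh.write(f"{xi:.6g}," + ",".join(f"{v:.6g}" for v in row) + "\n")
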