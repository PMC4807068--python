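"""Plain-text export: legacy-VTK meshes/fields, ASCII STL boundaries, CSV tables."""

from __future__ import annotations

import numpy as np

from .geometry import PassageGeometry, StructuredMesh

__all__ = ["write_vtk", "write_stl", "write_streamlines_vtk"]


def write_vtk(path, mesh: StructuredMesh, cell_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh and per-cell arrays as a legacy-VTK (ASCII) unstructured grid.

    Scalar arrays have shape (n_cells,), vector arrays (n_cells, 2) and are
    padded with a zero z component.
    """
    nodes = mesh.nodes.reshape(-1, 2)
    npts = len(nodes)
    ni, nj = mesh.ns + 1, mesh.nn + 1
    nid = np.arange(npts).reshape(ni, nj)
    quads = np.stack(
        [nid[:-1, :-1], nid[1:, :-1], nid[1:, 1:], nid[:-1, 1:]], axis=2
    ).reshape(-1, 4)

    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nnasocond field export\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {npts} double\n")
        for x, y in nodes:
            fh.write(f"{x:.9e} {y:.9e} 0.0\n")
        fh.write(f"CELLS {len(quads)} {len(quads) * 5}\n")
        for q in quads:
            fh.write(f"4 {q[0]} {q[1]} {q[2]} {q[3]}\n")
        fh.write(f"CELL_TYPES {len(quads)}\n")
        fh.write("9\n" * len(quads))
        if cell_data:
            fh.write(f"CELL_DATA {len(quads)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.9e}" for v in arr) + "\n")
                else:
                    fh.write(f"VECTORS {name} double\n")
                    for row in arr:
                        fh.write(f"{row[0]:.9e} {row[1]:.9e} 0.0\n")


def write_stl(path, geometry: PassageGeometry, depth_mm: float = 1.0) -> None:
    """Write the passage boundary as an ASCII STL surface.

    The planar boundary polylines (walls, inlet, outlet) are extruded by
    ``depth_mm`` in z so standard surface viewers accept the file."""
    lower, upper = geometry.boundary_polylines()
    loop = np.vstack([lower, upper[::-1], lower[:1]])

    def tri(fh, a, b, c):
        u, v = np.subtract(b, a), np.subtract(c, a)
        n = np.cross(u, v)
        norm = np.linalg.norm(n)
        if norm == 0.0:
            return
        n = n / norm
        fh.write(f"  facet normal {n[0]:.6e} {n[1]:.6e} {n[2]:.6e}\n    outer loop\n")
        for p in (a, b, c):
            fh.write(f"      vertex {p[0]:.6e} {p[1]:.6e} {p[2]:.6e}\n")
        fh.write("    endloop\n  endfacet\n")

    with open(path, "w") as fh:
        fh.write("solid nasocond_passage\n")
        for p0, p1 in zip(loop[:-1], loop[1:]):
            a = (p0[0], p0[1], 0.0)
            b = (p1[0], p1[1], 0.0)
            c = (p1[0], p1[1], depth_mm)
            d = (p0[0], p0[1], depth_mm)
            tri(fh, a, b, c)
            tri(fh, a, c, d)
        fh.write("endsolid nasocond_passage\n")


def write_streamlines_vtk(path, streamlines: list[np.ndarray]) -> None:
    """Write a streamline bundle as legacy-VTK polylines."""
    npts = sum(len(line) for line in streamlines)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nnasocond streamlines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {npts} double\n")
        for line in streamlines:
            for x, y in line:
                fh.write(f"{x:.9e} {y:.9e} 0.0\n")
        size = sum(len(line) + 1 for line in streamlines)
        fh.write(f"LINES {len(streamlines)} {size}\n")
        offset = 0
        for line in streamlines:
            ids = " ".join(str(offset + i) for i in range(len(line)))
            fh.write(f"{len(line)} {ids}\n")
            offset += len(line)
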