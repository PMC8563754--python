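"""Minimal legacy-ASCII VTK writers for grid fields and network polylines.

Only the two output shapes this package produces are supported: 2-D
cell-centered scalar fields on the square tissue grid (STRUCTURED_POINTS
with CELL_DATA) and the vascular network as POLYDATA line segments with
per-segment attributes.  Files are plain text and loadable by ParaView.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_structured_grid", "write_network_polydata"]


def write_structured_grid(path, fields: dict, h: float) -> None:
    """Write cell-centered scalar fields (all shape (n, n)) as legacy VTK."""
    if not fields:
        raise ValueError("no fields to write")
    shapes = {np.asarray(f).shape for f in fields.values()}
    if len(shapes) != 1:
        raise ValueError("all fields must share one shape")
    (n, m) = shapes.pop()
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nchemocycle grid fields\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {n + 1} {m + 1} 1\n")
        f.write("ORIGIN 0 0 0\n")
        f.write(f"SPACING {h!r} {h!r} {h!r}\n")
        f.write(f"CELL_DATA {n * m}\n")
        for name, arr in fields.items():
            a = np.asarray(arr, dtype=float)
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            # VTK expects x varying fastest: transpose the [ix, iy] layout
            f.write("\n".join(repr(float(v)) for v in a.T.ravel()))
            f.write("\n")


def write_network_polydata(path, network) -> None:
    """Write the network geometry (and solution, if solved) as VTK polydata."""
    pos = network.positions
    edges = network.edges
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nchemocycle vascular network\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {pos.shape[0]} double\n")
        for x, y in pos:
            f.write(f"{x!r} {y!r} 0.0\n")
        f.write(f"LINES {edges.shape[0]} {3 * edges.shape[0]}\n")
        for a, b in edges:
            f.write(f"2 {a} {b}\n")
        f.write(f"CELL_DATA {edges.shape[0]}\n")
        f.write("SCALARS diameter_um double 1\nLOOKUP_TABLE default\n")
        for d in network.diam_um:
            f.write(f"{float(d)!r}\n")
        if network.segment_flow is not None:
            f.write("SCALARS flow_m3_s double 1\nLOOKUP_TABLE default\n")
            for q in network.segment_flow:
                f.write(f"{float(q)!r}\n")
            f.write("SCALARS velocity_m_s double 1\nLOOKUP_TABLE default\n")
            for v in network.mean_velocities():
                f.write(f"{float(v)!r}\n")
        if network.node_pressure is not None:
            f.write(f"POINT_DATA {pos.shape[0]}\n")
            f.write("SCALARS pressure_pa double 1\nLOOKUP_TABLE default\n")
            for p_ in network.node_pressure:
                f.write(f"{float(p_)!r}\n")
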