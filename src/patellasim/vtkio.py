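"""Output writers: legacy-ASCII VTK unstructured grids and CSV tables.

Legacy VTK (version 2.0, ASCII) is used for all field output because it is
plain text, diffable, and readable by ParaView and friends without extra
dependencies.  Scalars are written as one POINT_DATA/CELL_DATA array per
field; 2D vectors are padded to three components.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .geometry import QuadMesh

__all__ = ["write_vtk", "write_element_csv", "write_events_csv"]


def _format_array(f, name: str, values: np.ndarray) -> None:
    values = np.asarray(values)
    if values.ndim == 1:
        f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
        for v in values:
            f.write(f"{v:.9g}\n")
    elif values.ndim == 2 and values.shape[1] == 2:
        f.write(f"VECTORS {name} double\n")
        for vx, vy in values:
            f.write(f"{vx:.9g} {vy:.9g} 0\n")
    else:
        raise ValueError(f"unsupported field shape {values.shape} for {name!r}")


def write_vtk(
    path: str | Path,
    mesh: QuadMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "patellasim output (units: mm, MPa, ng/ml)",
) -> Path:
    """Write the mesh and fields to a legacy ASCII VTK unstructured grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 2.0\n")
        f.write(title[:255] + "\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.nodes:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        E = mesh.n_elements
        f.write(f"CELLS {E} {5 * E}\n")
        for conn in mesh.elements:
            f.write("4 " + " ".join(str(int(n)) for n in conn) + "\n")
        f.write(f"CELL_TYPES {E}\n")
        f.write("9\n" * E)  # VTK_QUAD
        point_data = dict(point_data or {})
        # boundary tags as 0/1 point masks for inspection
        for tag, nodes in mesh.boundary_tags.items():
            marker = np.zeros(mesh.n_nodes)
            marker[nodes] = 1.0
            point_data.setdefault(f"tag_{tag}", marker)
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                _format_array(f, name, values)
        cell_data = dict(cell_data or {})
        cell_data.setdefault("region", mesh.element_region.astype(float))
        f.write(f"CELL_DATA {E}\n")
        for name, values in cell_data.items():
            _format_array(f, name, values)
    return path


def write_element_csv(
    path: str | Path, mesh: QuadMesh, columns: dict[str, np.ndarray]
) -> Path:
    """Per-element CSV: element id, region, centroid, then given columns."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cent = mesh.element_centroids()
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(
            ["element", "region", "cx_mm", "cy_mm", *columns.keys()]
        )
        for e in range(mesh.n_elements):
            writer.writerow(
                [
                    e,
                    int(mesh.element_region[e]),
                    f"{cent[e, 0]:.9g}",
                    f"{cent[e, 1]:.9g}",
                    *(f"{np.asarray(v)[e]:.9g}" for v in columns.values()),
                ]
            )
    return path


def write_events_csv(path: str | Path, events: dict[str, float]) -> Path:
    """Event log as (event, time) rows sorted by time."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["event", "time"])
        for name, t in sorted(events.items(), key=lambda kv: kv[1]):
            writer.writerow([name, f"{t:.9g}"])
    return path
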