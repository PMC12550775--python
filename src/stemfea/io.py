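"""Lightweight result export: VTU (XML unstructured grid, ASCII) meshes with
point/cell data, for inspection in ParaView or any VTK-based viewer."""

from __future__ import annotations

import numpy as np

from .meshing import FEMesh

__all__ = ["write_vtu"]

_VTK_QUADRATIC_TETRA = 24


def _array_block(name: str, data: np.ndarray, indent: str) -> str:
    data = np.asarray(data)
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    if np.issubdtype(data.dtype, np.integer):
        dtype, fmt = "Int64", "%d"
    else:
        dtype, fmt = "Float64", "%.10g"
    body = "\n".join(indent + " ".join(fmt % v for v in np.atleast_1d(row))
                     for row in data)
    return (f'{indent}<DataArray type="{dtype}" Name="{name}" '
            f'NumberOfComponents="{ncomp}" format="ascii">\n'
            f"{body}\n{indent}</DataArray>\n")


def write_vtu(path, mesh: FEMesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """Write the TET10 mesh and optional data arrays to a .vtu file."""
    n, m = mesh.n_nodes, mesh.n_elements
    ind = "      "
    parts = ['<?xml version="1.0"?>\n',
             '<VTKFile type="UnstructuredGrid" version="0.1" '
             'byte_order="LittleEndian">\n',
             '  <UnstructuredGrid>\n',
             f'    <Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n']
    parts.append("      <Points>\n")
    parts.append(_array_block("Points", mesh.nodes, ind))
    parts.append("      </Points>\n      <Cells>\n")
    parts.append(_array_block("connectivity", mesh.elements.ravel(), ind))
    parts.append(_array_block("offsets", 10 * np.arange(1, m + 1), ind))
    parts.append(_array_block("types",
                              np.full(m, _VTK_QUADRATIC_TETRA, dtype=np.int64),
                              ind))
    parts.append("      </Cells>\n")
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", mesh.regions.astype(np.int64))
    parts.append("      <CellData>\n")
    for name, arr in cell_data.items():
        parts.append(_array_block(name, np.asarray(arr), ind))
    parts.append("      </CellData>\n")
    if point_data:
        parts.append("      <PointData>\n")
        for name, arr in point_data.items():
            parts.append(_array_block(name, np.asarray(arr), ind))
        parts.append("      </PointData>\n")
    parts.append("    </Piece>\n  </UnstructuredGrid>\n</VTKFile>\n")
    with open(path, "w") as fh:
        fh.write("".join(parts))
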