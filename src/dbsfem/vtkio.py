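"""Minimal ASCII VTU writers for meshes and probe point clouds.

Plain-text XML UnstructuredGrid files readable by ParaView/VTK; enough to
inspect potentials, fields and activation point clouds without a VTK
dependency.
"""

from __future__ import annotations

import numpy as np


def _data_array(name: str, data: np.ndarray, n_comp: int = 1) -> str:
    flat = np.asarray(data).reshape(-1)
    body = " ".join(f"{v:.7g}" for v in flat)
    return (f'<DataArray type="Float64" Name="{name}" '
            f'NumberOfComponents="{n_comp}" format="ascii">{body}</DataArray>')


def write_vtu_points(path: str, points: np.ndarray,
                     point_data: dict | None = None) -> None:
    """Point cloud as VTK_VERTEX cells with attached scalar/vector data."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    pieces = [f'<Piece NumberOfPoints="{n}" NumberOfCells="{n}">']
    pieces.append("<Points>" + _data_array("points", points, 3) + "</Points>")
    if point_data:
        pieces.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            pieces.append(_data_array(name, arr, nc))
        pieces.append("</PointData>")
    conn = " ".join(str(i) for i in range(n))
    offs = " ".join(str(i + 1) for i in range(n))
    types = " ".join("1" for _ in range(n))
    pieces.append('<Cells>'
                  f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>'
                  f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>'
                  f'<DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>'
                  '</Cells>')
    pieces.append("</Piece>")
    _write(path, "".join(pieces))


def write_vtu_hex_grid(path: str, mesh, point_data: dict | None = None,
                       cell_data: dict | None = None) -> None:
    """Rectilinear hexahedral mesh as VTK_HEXAHEDRON cells."""
    pts = mesh.node_points()
    en = mesh.elem_nodes()
    # VTK hexahedron ordering from the (a, b, c)-offset local ordering
    vtk_order = [0, 4, 6, 2, 1, 5, 7, 3]
    cells = en[:, vtk_order]
    n, ne = len(pts), len(cells)
    pieces = [f'<Piece NumberOfPoints="{n}" NumberOfCells="{ne}">']
    pieces.append("<Points>" + _data_array("points", pts, 3) + "</Points>")
    if point_data:
        pieces.append("<PointData>")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            nc = 1 if arr.ndim == 1 else arr.shape[1]
            pieces.append(_data_array(name, arr, nc))
        pieces.append("</PointData>")
    if cell_data:
        pieces.append("<CellData>")
        for name, arr in cell_data.items():
            pieces.append(_data_array(name, np.asarray(arr, dtype=float), 1))
        pieces.append("</CellData>")
    conn = " ".join(str(i) for i in cells.reshape(-1))
    offs = " ".join(str(8 * (i + 1)) for i in range(ne))
    types = " ".join("12" for _ in range(ne))
    pieces.append('<Cells>'
                  f'<DataArray type="Int64" Name="connectivity" format="ascii">{conn}</DataArray>'
                  f'<DataArray type="Int64" Name="offsets" format="ascii">{offs}</DataArray>'
                  f'<DataArray type="UInt8" Name="types" format="ascii">{types}</DataArray>'
                  '</Cells>')
    pieces.append("</Piece>")
    _write(path, "".join(pieces))


def _write(path: str, piece: str) -> None:
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n'
                 '<VTKFile type="UnstructuredGrid" version="0.1" '
                 'byte_order="LittleEndian">\n<UnstructuredGrid>\n')
        fh.write(piece)
        fh.write("\n</UnstructuredGrid>\n</VTKFile>\n")
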