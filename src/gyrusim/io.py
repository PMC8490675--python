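"""Export helpers: VTU / Gmsh MSH2 meshes, NIfTI images, CSV tables.

The mesh writers emit plain-text formats readable by ParaView/Gmsh; cell
data carries the region labels and any per-element fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from gyrusim.geometry import Mesh, REGION_LABELS

__all__ = ["write_vtu", "write_msh2", "write_state_csv", "write_nifti"]


def _label_ids(labels) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(REGION_LABELS)}
    return np.array([lut.get(lab, -1) for lab in labels], dtype=int)


def write_vtu(path, mesh: Mesh, point_data: dict | None = None,
              cell_data: dict | None = None) -> None:
    """ASCII VTK XML unstructured grid with triangle cells."""
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("region", _label_ids(mesh.element_labels))
    n_pts, n_cells = mesh.n_nodes, mesh.n_elements

    def arr(a, fmt="%.9g"):
        return "\n".join(" ".join(fmt % x for x in np.atleast_1d(row))
                         for row in np.asarray(a))

    pts3 = np.column_stack([mesh.nodes, np.zeros(n_pts)])
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        '<UnstructuredGrid>',
        f'<Piece NumberOfPoints="{n_pts}" NumberOfCells="{n_cells}">',
        '<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">',
        arr(pts3), '</DataArray></Points>',
        '<Cells>',
        '<DataArray type="Int64" Name="connectivity" format="ascii">',
        arr(mesh.triangles, "%d"),
        '</DataArray>',
        '<DataArray type="Int64" Name="offsets" format="ascii">',
        arr(3 * np.arange(1, n_cells + 1), "%d"),
        '</DataArray>',
        '<DataArray type="UInt8" Name="types" format="ascii">',
        arr(np.full(n_cells, 5), "%d"),
        '</DataArray>',
        '</Cells>',
    ]
    lines.append('<PointData>')
    for name, data in point_data.items():
        data = np.asarray(data)
        ncomp = 1 if data.ndim == 1 else data.shape[1]
        lines += [f'<DataArray type="Float64" Name="{name}" '
                  f'NumberOfComponents="{ncomp}" format="ascii">',
                  arr(data), '</DataArray>']
    lines.append('</PointData>')
    lines.append('<CellData>')
    for name, data in cell_data.items():
        data = np.asarray(data, dtype=float)
        ncomp = 1 if data.ndim == 1 else int(np.prod(data.shape[1:]))
        lines += [f'<DataArray type="Float64" Name="{name}" '
                  f'NumberOfComponents="{ncomp}" format="ascii">',
                  arr(data.reshape(len(data), -1)), '</DataArray>']
    lines.append('</CellData>')
    lines += ['</Piece>', '</UnstructuredGrid>', '</VTKFile>']
    Path(path).write_text("\n".join(lines))


def write_msh2(path, mesh: Mesh) -> None:
    """Gmsh MSH v2.2 ASCII; physical tag = region id."""
    ids = _label_ids(mesh.element_labels)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.12g} {y:.12g} 0\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_elements}\n")
        for e, tri in enumerate(mesh.triangles, start=1):
            tag = ids[e - 1]
            fh.write(f"{e} 2 2 {tag} {tag} "
                     f"{tri[0] + 1} {tri[1] + 1} {tri[2] + 1}\n")
        fh.write("$EndElements\n")


def write_state_csv(path, state) -> None:
    """Node table (X, Y, u, v, d_tot) of a deformation state."""
    import pandas as pd
    from gyrusim.fem import total_displacement_field

    d = total_displacement_field(state)
    pd.DataFrame({
        "x_mm": state.p2_nodes[:, 0], "y_mm": state.p2_nodes[:, 1],
        "u_mm": state.u, "v_mm": state.v, "d_tot_um": d,
    }).to_csv(path, index=False)


def write_nifti(path, image) -> None:
    """Write an MRImage (or 2D array + voxel) as NIfTI with mm pixdim."""
    import nibabel as nib

    data = np.asarray(image.data, dtype=np.float32)[:, :, None]
    affine = np.diag([image.voxel, image.voxel, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
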