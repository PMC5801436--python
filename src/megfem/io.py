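"""File interchange: HDF5 containers and legacy-VTK visualization export."""

from __future__ import annotations

import numpy as np

from .eeg_cg import PotentialField
from .spheremesh import CompartmentSpec, HexMesh, VoxelSegmentation
from .transfer import TransferMatrix


def save_segmentation_h5(seg: VoxelSegmentation, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("labels", data=seg.labels, compression=None)
        d.attrs["origin"] = seg.origin
        d.attrs["voxel_size"] = seg.voxel_size


def load_segmentation_h5(path: str) -> VoxelSegmentation:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["labels"]
        return VoxelSegmentation(
            origin=np.asarray(d.attrs["origin"], dtype=float),
            voxel_size=float(d.attrs["voxel_size"]),
            labels=d[...],
        )


def save_potential_h5(pot: PotentialField, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("coefficients", data=pot.coefficients)
        d.attrs["basis_kind"] = pot.basis_kind
        d.attrs["mesh_h"] = pot.mesh.h
        d.attrs["n_elements"] = pot.mesh.n_elements


def save_transfer_h5(T: TransferMatrix, path: str) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("B_MEG", data=T.matrix)
        for k, v in T.provenance.items():
            d.attrs[k] = v


def save_bfields_csv(bfields: dict, path: str) -> None:
    """Flat CSV: dipole id, part, sensor id, component, value [T]."""
    import csv

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["dipole", "part", "sensor", "component", "value"])
        for did, bset in bfields.items():
            for part in ("Bp", "Bs_inf", "Bs_corr"):
                arr = getattr(bset, part)
                for n in range(arr.shape[0]):
                    for c, name in enumerate("xyz"):
                        wr.writerow([did, part, n, name, f"{arr[n, c]:.9e}"])


def export_mesh_vtk(
    mesh: HexMesh,
    path: str,
    cell_data: dict[str, np.ndarray] | None = None,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """ASCII legacy VTK unstructured grid with hexahedral cells.

    Compartment label and conductivity are always written as cell data; VTK
    hexahedron corner order differs from the tensor-product order by a swap
    of local corners 2/3 and 6/7.
    """
    vtk_order = np.array([0, 1, 3, 2, 4, 5, 7, 6])
    cells = mesh.elements[:, vtk_order]
    data = {"label": mesh.element_label.astype(float), "sigma": mesh.element_sigma}
    if cell_data:
        data.update(cell_data)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nhexahedral mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_vertices} double\n")
        np.savetxt(f, mesh.vertices, fmt="%.9g")
        f.write(f"CELLS {mesh.n_elements} {9 * mesh.n_elements}\n")
        np.savetxt(
            f,
            np.hstack([np.full((mesh.n_elements, 1), 8, dtype=np.int64), cells]),
            fmt="%d",
        )
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 12, dtype=np.int64), fmt="%d")
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in data.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.9g")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.9g")


def export_potential_vtk(pot: PotentialField, path: str) -> None:
    """Potential visualization: vertex data for the continuous basis,
    element-averaged corner values (plus max face jump proxy) for the
    broken basis."""
    mesh = pot.mesh
    if pot.basis_kind == "cg-trilinear":
        export_mesh_vtk(mesh, path, point_data={"u": pot.coefficients})
    else:
        ue = pot.element_coefficients()
        export_mesh_vtk(mesh, path, cell_data={"u_mean": ue.mean(axis=1)})
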