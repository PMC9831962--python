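"""Plain-text mesh and model serialisation.

Surfaces go to ASCII PLY (point clouds) or legacy ASCII VTK polydata;
volumes to legacy ASCII VTK unstructured grids with the structure labels as
cell data.  The shape model serialises to a single ``.npz`` archive with
provenance metadata.
"""

from __future__ import annotations

import json

import numpy as np

from .geometry import STRUCTURES, CorrespondedShape, VolumetricMesh


def write_ply(shape: CorrespondedShape, path) -> None:
    """ASCII PLY point cloud of one corresponded surface."""
    points = shape.points
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"comment subject {shape.subject_id}\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("end_header\n")
        for x, y, z in points:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def read_ply(path) -> CorrespondedShape:
    with open(path) as fh:
        subject_id = ""
        n = 0
        for line in fh:
            line = line.strip()
            if line.startswith("comment subject"):
                subject_id = line.split("subject", 1)[1].strip()
            elif line.startswith("element vertex"):
                n = int(line.split()[-1])
            elif line == "end_header":
                break
        points = np.loadtxt(fh, max_rows=n)
    return CorrespondedShape(points.reshape(n, 3), subject_id)


def write_vtk_unstructured(mesh: VolumetricMesh, path) -> None:
    """Legacy ASCII VTK unstructured grid with per-cell structure labels."""
    label_to_int = {name: i for i, name in enumerate(STRUCTURES)}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"spineshape volume {mesh.subject_id}\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} float\n")
        for x, y, z in mesh.nodes:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        fh.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        for conn in mesh.hexahedra:
            fh.write("8 " + " ".join(map(str, conn)) + "\n")
        fh.write(f"CELL_TYPES {mesh.n_elements}\n")
        fh.write("\n".join(["12"] * mesh.n_elements) + "\n")  # VTK_HEXAHEDRON
        fh.write(f"CELL_DATA {mesh.n_elements}\n")
        fh.write("SCALARS structure int 1\nLOOKUP_TABLE default\n")
        fh.write(
            "\n".join(str(label_to_int[str(l)]) for l in mesh.structure_label) + "\n"
        )


def save_model(model, path, metadata: dict | None = None) -> None:
    """Archive a fitted shape model (mean, modes, eigenvalues, provenance)."""
    np.savez_compressed(
        path,
        mean=model.mean_,
        modes=model.modes_,
        eigenvalues=model.eigenvalues_,
        retained=model.retained_,
        n_training=model.n_training_,
        metadata=json.dumps(metadata or {}),
    )


def load_model(path):
    from .ssm import PointDistributionModel

    data = np.load(path, allow_pickle=False)
    model = PointDistributionModel()
    model.mean_ = data["mean"]
    model.modes_ = data["modes"]
    model.eigenvalues_ = data["eigenvalues"]
    model.lambda_total_ = float(model.eigenvalues_.sum())
    model.lambda_bar_ = float(model.eigenvalues_.mean())
    model.n_total_modes_ = model.modes_.shape[1]
    model.n_points_ = model.mean_.size // 3
    model.n_training_ = int(data["n_training"])
    model.retained_ = int(data["retained"])
    return model, json.loads(str(data["metadata"]))
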