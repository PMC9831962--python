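"""Abaqus INP export of the full L4/L5 model (and a reader for round-trips).

The in-repo solver is a linear-elastic proxy; this export preserves the
complete model definition — hyperelastic disc materials (Neo-Hookean
nucleus, Holzapfel-Gasser-Ogden annulus with alternating +-30 degree fibre
orientations), per-structure element types, hard frictionless facet
contact, the 400 N endplate pressure and the fixed lower endplate — so any
subject can be solved externally with the full constitutive set.

Ordering is bit-stable: nodes ascending, elements ascending within each
structure block, ELSETs alphabetical.
"""

from __future__ import annotations

import numpy as np

from .geometry import ANNULUS_LAYERS, VolumetricMesh
from .mechanics import LoadCase, MaterialSet, boundary_faces

#: Element type per structure (reduced/hybrid designations are preserved in
#: the export even though the in-repo solver always integrates fully).
ELEMENT_TYPES = {
    "cancellous": "C3D8R",
    "cortical": "C3D8R",
    "nucleus": "C3D8RH",
    "cep_upper": "C3D8R",
    "cep_lower": "C3D8R",
    "facet_cartilage_left": "C3D8R",
    "facet_cartilage_right": "C3D8R",
    **{layer: "C3D8" for layer in ANNULUS_LAYERS},
}


def _structure_blocks(mesh: VolumetricMesh):
    labels = mesh.structure_label.astype(str)
    for name in sorted(set(labels)):
        yield name, np.flatnonzero(labels == name)


def export_inp(
    mesh: VolumetricMesh,
    materials: MaterialSet | None = None,
    load: LoadCase | None = None,
    path: str = "model.inp",
) -> str:
    """Write a complete Abaqus input deck for one subject.  Returns the path."""
    materials = materials or MaterialSet.default()
    load = load or LoadCase()
    labels = set(map(str, mesh.structure_label))
    if not labels:
        raise ValueError("mesh has no labelled elements")

    lines = ["*HEADING", f"spineshape export: {mesh.subject_id or 'subject'}"]

    lines.append("*NODE")
    for i, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{i}, {x:.9g}, {y:.9g}, {z:.9g}")

    # element blocks per structure (1-based ids, global numbering preserved)
    for name, elems in _structure_blocks(mesh):
        lines.append(f"*ELEMENT, TYPE={ELEMENT_TYPES[name]}, ELSET={name.upper()}")
        for e in elems:
            conn = ", ".join(str(n + 1) for n in mesh.hexahedra[e])
            lines.append(f"{e + 1}, {conn}")

    # materials + sections
    fibre = materials.annulus_fibre_angle_deg
    for name, _ in _structure_blocks(mesh):
        mat_name = f"MAT_{name.upper()}"
        lines.append(f"*SOLID SECTION, ELSET={name.upper()}, MATERIAL={mat_name}")
        lines.append(f"*MATERIAL, NAME={mat_name}")
        if name == "nucleus":
            h = materials.hyperelastic["nucleus"]
            lines.append("*HYPERELASTIC, NEO HOOKE")
            lines.append(f"{h['C10']}, {h['D']}")
        elif name.startswith("annulus_layer_"):
            h = materials.hyperelastic["annulus"]
            layer = int(name.rsplit("_", 1)[1])
            angle = fibre if layer % 2 else -fibre
            lines.append(
                "*ANISOTROPIC HYPERELASTIC, HOLZAPFEL, LOCAL DIRECTIONS=2"
            )
            lines.append(
                f"{h['C10']}, {h['D']}, {h['K1']}, {h['K2']}, {h['kappa']}"
            )
            lines.append(f"** fibre angle {angle:+.1f} deg in-plane")
        else:
            E, nu = materials.linear[name]
            lines.append("*ELASTIC")
            lines.append(f"{E}, {nu}")

    # boundary sets from the deformed geometry (near-axial exterior faces)
    faces, normals = boundary_faces(mesh.nodes, mesh.hexahedra)
    face_z = mesh.nodes[faces][:, :, 2].mean(axis=1)
    z_mid = 0.5 * (mesh.nodes[:, 2].min() + mesh.nodes[:, 2].max())
    top_nodes = np.unique(faces[(normals[:, 2] > 0.866) & (face_z > z_mid)])
    bottom_nodes = np.unique(faces[(normals[:, 2] < -0.866) & (face_z < z_mid)])

    def _nset(name, ids):
        lines.append(f"*NSET, NSET={name}")
        ids = [str(i + 1) for i in ids]
        for start in range(0, len(ids), 12):
            lines.append(", ".join(ids[start:start + 12]))

    _nset("TOP_ENDPLATE", top_nodes)
    _nset("BOTTOM_ENDPLATE", bottom_nodes)

    # facet contact pairs: hard, frictionless
    for side in ("LEFT", "RIGHT"):
        lines.append(f"*SURFACE, NAME=FACET_{side}_UPPER, TYPE=ELEMENT")
        lines.append(f"FACET_CARTILAGE_{side},")
        lines.append(f"*SURFACE, NAME=FACET_{side}_LOWER, TYPE=ELEMENT")
        lines.append(f"FACET_CARTILAGE_{side},")
    lines.append("*SURFACE INTERACTION, NAME=HARD_FRICTIONLESS")
    lines.append("*SURFACE BEHAVIOR, PRESSURE-OVERCLOSURE=HARD")
    for side in ("LEFT", "RIGHT"):
        lines.append(
            f"*CONTACT PAIR, INTERACTION=HARD_FRICTIONLESS, TYPE=SURFACE TO SURFACE"
        )
        lines.append(f"FACET_{side}_UPPER, FACET_{side}_LOWER")

    # load step: uniform pressure integrating to the total force
    top_mask = (normals[:, 2] > 0.866) & (face_z > z_mid)
    top_faces = faces[top_mask]
    X = mesh.nodes[top_faces]
    area = float(
        np.linalg.norm(np.cross(X[:, 2] - X[:, 0], X[:, 3] - X[:, 1]), axis=1).sum() / 2.0
    )
    pressure = load.total_force / area if area > 0 else 0.0
    lines.append("*STEP")
    lines.append("*STATIC")
    lines.append("*BOUNDARY")
    lines.append("BOTTOM_ENDPLATE, 1, 3, 0.0")
    lines.append(f"** total force {load.total_force} N over {area:.6g} mm^2")
    lines.append("*DSLOAD")
    lines.append(f"TOP_ENDPLATE_SURF, P, {pressure:.9g}")
    lines.append("*SURFACE, NAME=TOP_ENDPLATE_SURF, TYPE=NODE")
    lines.append("TOP_ENDPLATE,")
    lines.append("*END STEP")

    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_inp(path: str) -> VolumetricMesh:
    """Parse nodes, hex connectivity and structure labels from an INP file.

    Supports the subset written by :func:`export_inp` (sufficient for
    round-trip verification).
    """
    nodes = {}
    elements = {}
    labels = {}
    mode = None
    current_set = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                keyword = line.split(",")[0].upper()
                if keyword == "*NODE":
                    mode = "node"
                elif keyword == "*ELEMENT":
                    mode = "element"
                    current_set = None
                    for part in line.split(",")[1:]:
                        k, _, v = part.partition("=")
                        if k.strip().upper() == "ELSET":
                            current_set = v.strip().lower()
                else:
                    mode = None
                continue
            if mode == "node":
                parts = line.split(",")
                nodes[int(parts[0])] = [float(x) for x in parts[1:4]]
            elif mode == "element":
                parts = [int(x) for x in line.split(",")]
                elements[parts[0]] = parts[1:9]
                labels[parts[0]] = current_set
    node_ids = sorted(nodes)
    remap = {n: i for i, n in enumerate(node_ids)}
    elem_ids = sorted(elements)
    hexes = np.array([[remap[n] for n in elements[e]] for e in elem_ids])
    label_arr = np.array([labels[e] for e in elem_ids], dtype=object)
    return VolumetricMesh(
        nodes=np.array([nodes[n] for n in node_ids]),
        hexahedra=hexes,
        structure_label=label_arr,
        surface_index=np.array([], dtype=np.int64),
    )
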