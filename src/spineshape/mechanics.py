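"""Mechanical response evaluation for morphed subjects.

In-repo solves use a small-strain, linear-elastic 8-node hexahedral finite
element model (full 2x2x2 Gauss integration) under the study's axial load
case: a uniform pressure on the upper bony endplate integrating to the
total force (400 N by default) with the bottom endplate fully fixed.  The
hyperelastic structures of the full model (Neo-Hookean nucleus,
Holzapfel-Gasser-Ogden annulus) are mapped to documented linear-elastic
surrogates for these solves; the full material set is preserved in the
Abaqus INP export (see :mod:`spineshape.inp`) so the complete model remains
externally solvable.

Outcomes:

* IDP — maximum hydrostatic pressure ``-tr(sigma)/3`` over the nucleus
  quadrature points;
* FCP — analytic facet surrogate: penalty contact pressure from the
  post-deformation closure of the facet pad clearance.  The facet pads are
  excluded from the stiffness system (in the full model they interact
  through frictionless contact, not bonding) and follow their adjacent
  vertebra rigidly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ANNULUS_LAYERS, FACET_STRUCTURES, VolumetricMesh

logger = logging.getLogger(__name__)

# Facet penalty surrogate constants (documented in the methods note)
FACET_PENALTY_STIFFNESS = 1.5  # MPa per mm of clearance closure
FACET_ENGAGEMENT_CLEARANCE = 1.0  # mm; closure is measured against this datum

# local corner coordinates of the trilinear hex
_XI = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)
_GAUSS = _XI / np.sqrt(3.0)  # 2x2x2 points, unit weights


def _shape_gradients(point: np.ndarray) -> np.ndarray:
    """dN_a/dxi_j of the 8 trilinear shape functions at one natural point."""
    xi, eta, zeta = point
    g = np.empty((8, 3))
    g[:, 0] = _XI[:, 0] * (1 + _XI[:, 1] * eta) * (1 + _XI[:, 2] * zeta) / 8.0
    g[:, 1] = _XI[:, 1] * (1 + _XI[:, 0] * xi) * (1 + _XI[:, 2] * zeta) / 8.0
    g[:, 2] = _XI[:, 2] * (1 + _XI[:, 0] * xi) * (1 + _XI[:, 1] * eta) / 8.0
    return g


def _jacobians_at(coords: np.ndarray, points: np.ndarray):
    """Jacobian matrices (E, n_pts, 3, 3) of elements at natural points."""
    grads = np.stack([_shape_gradients(p) for p in points])  # (n, 8, 3)
    # J_ij = d x_i / d xi_j
    return np.einsum("eai,naj->neij", coords, grads), grads


def corner_jacobians(mesh: VolumetricMesh) -> np.ndarray:
    """Corner Jacobian determinants, shape (E, 8)."""
    coords = mesh.nodes[mesh.hexahedra]
    J, _ = _jacobians_at(coords, _XI)
    return np.linalg.det(J).T


def scaled_jacobians(mesh: VolumetricMesh) -> np.ndarray:
    """Corner determinants normalised by the corner edge-length products."""
    coords = mesh.nodes[mesh.hexahedra]
    J, _ = _jacobians_at(coords, _XI)  # (8, E, 3, 3)
    det = np.linalg.det(J)
    norms = np.linalg.norm(J, axis=2)  # column norms: (8, E, 3)
    denom = norms.prod(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        sj = np.where(denom > 0, det / denom, -1.0)
    return sj.T


def screen_quality(mesh: VolumetricMesh, min_scaled_jacobian: float = 0.05):
    """Element-quality gate applied before any solve.

    Invalid if any corner Jacobian determinant is non-positive, or any
    scaled Jacobian falls below the configured floor.
    """
    det = corner_jacobians(mesh)
    sj = scaled_jacobians(mesh)
    metrics = {
        "min_corner_jacobian": float(det.min()),
        "min_scaled_jacobian": float(sj.min()),
        "inverted_elements": int(np.sum(det.min(axis=1) <= 0.0)),
        "n_elements": mesh.n_elements,
    }
    valid = metrics["inverted_elements"] == 0 and metrics["min_scaled_jacobian"] >= min_scaled_jacobian
    return bool(valid), metrics


@dataclass
class MaterialSet:
    """Per-structure material parameters (units: MPa, mm, N).

    ``linear`` drives the in-repo solves; ``hyperelastic`` is carried
    through to the INP export only.  The nucleus and annulus linear
    surrogates derive from the Neo-Hookean ground stiffness
    (mu = 2*C10, E = 2*mu*(1+nu)) at near-incompressible and moderately
    compressible Poisson ratios respectively.
    """

    linear: dict = field(default_factory=dict)
    hyperelastic: dict = field(default_factory=dict)
    annulus_fibre_angle_deg: float = 30.0

    @classmethod
    def default(cls) -> "MaterialSet":
        linear = {
            "cancellous": (100.0, 0.2),
            "cortical": (12000.0, 0.3),
            "cep_upper": (23.0, 0.4),
            "cep_lower": (23.0, 0.4),
            "facet_cartilage_left": (35.0, 0.4),
            "facet_cartilage_right": (35.0, 0.4),
        }
        # nu = 0.49: near-incompressible, while avoiding the severe
        # volumetric locking of fully-integrated trilinear hexes at 0.499
        nucleus_c10, nucleus_nu = 0.16, 0.49
        annulus_c10, annulus_nu = 0.34, 0.45
        linear["nucleus"] = (4.0 * nucleus_c10 * (1.0 + nucleus_nu), nucleus_nu)
        for layer in ANNULUS_LAYERS:
            linear[layer] = (4.0 * annulus_c10 * (1.0 + annulus_nu), annulus_nu)
        hyperelastic = {
            "nucleus": {"model": "neo_hooke", "C10": 0.16, "D": 0.024},
            "annulus": {
                "model": "holzapfel",
                "C10": 0.34,
                "D": 0.3,
                "K1": 1.81,
                "K2": 11.0,
                "kappa": 0.0,
            },
        }
        return cls(linear=linear, hyperelastic=hyperelastic)

    def validate_for(self, mesh: VolumetricMesh) -> None:
        missing = set(map(str, np.unique(mesh.structure_label))) - set(self.linear)
        if missing:
            raise ValueError(f"no material defined for structures: {sorted(missing)}")
        for name, (E, nu) in self.linear.items():
            if E <= 0:
                raise ValueError(f"{name}: Young's modulus must be positive")
            if not 0 <= nu < 0.5:
                raise ValueError(f"{name}: Poisson ratio must be in [0, 0.5)")


@dataclass
class LoadCase:
    """Axial compression: pressure on the top endplate, bottom fully fixed."""

    total_force: float = 400.0

    def __post_init__(self) -> None:
        if self.total_force < 0:
            raise ValueError("total_force must be non-negative")


@dataclass
class SimulationResult:
    subject_id: str
    idp: float
    fcp: float
    valid: bool
    failure_reason: str | None = None

    def __post_init__(self) -> None:
        if self.valid and not (np.isfinite(self.idp) and np.isfinite(self.fcp)):
            raise ValueError("valid results must carry finite outcomes")
        if (not self.valid) != (self.failure_reason is not None):
            raise ValueError("failure_reason must be set exactly when invalid")


def _isotropic_d_matrix(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Voigt elasticity matrices (n, 6, 6); order xx,yy,zz,xy,yz,zx."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    n = E.shape[0]
    D = np.zeros((n, 6, 6))
    for i in range(3):
        for j in range(3):
            D[:, i, j] = lam
        D[:, i, i] = lam + 2 * mu
    for i in range(3, 6):
        D[:, i, i] = mu
    return D


def element_stiffness(coords: np.ndarray, E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Stiffness matrices (n_el, 24, 24) by full 2x2x2 Gauss quadrature."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    E = np.atleast_1d(np.asarray(E, dtype=float))
    nu = np.atleast_1d(np.asarray(nu, dtype=float))
    D = _isotropic_d_matrix(E, nu)
    n_el = coords.shape[0]
    K = np.zeros((n_el, 24, 24))
    for g in _GAUSS:
        dN = _shape_gradients(g)  # (8, 3)
        J = np.einsum("eai,aj->eij", coords, dN)
        detJ = np.linalg.det(J)
        invJ = np.linalg.inv(J)
        gradN = np.einsum("aj,eji->eai", dN, invJ)  # dN_a/dx_i
        B = np.zeros((n_el, 6, 24))
        gx, gy, gz = gradN[:, :, 0], gradN[:, :, 1], gradN[:, :, 2]
        cols = np.arange(8)
        B[:, 0, cols * 3 + 0] = gx
        B[:, 1, cols * 3 + 1] = gy
        B[:, 2, cols * 3 + 2] = gz
        B[:, 3, cols * 3 + 0] = gy
        B[:, 3, cols * 3 + 1] = gx
        B[:, 4, cols * 3 + 1] = gz
        B[:, 4, cols * 3 + 2] = gy
        B[:, 5, cols * 3 + 0] = gz
        B[:, 5, cols * 3 + 2] = gx
        K += np.einsum("eqi,eqr,erj,e->eij", B, D, B, detJ, optimize=True)
    return K


def assemble_stiffness(mesh: VolumetricMesh, materials: MaterialSet,
                       element_ids: np.ndarray | None = None) -> sp.csr_matrix:
    """Assemble the global sparse stiffness over the given elements."""
    if element_ids is None:
        element_ids = np.arange(mesh.n_elements)
    conn = mesh.hexahedra[element_ids]
    coords = mesh.nodes[conn]
    labels = mesh.structure_label[element_ids]
    Es = np.array([materials.linear[str(l)][0] for l in labels])
    nus = np.array([materials.linear[str(l)][1] for l in labels])
    Ke = element_stiffness(coords, Es, nus)
    dof = (conn[:, :, None] * 3 + np.arange(3)[None, None, :]).reshape(len(conn), 24)
    rows = np.repeat(dof, 24, axis=1).ravel()
    cols = np.tile(dof, (1, 24)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n_dof, n_dof))
    return K.tocsr()


def _quad_face_forces(nodes: np.ndarray, faces: np.ndarray, traction: np.ndarray):
    """Consistent nodal forces of a uniform traction on bilinear quad faces.

    Returns (forces (N,3) scattered to nodes, total face area).
    """
    gp = np.array([-1, 1]) / np.sqrt(3.0)
    forces = np.zeros_like(nodes)
    area = 0.0
    X = nodes[faces]  # (F, 4, 3)
    for xi in gp:
        for eta in gp:
            N = np.array(
                [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                 (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
            ) / 4.0
            dNxi = np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)]) / 4.0
            dNeta = np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)]) / 4.0
            t1 = np.einsum("a,fai->fi", dNxi, X)
            t2 = np.einsum("a,fai->fi", dNeta, X)
            dA = np.linalg.norm(np.cross(t1, t2), axis=1)  # (F,)
            area += float(dA.sum())
            contrib = N[None, :, None] * dA[:, None, None] * traction[None, None, :]
            np.add.at(forces, faces.ravel(), contrib.reshape(-1, 3))
    return forces, area


_FACE_LOCAL = np.array(
    [[0, 1, 2, 3], [4, 5, 6, 7], [0, 1, 5, 4], [1, 2, 6, 5], [2, 3, 7, 6], [3, 0, 4, 7]]
)


def _faces_on_nodes(hexes: np.ndarray, node_set: np.ndarray) -> np.ndarray:
    """Element faces whose four nodes all belong to ``node_set``."""
    in_set = np.zeros(hexes.max() + 1, dtype=bool)
    in_set[node_set] = True
    faces = hexes[:, _FACE_LOCAL]  # (E, 6, 4)
    mask = in_set[faces].all(axis=2)
    return faces[mask]


def boundary_faces(nodes: np.ndarray, hexes: np.ndarray):
    """Exterior quad faces of a hex mesh with outward unit normals.

    Returns (faces (F, 4), normals (F, 3)).  A face is exterior when it is
    referenced by exactly one element; normals are oriented away from the
    owning element's centroid.
    """
    faces = hexes[:, _FACE_LOCAL].reshape(-1, 4)
    owner = np.repeat(np.arange(len(hexes)), 6)
    key = np.sort(faces, axis=1)
    _, index, counts = np.unique(
        key, axis=0, return_index=True, return_counts=True
    )
    keep = index[counts == 1]
    faces = faces[keep]
    owner = owner[keep]
    X = nodes[faces]
    n = np.cross(X[:, 2] - X[:, 0], X[:, 3] - X[:, 1])
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    to_face = X.mean(axis=1) - nodes[hexes[owner]].mean(axis=1)
    flip = np.sign(np.einsum("fi,fi->f", n, to_face))
    return faces, n * flip[:, None]


def solve_linear_elastic(
    mesh: VolumetricMesh,
    materials: MaterialSet,
    forces: np.ndarray,
    fixed_dof: np.ndarray,
    element_ids: np.ndarray | None = None,
):
    """Solve K u = f with zero-displacement constraints on ``fixed_dof``.

    Returns (displacements (N,3), global stiffness).  ``fixed_dof`` is a
    boolean mask over the 3N degrees of freedom.
    """
    K = assemble_stiffness(mesh, materials, element_ids)
    n_dof = K.shape[0]
    f = np.asarray(forces, dtype=float).reshape(n_dof)
    fixed_dof = np.asarray(fixed_dof, dtype=bool).reshape(n_dof)
    if element_ids is not None:
        active = np.zeros(mesh.n_nodes, dtype=bool)
        active[mesh.hexahedra[element_ids].ravel()] = True
        inactive_dof = np.repeat(~active, 3)
        fixed_dof = fixed_dof | inactive_dof
    free = ~fixed_dof
    if not fixed_dof.any():
        raise ValueError("the system is unconstrained (no fixed degrees of freedom)")
    K_ff = K[free][:, free]
    u = np.zeros(n_dof)
    try:
        u[free] = spla.spsolve(K_ff.tocsc(), f[free])
    except RuntimeError as exc:
        raise ValueError(f"singular stiffness system: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise ValueError(
            "singular stiffness system (insufficient constraints or degenerate elements)"
        )
    return u.reshape(-1, 3), K


def element_stresses(mesh: VolumetricMesh, materials: MaterialSet,
                     displacements: np.ndarray,
                     element_ids: np.ndarray) -> np.ndarray:
    """Voigt stresses at the 2x2x2 quadrature points, shape (n_el, 8, 6)."""
    conn = mesh.hexahedra[element_ids]
    coords = mesh.nodes[conn]
    labels = mesh.structure_label[element_ids]
    Es = np.array([materials.linear[str(l)][0] for l in labels])
    nus = np.array([materials.linear[str(l)][1] for l in labels])
    D = _isotropic_d_matrix(Es, nus)
    u_e = displacements[conn].reshape(len(conn), 24)
    out = np.zeros((len(conn), 8, 6))
    for gi, g in enumerate(_GAUSS):
        dN = _shape_gradients(g)
        J = np.einsum("eai,aj->eij", coords, dN)
        invJ = np.linalg.inv(J)
        gradN = np.einsum("aj,eji->eai", dN, invJ)
        B = np.zeros((len(conn), 6, 24))
        gx, gy, gz = gradN[:, :, 0], gradN[:, :, 1], gradN[:, :, 2]
        colsv = np.arange(8)
        B[:, 0, colsv * 3 + 0] = gx
        B[:, 1, colsv * 3 + 1] = gy
        B[:, 2, colsv * 3 + 2] = gz
        B[:, 3, colsv * 3 + 0] = gy
        B[:, 3, colsv * 3 + 1] = gx
        B[:, 4, colsv * 3 + 1] = gz
        B[:, 4, colsv * 3 + 2] = gy
        B[:, 5, colsv * 3 + 0] = gz
        B[:, 5, colsv * 3 + 2] = gx
        eps = np.einsum("eqi,ei->eq", B, u_e)
        out[:, gi, :] = np.einsum("eqr,er->eq", D, eps)
    return out


def _pad_components(mesh: VolumetricMesh, side: str):
    """Split one side's facet pad elements into its two (upper/lower) boxes."""
    elems = mesh.elements_of(f"facet_cartilage_{side}")
    if elems.size == 0:
        return None
    conn = mesh.hexahedra[elems]
    node_ids = np.unique(conn)
    remap = {n: i for i, n in enumerate(node_ids)}
    n_local = len(node_ids)
    rows, cols = [], []
    for e in conn:
        for a in range(8):
            for b in range(a + 1, 8):
                rows.append(remap[e[a]])
                cols.append(remap[e[b]])
    adj = sp.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_local, n_local)
    )
    n_comp, comp = sp.csgraph.connected_components(adj, directed=False)
    if n_comp != 2:
        return None
    groups = [node_ids[comp == c] for c in range(2)]
    means = [mesh.nodes[g][:, 2].mean() for g in groups]
    lower, upper = (groups[0], groups[1]) if means[0] < means[1] else (groups[1], groups[0])
    return upper, lower


def _facet_surrogate(mesh: VolumetricMesh, displacements: np.ndarray,
                     solved_nodes: np.ndarray) -> float:
    """Penalty facet contact pressure from post-deformation pad clearance.

    Each pad box follows its adjacent vertebra rigidly: its displacement is
    the mean displacement of the nearest solved column nodes.  Clearance is
    measured between the facing face node sets of the upper/lower boxes;
    pressure is the penalty stiffness times the closure against the
    engagement datum, floored at zero.
    """
    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.nodes[solved_nodes])
    pressures = [0.0]
    for side in ("left", "right"):
        comps = _pad_components(mesh, side)
        if comps is None:
            continue
        upper, lower = comps
        gap_faces = []
        for group, pick_low in ((upper, True), (lower, False)):
            z = mesh.nodes[group][:, 2]
            order = np.argsort(z)
            face = group[order[:9]] if pick_low else group[order[-9:]]
            centroid = mesh.nodes[group].mean(axis=0)
            _, nearest = tree.query(centroid, k=min(12, len(solved_nodes)))
            rigid_u = displacements[solved_nodes[np.atleast_1d(nearest)]].mean(axis=0)
            gap_faces.append(mesh.nodes[face][:, 2].mean() + rigid_u[2])
        gap = gap_faces[0] - gap_faces[1]
        closure = FACET_ENGAGEMENT_CLEARANCE - gap
        pressures.append(FACET_PENALTY_STIFFNESS * max(0.0, closure))
    return float(max(pressures))


def solve_axial(
    mesh: VolumetricMesh,
    materials: MaterialSet | None = None,
    load: LoadCase | None = None,
    min_scaled_jacobian: float = 0.05,
    skip_screening: bool = False,
    full_output: bool = False,
):
    """Screen, solve the axial load case, and extract IDP/FCP outcomes.

    With ``full_output=True`` returns ``(result, state)`` where ``state``
    carries the displacement field, applied force vector, fixed-dof mask
    and assembled stiffness for diagnostic checks (equilibrium, reactions).
    """
    materials = materials or MaterialSet.default()
    load = load or LoadCase()
    materials.validate_for(mesh)

    if not skip_screening:
        valid, metrics = screen_quality(mesh, min_scaled_jacobian)
        if not valid:
            result = SimulationResult(
                subject_id=mesh.subject_id,
                idp=float("nan"),
                fcp=float("nan"),
                valid=False,
                failure_reason=(
                    "element quality: "
                    f"{metrics['inverted_elements']} inverted elements, "
                    f"min scaled Jacobian {metrics['min_scaled_jacobian']:.3g}"
                ),
            )
            return (result, None) if full_output else result

    solved_elems = np.flatnonzero(
        ~np.isin(mesh.structure_label.astype(str), FACET_STRUCTURES)
    )
    solved_nodes = np.unique(mesh.hexahedra[solved_elems].ravel())
    # endplates found topologically: exterior faces whose outward normal is
    # near-axial, above/below the segment midplane (robust to deformation)
    bfaces, bnormals = boundary_faces(mesh.nodes, mesh.hexahedra[solved_elems])
    face_z = mesh.nodes[bfaces][:, :, 2].mean(axis=1)
    z_mid = 0.5 * (mesh.nodes[solved_nodes][:, 2].min()
                   + mesh.nodes[solved_nodes][:, 2].max())
    top_mask = (bnormals[:, 2] > 0.866) & (face_z > z_mid)
    bottom_mask = (bnormals[:, 2] < -0.866) & (face_z < z_mid)
    faces = bfaces[top_mask]
    bottom_nodes = np.unique(bfaces[bottom_mask])
    if faces.size == 0:
        raise ValueError("no loaded faces found on the upper endplate")
    if bottom_nodes.size == 0:
        raise ValueError("no fixed faces found on the lower endplate")
    # unit traction first, then scale so the resultant equals total_force
    probe, area = _quad_face_forces(mesh.nodes, faces, np.array([0.0, 0.0, -1.0]))
    pressure = load.total_force / area
    forces = probe * pressure

    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fixed[bottom_nodes] = True

    u, K = solve_linear_elastic(
        mesh, materials, forces, fixed, element_ids=solved_elems
    )

    nucleus = mesh.elements_of("nucleus")
    if nucleus.size == 0:
        raise ValueError("mesh has no nucleus elements; IDP is undefined")
    sigma = element_stresses(mesh, materials, u, nucleus)
    hydro = -(sigma[:, :, 0] + sigma[:, :, 1] + sigma[:, :, 2]) / 3.0
    idp = float(hydro.max())

    fcp = _facet_surrogate(mesh, u, solved_nodes)
    result = SimulationResult(
        subject_id=mesh.subject_id, idp=idp, fcp=fcp, valid=True
    )
    if full_output:
        state = {
            "displacements": u,
            "forces": forces,
            "fixed_dof": fixed,
            "stiffness": K,
            "loaded_area": area,
            "pressure": pressure,
        }
        return result, state
    return result


def batch_simulate(
    meshes: list,
    materials: MaterialSet | None = None,
    load: LoadCase | None = None,
    min_scaled_jacobian: float = 0.05,
) -> list:
    """Screen + solve every subject; failures become invalid results."""
    materials = materials or MaterialSet.default()
    load = load or LoadCase()
    results = []
    for mesh in meshes:
        result = solve_axial(
            mesh, materials, load, min_scaled_jacobian=min_scaled_jacobian
        )
        if not result.valid:
            logger.warning("subject %s failed screening: %s",
                           mesh.subject_id, result.failure_reason)
        results.append(result)
    n_fail = sum(not r.valid for r in results)
    logger.info("batch complete: %d/%d valid (%.1f%% failed)",
                len(results) - n_fail, len(results),
                100.0 * n_fail / max(1, len(results)))
    return results


def results_to_frame(results: list):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "idp": r.idp,
                "fcp": r.fcp,
                "valid": r.valid,
                "failure_reason": r.failure_reason or "",
            }
            for r in results
        ]
    )
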