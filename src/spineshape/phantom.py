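"""Synthetic L4/L5 phantom cohorts with known latent structure.

The real training cohort behind this kind of study (subject-specific,
corresponded volumetric meshes of the L4/L5 functional spinal unit) is not
publicly available.  This module generates a stand-in: a *phantom* made of
two extruded super-elliptical vertebral blocks separated by an
intervertebral-disc region (nucleus core plus seven concentric annulus
layers, capped by cartilaginous endplates) and two posterior facet-cartilage
pad pairs.  Every subject is produced from a known low-dimensional latent
shape space (smooth global deformation fields), plus iid point noise and a
multiplicative size factor, so downstream stages can be tested against
exact ground truth.

The phantom also carries analytic response functions producing
intradiscal-pressure-like (IDP) and facet-contact-pressure-like (FCP)
outcomes as smooth functions of interpretable geometric features (segment
height, nucleus width, facet gap, sagittal shear).  Signs follow the
physical expectations: a wider nucleus lowers the IDP-like outcome; a
tighter facet gap raises the FCP-like outcome.

Everything is synthetic and labelled as such; no anatomical realism is
claimed beyond exposing the full structure-label set of the real model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import CorrespondedShape, VolumetricMesh, flatten_points

# Fixed phantom dimensions (mm)
VERTEBRA_HEIGHT = 26.0
CEP_HEIGHT = 1.0
DISC_HEIGHT = 10.0
SEMI_AXIS_A = 22.0  # lateral half-width
SEMI_AXIS_B = 16.0  # antero-posterior half-width
PAD_SIZE = (8.0, 6.0, 2.0)  # facet pad block dimensions
PAD_GAP = 0.7  # initial vertical clearance between pad pairs (mm)
PAD_X_OFFSET = 13.0
PAD_Y_CENTER = -(SEMI_AXIS_B + 5.0)  # posterior of the column

TOTAL_HEIGHT = 2 * VERTEBRA_HEIGHT + 2 * CEP_HEIGHT + DISC_HEIGHT
Z_MID = TOTAL_HEIGHT / 2.0

#: Baseline intercepts and feature coefficients of the analytic responses.
#: Units: MPa and MPa/mm.  Jittered by +-10% per cohort seed.  The sign and
#: dominance structure mirrors the linear-elastic proxy solver: a taller,
#: narrower segment raises the nucleus pressure; a wider nucleus lowers it;
#: a tighter facet gap raises the facet contact pressure.
RESPONSE_TEMPLATE = {
    "idp": {"intercept": 0.48, "height": 0.044, "nucleus_halfwidth": -0.011},
    "fcp": {"intercept": 0.80, "height": -0.019, "facet_gap": -0.30, "shear": 0.01},
}

FEATURE_NAMES = ("height", "nucleus_halfwidth", "facet_gap", "shear")


@dataclass
class PhantomSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the real training cohort's scale: 152 subjects and a
    surface sampling of roughly 14,015 points.  ``p`` is a target: the
    structured phantom grid is chosen to get as close as possible and the
    realised count is reported by the generator.
    """

    t: int = 152
    p: int = 14015
    latent_dim: int = 4
    latent_sd: list | None = None
    noise_sd: float = 0.05
    size_sd: float = 0.04
    seed: int = 0
    structure_fractions: dict | None = None

    def __post_init__(self) -> None:
        if self.t < 3:
            raise ValueError("t must be >= 3")
        if self.p < 12:
            raise ValueError("p must be >= 12")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.latent_dim >= self.t:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) must be smaller than t ({self.t})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.size_sd < 0:
            raise ValueError("size_sd must be >= 0")
        if self.latent_sd is None:
            # geometric decay keeps the spectrum strictly decreasing
            self.latent_sd = [12.0 * 0.66**j for j in range(self.latent_dim)]
        self.latent_sd = [float(s) for s in self.latent_sd]
        if len(self.latent_sd) != self.latent_dim:
            raise ValueError("latent_sd length must equal latent_dim")
        if any(s < 0 for s in self.latent_sd):
            raise ValueError("latent_sd entries must be >= 0")
        positive = [s for s in self.latent_sd if s > 0]
        if any(b >= a for a, b in zip(positive, positive[1:])):
            raise ValueError("positive latent_sd entries must be strictly decreasing")
        if sorted(self.latent_sd, reverse=True) != self.latent_sd:
            raise ValueError("latent_sd must be non-increasing")
        fractions = {"nucleus_radius_fraction": 0.4}
        if self.structure_fractions:
            fractions.update(self.structure_fractions)
        self.structure_fractions = fractions
        nf = self.structure_fractions["nucleus_radius_fraction"]
        if not 0 < nf < 1:
            raise ValueError("nucleus_radius_fraction must be in (0, 1)")


@dataclass
class PhantomGeometry:
    """Construction metadata of the mean phantom (one per cohort)."""

    nxy: int
    n_vert_layers: int
    n_disc_layers: int
    n_nucleus_rings: int
    z_planes: np.ndarray
    node_square_uv: np.ndarray  # (N, 2); NaN for pad nodes
    node_ring: np.ndarray  # integer Chebyshev ring index; -1 for pad nodes
    pad_node_sets: dict  # side -> {"upper": ids, "lower": ids}
    feature_nodes: dict  # feature name -> node-id arrays
    surface_positions: dict  # feature name -> positions within surface ordering


@dataclass
class GroundTruth:
    """Everything needed to score downstream recovery against the generator."""

    latent_weights: np.ndarray  # (t, k)
    latent_sd: np.ndarray  # (k,)
    surface_fields: np.ndarray  # (k, 3p) orthonormal generative modes (flattened)
    response_coefficients: dict  # outcome -> {feature: coefficient}
    latent_jacobian: dict  # outcome -> (k,) d outcome / d latent weight
    true_importance_ranking: dict  # outcome -> mode indices, most important first
    feature_refs: dict  # feature name -> value on the mean phantom
    surface_feature_positions: dict  # feature name -> index arrays into surface order
    seed: int


# ---------------------------------------------------------------------------
# mean phantom construction


def _squircle_xy(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Map the unit square onto the super-elliptical cross-section.

    A blend of the identity and the smooth elliptical square-to-disc map:
    the boundary becomes a rounded square (squircle) and, unlike the pure
    elliptical map, corner cells keep a healthy Jacobian.
    """
    beta = 0.75  # 0 -> square cross-section, 1 -> ellipse
    fx = 1.0 - beta + beta * np.sqrt(np.maximum(0.0, 1.0 - v**2 / 2.0))
    fy = 1.0 - beta + beta * np.sqrt(np.maximum(0.0, 1.0 - u**2 / 2.0))
    return np.column_stack([SEMI_AXIS_A * u * fx, SEMI_AXIS_B * v * fy])


def _layer_plan(nxy: int, n_vert: int, n_disc: int):
    """Per-element-layer (part, z_bottom, z_top) stack from bottom to top."""
    parts = (
        ["L5"] * n_vert + ["cep_lower"] + ["disc"] * n_disc + ["cep_upper"] + ["L4"] * n_vert
    )
    z = [0.0]
    for part in parts:
        h = {"L5": VERTEBRA_HEIGHT / n_vert, "L4": VERTEBRA_HEIGHT / n_vert,
             "cep_lower": CEP_HEIGHT, "cep_upper": CEP_HEIGHT,
             "disc": DISC_HEIGHT / n_disc}[part]
        z.append(z[-1] + h)
    return parts, np.asarray(z)


def _surface_count(nxy: int, n_vert: int, n_disc: int, n_nuc: int) -> int:
    nz = 2 * n_vert + 2 + n_disc
    exterior = 2 * (nxy + 1) ** 2 + 4 * nxy * (nz - 1)
    lateral_interface = (n_disc + 1) * 8 * n_nuc
    cep_interface = 2 * (2 * n_nuc - 1) ** 2
    pads = 4 * 18
    return exterior + lateral_interface + cep_interface + pads


def _grid_for_p(p: int, nucleus_fraction: float):
    """Pick grid resolution whose realised surface count is closest to ``p``."""
    best = None
    for nxy in range(16, 97, 2):
        h = nxy // 2
        n_nuc = int(np.clip(round(h * nucleus_fraction), 1, h - 7))
        n_vert = max(3, round(nxy * 0.2))
        n_disc = max(3, round(nxy * 0.17))
        count = _surface_count(nxy, n_vert, n_disc, n_nuc)
        score = abs(count - p)
        if best is None or score < best[0]:
            best = (score, nxy, n_vert, n_disc, n_nuc)
    _, nxy, n_vert, n_disc, n_nuc = best
    return nxy, n_vert, n_disc, n_nuc


def _pad_box(center, dims, divisions=(2, 2, 1)):
    """Small structured box mesh (nodes, hexes with local indices)."""
    nx, ny, nz = divisions
    xs = np.linspace(-dims[0] / 2, dims[0] / 2, nx + 1) + center[0]
    ys = np.linspace(-dims[1] / 2, dims[1] / 2, ny + 1) + center[1]
    zs = np.linspace(-dims[2] / 2, dims[2] / 2, nz + 1) + center[2]
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return k * (ny + 1) * (nx + 1) + j * (nx + 1) + i

    hexes = []
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                hexes.append(
                    [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                     nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
                     nid(i, j + 1, k + 1)]
                )
    return nodes, np.asarray(hexes)


def build_mean_phantom(spec: PhantomSpec):
    """Construct the mean phantom mesh and its geometry metadata."""
    nucleus_fraction = spec.structure_fractions["nucleus_radius_fraction"]
    nxy, n_vert, n_disc, n_nuc = _grid_for_p(spec.p, nucleus_fraction)
    h = nxy // 2
    parts, z_planes = _layer_plan(nxy, n_vert, n_disc)
    n_layers = len(parts)
    n_planes = n_layers + 1
    npp = (nxy + 1) ** 2

    # column nodes
    uu = np.linspace(-1.0, 1.0, nxy + 1)
    U, V = np.meshgrid(uu, uu, indexing="xy")  # V varies along rows (iy)
    u_flat, v_flat = U.ravel(), V.ravel()
    xy = _squircle_xy(u_flat, v_flat)
    nodes = np.concatenate(
        [np.column_stack([xy, np.full(npp, z)]) for z in z_planes], axis=0
    )
    node_uv = np.tile(np.column_stack([u_flat, v_flat]), (n_planes, 1))
    ii = np.arange(nxy + 1)
    IX, IY = np.meshgrid(ii, ii, indexing="xy")
    ring_plane = np.maximum(np.abs(IX - h), np.abs(IY - h)).ravel()
    node_ring = np.tile(ring_plane, n_planes)

    def col_id(ix, iy, plane):
        return plane * npp + iy * (nxy + 1) + ix

    # column elements + labels
    ex, ey = np.meshgrid(np.arange(nxy), np.arange(nxy), indexing="xy")
    ex, ey = ex.ravel(), ey.ravel()
    elem_ring = (np.maximum(np.abs(ex - h + 0.5), np.abs(ey - h + 0.5)) + 0.5).astype(int)
    hexes, labels = [], []
    for k, part in enumerate(parts):
        n0 = col_id(ex, ey, k)
        n1 = col_id(ex + 1, ey, k)
        n2 = col_id(ex + 1, ey + 1, k)
        n3 = col_id(ex, ey + 1, k)
        conn = np.column_stack([n0, n1, n2, n3, n0 + npp, n1 + npp, n2 + npp, n3 + npp])
        hexes.append(conn)
        if part in ("L4", "L5"):
            lab = np.where(elem_ring > h - 2, "cortical", "cancellous")
        elif part in ("cep_lower", "cep_upper"):
            lab = np.full(ex.shape, part, dtype=object)
        else:  # disc
            ann = np.ceil((elem_ring - n_nuc) * 7.0 / (h - n_nuc)).astype(int)
            lab = np.where(
                elem_ring <= n_nuc,
                "nucleus",
                np.array([f"annulus_layer_{max(1, a)}" for a in ann], dtype=object),
            )
        labels.append(np.asarray(lab, dtype=object))

    nodes_list = [nodes]
    uv_list = [node_uv]
    ring_list = [node_ring]
    offset = nodes.shape[0]

    # facet pads: two vertical pairs, posterior of the column
    pad_node_sets = {}
    for side, sx in (("left", +1.0), ("right", -1.0)):
        sets = {}
        for pos, zc in (
            ("lower", Z_MID - PAD_GAP / 2 - PAD_SIZE[2] / 2),
            ("upper", Z_MID + PAD_GAP / 2 + PAD_SIZE[2] / 2),
        ):
            pn, ph = _pad_box((sx * PAD_X_OFFSET, PAD_Y_CENTER, zc), PAD_SIZE)
            hexes.append(ph + offset)
            labels.append(np.full(ph.shape[0], f"facet_cartilage_{side}", dtype=object))
            sets[pos] = np.arange(offset, offset + pn.shape[0])
            nodes_list.append(pn)
            uv_list.append(np.full((pn.shape[0], 2), np.nan))
            ring_list.append(np.full(pn.shape[0], -1))
            offset += pn.shape[0]
        pad_node_sets[side] = sets

    all_nodes = np.concatenate(nodes_list, axis=0)
    node_uv = np.concatenate(uv_list, axis=0)
    node_ring = np.concatenate(ring_list, axis=0)
    all_hexes = np.concatenate(hexes, axis=0)
    all_labels = np.concatenate(labels, axis=0)

    # surface node sets
    n_col = n_planes * npp
    plane_of = np.arange(n_col) // npp
    exterior = (plane_of == 0) | (plane_of == n_planes - 1) | (node_ring[:n_col] == h)
    disc_first_plane = n_vert + 1
    disc_last_plane = disc_first_plane + n_disc
    on_disc_plane = (plane_of >= disc_first_plane) & (plane_of <= disc_last_plane)
    lateral_interface = on_disc_plane & (node_ring[:n_col] == n_nuc)
    on_end_plane = (plane_of == disc_first_plane) | (plane_of == disc_last_plane)
    cep_interface = on_end_plane & (node_ring[:n_col] < n_nuc)
    surface_mask = np.zeros(all_nodes.shape[0], dtype=bool)
    surface_mask[:n_col] = exterior | lateral_interface | cep_interface
    surface_mask[n_col:] = True  # all pad nodes
    surface_index = np.flatnonzero(surface_mask)

    # feature node sets (used by the analytic responses)
    top_face = np.flatnonzero(plane_of == n_planes - 1)
    bottom_face = np.flatnonzero(plane_of == 0)
    interface_ring = np.flatnonzero(lateral_interface)
    feature_nodes = {
        "top_face": top_face,
        "bottom_face": bottom_face,
        "interface_ring": interface_ring,
    }
    for side in ("left", "right"):
        upper = pad_node_sets[side]["upper"]
        lower = pad_node_sets[side]["lower"]
        un = all_nodes[upper]
        ln = all_nodes[lower]
        feature_nodes[f"pad_{side}_upper_bottom"] = upper[
            np.isclose(un[:, 2], un[:, 2].min())
        ]
        feature_nodes[f"pad_{side}_lower_top"] = lower[
            np.isclose(ln[:, 2], ln[:, 2].max())
        ]

    surface_positions = {
        name: np.searchsorted(surface_index, ids) for name, ids in feature_nodes.items()
    }
    # fixed reference radial directions of the interface ring (unit xy),
    # making the nucleus-width feature a linear functional of the points;
    # directions and centroids are taken per z-plane of the ring
    ring_plane = plane_of[interface_ring]
    ring_plane = (ring_plane - ring_plane.min()).astype(np.int64)
    ring_xy = all_nodes[interface_ring][:, :2]
    n_ring_planes = ring_plane.max() + 1
    sums = np.zeros((n_ring_planes, 2))
    counts = np.bincount(ring_plane, minlength=n_ring_planes).astype(float)
    np.add.at(sums, ring_plane, ring_xy)
    rel = ring_xy - (sums / counts[:, None])[ring_plane]
    surface_positions["interface_ring_dirs"] = rel / np.linalg.norm(
        rel, axis=1, keepdims=True
    )
    surface_positions["interface_ring_plane"] = ring_plane

    mesh = VolumetricMesh(
        nodes=all_nodes,
        hexahedra=all_hexes,
        structure_label=all_labels,
        surface_index=surface_index,
        subject_id="mean_phantom",
    )
    geom = PhantomGeometry(
        nxy=nxy,
        n_vert_layers=n_vert,
        n_disc_layers=n_disc,
        n_nucleus_rings=n_nuc,
        z_planes=z_planes,
        node_square_uv=node_uv,
        node_ring=node_ring,
        pad_node_sets=pad_node_sets,
        feature_nodes=feature_nodes,
        surface_positions=surface_positions,
    )
    return mesh, geom


# ---------------------------------------------------------------------------
# generative deformation fields


def generative_fields(mesh: VolumetricMesh, geom: PhantomGeometry, latent_dim: int) -> np.ndarray:
    """Smooth global deformation fields, orthonormalised over the surface.

    Field order: axial height, nucleus width, facet gap, sagittal shear, then
    end-clamped bending harmonics for any further dimensions.  Fields are
    Gram-Schmidt orthogonalised (in the flattened-surface inner product) and
    scaled to unit flattened-surface norm, so a latent weight ``w`` displaces
    the surface by exactly ``w`` in the shape-vector metric.
    """
    nodes = mesh.nodes
    n = nodes.shape[0]
    h = geom.nxy // 2
    half_height = TOTAL_HEIGHT / 2.0
    zc = (nodes[:, 2] - Z_MID) / half_height
    fields = []

    # 1: axial height change
    f = np.zeros((n, 3))
    f[:, 2] = zc
    fields.append(f)

    if latent_dim >= 2:
        # 2: nucleus width.  Inside the nucleus the radial motion ramps
        # linearly with the square radius (an affine dilation, which cannot
        # invert elements at moderate weights); outside it decays smoothly.
        rho = geom.node_ring / h  # normalised square radius, -1 -> pads
        rho_nuc = geom.n_nucleus_rings / h
        gz = np.exp(-2.77 * ((nodes[:, 2] - Z_MID) / DISC_HEIGHT) ** 2)
        profile = np.where(
            rho <= rho_nuc,
            rho / rho_nuc,
            np.exp(-(((rho - rho_nuc) / 0.25) ** 2)),
        )
        mag = gz * profile
        mag[geom.node_ring < 0] = 0.0  # pads untouched
        r_xy = np.hypot(nodes[:, 0], nodes[:, 1])
        with np.errstate(invalid="ignore", divide="ignore"):
            ux = np.where(r_xy > 1e-9, nodes[:, 0] / r_xy, 0.0)
            uy = np.where(r_xy > 1e-9, nodes[:, 1] / r_xy, 0.0)
        f = np.zeros((n, 3))
        f[:, 0] = mag * ux
        f[:, 1] = mag * uy
        fields.append(f)

    if latent_dim >= 3:
        # 3: facet gap (pads move apart)
        f = np.zeros((n, 3))
        for side in ("left", "right"):
            f[geom.pad_node_sets[side]["upper"], 2] = +0.5
            f[geom.pad_node_sets[side]["lower"], 2] = -0.5
        fields.append(f)

    if latent_dim >= 4:
        # 4: lordosis-like sagittal shear
        f = np.zeros((n, 3))
        f[:, 0] = zc
        fields.append(f)

    # 5+: lateral cosine harmonics with even axial frequency.  Equal end
    # values and even symmetry make every analytic response feature exactly
    # invariant (zero response coefficient by design), and keep the fields
    # orthogonal to the rigid rotations on the symmetric phantom grid.
    for m in range(1, latent_dim - 3):
        f = np.zeros((n, 3))
        axis = (m - 1) % 2  # alternate x / y
        freq = 2 * ((m + 1) // 2)
        f[:, axis] = np.cos(freq * np.pi * nodes[:, 2] / TOTAL_HEIGHT)
        f[geom.node_ring < 0] = 0.0  # pads untouched
        fields.append(f)

    fields = np.asarray(fields[:latent_dim])
    n_named = min(latent_dim, 4)
    sidx = mesh.surface_index

    # Project out the similarity-transform algebra (3 translations,
    # 3 rotations, 1 isotropic scale) so Procrustes alignment cannot absorb
    # any part of a generative mode: the aligned-cohort eigenvalues then
    # equal the latent variances (up to noise) with modes matched 1:1.
    centroid = nodes[sidx].mean(axis=0)
    rel = nodes - centroid
    sim = [np.zeros((n, 3)) for _ in range(7)]
    for k in range(3):
        sim[k][:, k] = 1.0  # translations
    for k, (i, j) in enumerate(((1, 2), (2, 0), (0, 1))):
        sim[3 + k][:, i] = -rel[:, j]  # infinitesimal rotations
        sim[3 + k][:, j] = rel[:, i]
    sim[6] = rel.copy()  # isotropic scale

    basis_full, basis_flat = [], []

    def _push_basis(g_full, min_norm=1e-10):
        g_flat = flatten_points(g_full[sidx])
        g_full = g_full.copy()
        for b_full, b_flat in zip(basis_full, basis_flat):
            c = g_flat @ b_flat
            g_flat -= c * b_flat
            g_full -= c * b_full
        norm = np.linalg.norm(g_flat)
        if norm < min_norm:
            return None
        basis_full.append(g_full / norm)
        basis_flat.append(g_flat / norm)
        return basis_full[-1]

    def _project_off(f):
        f_flat = flatten_points(f[sidx])
        for b_full, b_flat in zip(basis_full, basis_flat):
            f -= (f_flat @ b_flat) * b_full

    for g in sim:
        _push_basis(g)

    out = []
    for k in range(n_named):
        f = fields[k].copy()
        _project_off(f)
        mode = _push_basis(f, min_norm=1e-12)
        if mode is None:
            raise RuntimeError("generative fields are linearly dependent")
        out.append(mode)

    if latent_dim > 4:
        # Harmonic modes must carry exactly zero analytic response; the
        # response features are linear functionals, so projecting their
        # gradient directions out of the harmonics enforces this exactly.
        for grad in _feature_gradient_fields(mesh, geom):
            _push_basis(grad)
        for k in range(n_named, latent_dim):
            f = fields[k].copy()
            _project_off(f)
            mode = _push_basis(f, min_norm=1e-12)
            if mode is None:
                raise RuntimeError("generative fields are linearly dependent")
            out.append(mode)

    return np.asarray(out)


def _feature_gradient_fields(mesh: VolumetricMesh, geom: PhantomGeometry) -> list:
    """Gradients of the four (linear) response features as node fields."""
    pos = geom.surface_positions
    sidx = mesh.surface_index
    grads = []

    def blank():
        return np.zeros_like(mesh.nodes)

    g = blank()  # height
    g[sidx[pos["top_face"]], 2] = 1.0 / len(pos["top_face"])
    g[sidx[pos["bottom_face"]], 2] = -1.0 / len(pos["bottom_face"])
    grads.append(g)

    g = blank()  # shear
    g[sidx[pos["top_face"]], 0] = 1.0 / len(pos["top_face"])
    g[sidx[pos["bottom_face"]], 0] = -1.0 / len(pos["bottom_face"])
    grads.append(g)

    g = blank()  # facet gap (mean of the two sides)
    for side in ("left", "right"):
        up = sidx[pos[f"pad_{side}_upper_bottom"]]
        lo = sidx[pos[f"pad_{side}_lower_top"]]
        g[up, 2] += 1.0 / (2 * len(up))
        g[lo, 2] -= 1.0 / (2 * len(lo))
    grads.append(g)

    # nucleus halfwidth: mean_i <p_i - c_plane(i), d_i> with per-plane
    # centroids c; the centroid term redistributes -mean(d) over each plane
    g = blank()
    ring = sidx[pos["interface_ring"]]
    dirs = pos["interface_ring_dirs"]
    plane = pos["interface_ring_plane"]
    n_ring = len(ring)
    n_planes = plane.max() + 1
    counts = np.bincount(plane, minlength=n_planes).astype(float)
    dir_sums = np.zeros((n_planes, 2))
    np.add.at(dir_sums, plane, dirs)
    coeff = (dirs - dir_sums[plane] / counts[plane, None]) / n_ring
    g[ring, 0] = coeff[:, 0]
    g[ring, 1] = coeff[:, 1]
    grads.append(g)
    return grads


# ---------------------------------------------------------------------------
# analytic responses


def _features(points: np.ndarray, positions: dict) -> dict:
    """Interpretable geometric features of a surface point set.

    All four features are *linear* functionals of the point coordinates
    (means, differences, and projections of the annulus-nucleus interface
    ring onto fixed reference radial directions), so the analytic responses
    are exactly linear in any superposed deformation field.
    """
    top = points[positions["top_face"]]
    bottom = points[positions["bottom_face"]]
    ring = points[positions["interface_ring"]]
    dirs = positions["interface_ring_dirs"]  # fixed unit xy directions
    plane = positions["interface_ring_plane"]  # ring nodes grouped by z-plane
    # per-plane centroids: whole-ring rigid shifts cancel exactly
    n_planes = plane.max() + 1
    sums = np.zeros((n_planes, 2))
    counts = np.bincount(plane, minlength=n_planes).astype(float)
    np.add.at(sums, plane, ring[:, :2])
    c = sums / counts[:, None]
    halfwidth = float(np.einsum("ij,ij->i", ring[:, :2] - c[plane], dirs).mean())
    gaps = []
    for side in ("left", "right"):
        up = points[positions[f"pad_{side}_upper_bottom"]][:, 2].mean()
        lo = points[positions[f"pad_{side}_lower_top"]][:, 2].mean()
        gaps.append(up - lo)
    return {
        "height": float(top[:, 2].mean() - bottom[:, 2].mean()),
        "nucleus_halfwidth": halfwidth,
        "facet_gap": float(np.mean(gaps)),
        "shear": float(top[:, 0].mean() - bottom[:, 0].mean()),
    }


def true_response(shape: CorrespondedShape, truth: GroundTruth):
    """Analytic (IDP-like, FCP-like) outcome of one corresponded shape, MPa."""
    feats = _features(shape.points, truth.surface_feature_positions)
    out = []
    for outcome in ("idp", "fcp"):
        coeffs = truth.response_coefficients[outcome]
        value = coeffs["intercept"]
        for name in FEATURE_NAMES:
            if name in coeffs:
                value += coeffs[name] * (feats[name] - truth.feature_refs[name])
        out.append(float(value))
    return tuple(out)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(spec: PhantomSpec):
    """Generate ``spec.t`` corresponded phantom subjects plus ground truth.

    Each subject is ``mean + sum_j w_ij * field_j + noise``, scaled about its
    centroid by a multiplicative size factor.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    mean_mesh, geom = build_mean_phantom(spec)
    fields = generative_fields(mean_mesh, geom, spec.latent_dim)
    k = spec.latent_dim
    sd = np.asarray(spec.latent_sd)

    weights = rng.standard_normal((spec.t, k)) * sd
    noise = (
        rng.standard_normal((spec.t,) + mean_mesh.nodes.shape) * spec.noise_sd
        if spec.noise_sd > 0
        else np.zeros((spec.t,) + mean_mesh.nodes.shape)
    )
    size_factors = np.exp(rng.standard_normal(spec.t) * spec.size_sd)

    # jitter the response coefficients (+-10%) so each cohort seed carries
    # its own, recorded, ground truth
    coefficients = {}
    for outcome, template in RESPONSE_TEMPLATE.items():
        coefficients[outcome] = {
            name: float(value * (1.0 + 0.1 * (2 * rng.random() - 1)))
            if name != "intercept"
            else float(value)
            for name, value in template.items()
        }

    refs = _features(mean_mesh.nodes[mean_mesh.surface_index], geom.surface_positions)

    shapes, meshes = [], []
    for i in range(spec.t):
        nodes = mean_mesh.nodes + np.tensordot(weights[i], fields, axes=1) + noise[i]
        centroid = nodes.mean(axis=0)
        nodes = centroid + size_factors[i] * (nodes - centroid)
        subject_id = f"subject_{i:03d}"
        mesh = mean_mesh.with_nodes(nodes, subject_id=subject_id)
        meshes.append(mesh)
        shapes.append(mesh.surface_shape())

    # linearised outcome sensitivities to each latent weight (central FD on
    # the actual feature/response functions)
    surface_fields = np.array(
        [flatten_points(f[mean_mesh.surface_index]) for f in fields]
    )
    truth = GroundTruth(
        latent_weights=weights,
        latent_sd=sd,
        surface_fields=surface_fields,
        response_coefficients=coefficients,
        latent_jacobian={},
        true_importance_ranking={},
        feature_refs=refs,
        surface_feature_positions=geom.surface_positions,
        seed=spec.seed,
    )
    base_points = mean_mesh.nodes[mean_mesh.surface_index]
    jac = {"idp": np.zeros(k), "fcp": np.zeros(k)}
    step = 1.0
    for j in range(k):
        delta = fields[j][mean_mesh.surface_index]
        hi = true_response(CorrespondedShape(base_points + step * delta), truth)
        lo = true_response(CorrespondedShape(base_points - step * delta), truth)
        jac["idp"][j] = (hi[0] - lo[0]) / (2 * step)
        jac["fcp"][j] = (hi[1] - lo[1]) / (2 * step)
    truth.latent_jacobian = jac
    truth.true_importance_ranking = {
        outcome: list(np.argsort(-np.abs(jac[outcome]) * sd, kind="stable"))
        for outcome in ("idp", "fcp")
    }
    return shapes, meshes, truth
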