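"""Template construction and thin-plate-spline volumetric mesh morphing.

The shape model only generates new positions for the surface points; the
interior nodes of the volumetric template are carried along by a 3-D
thin-plate-spline (TPS) deformation fitted on a fixed, randomly downsampled
set of surface control points.  The TPS uses the true 3-D biharmonic kernel
``U(r) = r`` plus an affine part; at zero regularisation it interpolates
the control points exactly and reproduces any affine map exactly at every
node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import CorrespondedShape, VolumetricMesh
from .ssm import rmse_between


class ThinPlateSpline(BaseEstimator, TransformerMixin):
    """3-D TPS interpolant between corresponded control point sets.

    ``fit(source, target)`` solves the standard augmented linear system

        [K + reg*I  P] [w]   [target]
        [P^T        0] [a] = [0]

    with ``K_ij = |c_i - c_j|`` and ``P = [1, x, y, z]``; ``transform``
    evaluates the deformation at arbitrary points.  The side conditions
    (kernel weights orthogonal to constants and coordinates) are implied by
    the lower block rows.
    """

    def __init__(self, regularisation: float = 0.0):
        self.regularisation = regularisation

    def fit(self, source: np.ndarray, target: np.ndarray):
        source = np.asarray(source, dtype=float)
        target = np.asarray(target, dtype=float)
        if source.shape != target.shape or source.ndim != 2 or source.shape[1] != 3:
            raise ValueError("source and target must both be (c, 3)")
        c = source.shape[0]
        if c < 4:
            raise ValueError("at least 4 control points are required")
        d = cdist(source, source)
        dup = np.argwhere((d + np.eye(c)) < 1e-9)
        if dup.size:
            i, j = dup[0]
            raise ValueError(
                f"duplicate control points {i} and {j} make the TPS system singular"
            )
        sv = np.linalg.svd(source - source.mean(axis=0), compute_uv=False)
        if sv[2] < 1e-9 * max(sv[0], 1.0):
            raise ValueError(
                "control points are coplanar; the 3-D TPS system is singular"
            )
        K = d + self.regularisation * np.eye(c)
        P = np.column_stack([np.ones(c), source])
        A = np.zeros((c + 4, c + 4))
        A[:c, :c] = K
        A[:c, c:] = P
        A[c:, :c] = P.T
        rhs = np.zeros((c + 4, 3))
        rhs[:c] = target
        try:
            sol = np.linalg.solve(A, rhs)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise ValueError(f"TPS system is singular: {exc}") from exc
        self.control_source_ = source
        self.control_target_ = target
        self.kernel_weights_ = sol[:c]
        self.affine_part_ = sol[c:]  # rows: [1, x, y, z] coefficients
        return self

    def transform(self, points: np.ndarray) -> np.ndarray:
        if not hasattr(self, "kernel_weights_"):
            raise RuntimeError("ThinPlateSpline is not fitted")
        points = np.asarray(points, dtype=float)
        U = cdist(points, self.control_source_)
        P = np.column_stack([np.ones(points.shape[0]), points])
        return U @ self.kernel_weights_ + P @ self.affine_part_


def tps_fit(source: np.ndarray, target: np.ndarray,
            regularisation: float = 0.0) -> ThinPlateSpline:
    """Functional wrapper over :class:`ThinPlateSpline`."""
    return ThinPlateSpline(regularisation=regularisation).fit(source, target)


def build_template(volumes: list, transforms: list,
                   subject_id: str = "template") -> VolumetricMesh:
    """Mean volumetric mesh after mapping every subject into the aligned frame.

    The Procrustes transforms estimated on the surfaces are re-applied to
    *all* nodes of each subject's volumetric mesh; the template is the
    per-node arithmetic mean with the shared connectivity carried over.
    """
    if len(volumes) != len(transforms):
        raise ValueError("one transform per volume is required")
    if not volumes:
        raise ValueError("no volumes given")
    ref = volumes[0]
    for v in volumes[1:]:
        if not np.array_equal(v.hexahedra, ref.hexahedra):
            raise ValueError("volumes do not share element connectivity")
        if v.n_nodes != ref.n_nodes:
            raise ValueError("volumes do not share node count")
    mean_nodes = np.mean(
        [t.apply(v.nodes) for v, t in zip(volumes, transforms)], axis=0
    )
    return ref.with_nodes(mean_nodes, subject_id=subject_id)


def select_control_points(p: int, c: int, seed: int = 0) -> np.ndarray:
    """Draw ``c`` distinct surface-point indices, fixed for a pipeline run."""
    if c > p:
        raise ValueError(f"cannot select {c} control points from {p} surface points")
    if c == p:
        return np.arange(p)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(p, size=c, replace=False))


@dataclass
class MorphReport:
    """Surface fidelity and element quality of one morphed subject."""

    surface_rmse: float
    surface_max_error: float
    control_rmse: float
    inverted_fraction: float


def morph(template: VolumetricMesh, field: ThinPlateSpline,
          subject_id: str = "") -> VolumetricMesh:
    """Map every node of the template through a fitted TPS field."""
    return template.with_nodes(field.transform(template.nodes), subject_id=subject_id)


def morph_to_surface(
    template: VolumetricMesh,
    target_surface: CorrespondedShape,
    control_indices: np.ndarray | None = None,
    regularisation: float = 0.0,
):
    """Morph the template so its surface matches an SSM-generated surface.

    Fits the TPS on the selected control points (template surface as
    source, target surface as target), morphs all nodes, and reports the
    achieved surface RMSE over *all* surface points plus the fraction of
    hexahedra with non-positive corner Jacobians.
    """
    from .mechanics import corner_jacobians  # local import avoids cycle

    template_surface = template.nodes[template.surface_index]
    if target_surface.n_points != template_surface.shape[0]:
        raise ValueError("target surface point count does not match the template")
    if control_indices is None:
        control_indices = np.arange(template_surface.shape[0])
    control_indices = np.asarray(control_indices)
    field = tps_fit(
        template_surface[control_indices],
        target_surface.points[control_indices],
        regularisation=regularisation,
    )
    morphed = morph(template, field, subject_id=target_surface.subject_id)
    achieved = CorrespondedShape(
        morphed.nodes[morphed.surface_index], target_surface.subject_id
    )
    err = np.linalg.norm(achieved.points - target_surface.points, axis=1)
    ctrl_err = err[control_indices]
    det = corner_jacobians(morphed)
    report = MorphReport(
        surface_rmse=rmse_between(achieved, target_surface),
        surface_max_error=float(err.max()),
        control_rmse=float(np.sqrt(np.mean(ctrl_err**2))),
        inverted_fraction=float(np.mean(det.min(axis=1) <= 0.0)),
    )
    return morphed, report
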