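"""Generalised Procrustes alignment of corresponded shapes.

Shapes are aligned to a reference subject (by default the first) with a
similarity transform: rotation, translation and, optionally, scaling.
Reflections are forbidden — anatomy must not mirror.  The per-subject
transforms are retained so they can later be re-applied to the full
volumetric meshes when building the mean template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .geometry import CorrespondedShape


@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.scale = float(self.scale)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if self.translation.shape != (3,):
            raise ValueError("translation must be a 3-vector")
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-10):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("reflections are not allowed (det must be +1)")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls(np.eye(3), np.zeros(3), 1.0)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return self.scale * points @ self.rotation.T + self.translation

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation + self.translation,
            scale=self.scale * other.scale,
        )

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]), d["scale"])


@dataclass
class AlignedCohort:
    """Aligned shapes plus the transforms that produced them."""

    shapes: list
    transforms: list
    reference_id: str

    def __len__(self) -> int:
        return len(self.shapes)

    def save_transforms(self, path) -> None:
        payload = {
            "reference_id": self.reference_id,
            "transforms": [
                {"subject_id": s.subject_id, **t.to_dict()}
                for s, t in zip(self.shapes, self.transforms)
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _check_nondegenerate(points: np.ndarray, name: str) -> None:
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] < 1e-12 or sv[1] < 1e-9 * sv[0]:
        raise ValueError(
            f"{name} point set is degenerate (collinear or coincident points); "
            "a rotation cannot be determined"
        )


def procrustes_fit(
    source: CorrespondedShape,
    target: CorrespondedShape,
    with_scaling: bool = True,
):
    """Least-squares similarity transform mapping ``source`` onto ``target``.

    Rotation via the Kabsch/orthogonal-Procrustes solution with the
    determinant corrected to +1 (no reflections); scaling, when enabled,
    matches the source centroid size to the target centroid size.  Returns
    the transform and the per-point RMSE of the transformed source against
    the target.
    """
    if source.n_points != target.n_points:
        raise ValueError(
            f"point counts differ: {source.n_points} vs {target.n_points}"
        )
    if source.n_points < 3:
        raise ValueError("at least 3 points are required")
    src = source.points
    tgt = target.points
    _check_nondegenerate(src, "source")
    _check_nondegenerate(tgt, "target")

    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    src_c, tgt_c = src - mu_s, tgt - mu_t
    scale = float(np.linalg.norm(tgt_c) / np.linalg.norm(src_c)) if with_scaling else 1.0

    H = src_c.T @ tgt_c
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T

    translation = mu_t - scale * R @ mu_s
    transform = SimilarityTransform(R, translation, scale)
    residual = transform.apply(src) - tgt
    rmse = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return transform, rmse


def align_cohort(
    shapes: list,
    reference: int | str = 0,
    with_scaling: bool = True,
    iterative: bool = False,
    max_iter: int = 10,
    tol: float = 1e-10,
) -> AlignedCohort:
    """Align every shape of a cohort to a reference subject.

    Single-pass alignment to the reference (left untouched) is the default.
    ``iterative=True`` switches to classical generalised Procrustes analysis
    against an evolving mean.
    """
    if len(shapes) < 2:
        raise ValueError("at least 2 shapes are required")
    counts = {s.n_points for s in shapes}
    if len(counts) != 1:
        raise ValueError(f"shapes have mismatched point counts: {sorted(counts)}")
    if isinstance(reference, str):
        ids = [s.subject_id for s in shapes]
        if reference not in ids:
            raise ValueError(f"reference subject {reference!r} not in cohort")
        ref_idx = ids.index(reference)
    else:
        ref_idx = int(reference)
    ref = shapes[ref_idx]

    aligned, transforms = [], []
    for i, shape in enumerate(shapes):
        if i == ref_idx:
            transform = SimilarityTransform.identity()
        else:
            transform, _ = procrustes_fit(shape, ref, with_scaling=with_scaling)
        aligned.append(
            CorrespondedShape(transform.apply(shape.points), shape.subject_id)
        )
        transforms.append(transform)

    if iterative:
        for _ in range(max_iter):
            mean = CorrespondedShape(
                np.mean([s.points for s in aligned], axis=0), "mean"
            )
            shift = 0.0
            for i, shape in enumerate(shapes):
                transform, _ = procrustes_fit(shape, mean, with_scaling=with_scaling)
                new_points = transform.apply(shape.points)
                shift = max(shift, float(np.abs(new_points - aligned[i].points).max()))
                aligned[i] = CorrespondedShape(new_points, shape.subject_id)
                transforms[i] = transform
            if shift < tol:
                break

    return AlignedCohort(
        shapes=aligned, transforms=transforms, reference_id=ref.subject_id
    )


class ProcrustesAligner(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`align_cohort`.

    ``fit`` learns the reference shape from a training cohort; ``transform``
    maps shapes (a list of :class:`CorrespondedShape` or an ``(t, p, 3)``
    array) into the reference frame.
    """

    def __init__(self, reference: int | str = 0, with_scaling: bool = True,
                 iterative: bool = False):
        self.reference = reference
        self.with_scaling = with_scaling
        self.iterative = iterative

    @staticmethod
    def _as_shapes(X) -> list:
        if isinstance(X, np.ndarray):
            if X.ndim != 3 or X.shape[2] != 3:
                raise ValueError("array input must be (t, p, 3)")
            return [CorrespondedShape(pts, f"subject_{i}") for i, pts in enumerate(X)]
        return list(X)

    def fit(self, X, y=None):
        shapes = self._as_shapes(X)
        cohort = align_cohort(
            shapes,
            reference=self.reference,
            with_scaling=self.with_scaling,
            iterative=self.iterative,
        )
        self.cohort_ = cohort
        if self.iterative:
            self.reference_shape_ = CorrespondedShape(
                np.mean([s.points for s in cohort.shapes], axis=0), "mean"
            )
        else:
            idx = [s.subject_id for s in cohort.shapes].index(cohort.reference_id)
            self.reference_shape_ = cohort.shapes[idx]
        return self

    def transform(self, X):
        if not hasattr(self, "reference_shape_"):
            raise RuntimeError("ProcrustesAligner is not fitted")
        shapes = self._as_shapes(X)
        out = []
        for shape in shapes:
            t, _ = procrustes_fit(
                shape, self.reference_shape_, with_scaling=self.with_scaling
            )
            out.append(CorrespondedShape(t.apply(shape.points), shape.subject_id))
        return out
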