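"""Core geometric containers shared across the pipeline.

A cohort is a set of *corresponded* meshes: every subject has the same
number of nodes with identical element connectivity, and node ``k`` lies on
the same anatomical feature in every subject.  The shape model operates on
an ordered subset of the nodes (the anatomical surfaces plus the internal
annulus-nucleus and endplate-nucleus interfaces); the volumetric mesh keeps
the full node set for finite-element work.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: All element structure labels of the L4/L5 functional-spinal-unit model.
STRUCTURES = (
    "cancellous",
    "cortical",
    "annulus_layer_1",
    "annulus_layer_2",
    "annulus_layer_3",
    "annulus_layer_4",
    "annulus_layer_5",
    "annulus_layer_6",
    "annulus_layer_7",
    "nucleus",
    "cep_upper",
    "cep_lower",
    "facet_cartilage_left",
    "facet_cartilage_right",
)

ANNULUS_LAYERS = tuple(f"annulus_layer_{i}" for i in range(1, 8))
FACET_STRUCTURES = ("facet_cartilage_left", "facet_cartilage_right")


def flatten_points(points: np.ndarray) -> np.ndarray:
    """Flatten a ``(p, 3)`` point array to ``[x_1..x_p, y_1..y_p, z_1..z_p]``."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError(f"expected (p, 3) points, got {points.shape}")
    return points.T.ravel()


def unflatten_points(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_points`."""
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size % 3:
        raise ValueError(f"expected a 3p vector, got shape {vector.shape}")
    return vector.reshape(3, -1).T


@dataclass
class CorrespondedShape:
    """Ordered surface point set of one subject (coordinates in mm).

    Point ordering is identical across all subjects of a cohort, which is
    what makes pointwise statistics (Procrustes, PCA) meaningful.
    """

    points: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (p, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("shape contains non-finite coordinates")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def as_vector(self) -> np.ndarray:
        return flatten_points(self.points)

    @classmethod
    def from_vector(cls, vector: np.ndarray, subject_id: str = "") -> "CorrespondedShape":
        return cls(points=unflatten_points(vector), subject_id=subject_id)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    @property
    def centroid_size(self) -> float:
        """Root sum of squared distances from the centroid (Procrustes size)."""
        return float(np.linalg.norm(self.points - self.centroid))

    def copy(self) -> "CorrespondedShape":
        return CorrespondedShape(self.points.copy(), self.subject_id)


@dataclass
class VolumetricMesh:
    """Hexahedral mesh with per-element structure labels.

    ``surface_index`` maps the ordered shape-model surface points into node
    indices: ``nodes[surface_index]`` is the subject's
    :class:`CorrespondedShape` point array.
    """

    nodes: np.ndarray
    hexahedra: np.ndarray
    structure_label: np.ndarray
    surface_index: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.hexahedra = np.asarray(self.hexahedra, dtype=np.int64)
        self.structure_label = np.asarray(self.structure_label, dtype=object)
        self.surface_index = np.asarray(self.surface_index, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (N, 3)")
        if self.hexahedra.ndim != 2 or self.hexahedra.shape[1] != 8:
            raise ValueError("hexahedra must be (E, 8)")
        if self.structure_label.shape[0] != self.hexahedra.shape[0]:
            raise ValueError("one structure label per element is required")
        if self.hexahedra.size and (
            self.hexahedra.min() < 0 or self.hexahedra.max() >= len(self.nodes)
        ):
            raise ValueError("element connectivity references missing nodes")
        if self.surface_index.size and (
            self.surface_index.min() < 0 or self.surface_index.max() >= len(self.nodes)
        ):
            raise ValueError("surface_index references missing nodes")
        unknown = set(map(str, self.structure_label)) - set(STRUCTURES)
        if unknown:
            raise ValueError(f"unknown structure labels: {sorted(unknown)}")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexahedra.shape[0]

    def surface_shape(self) -> CorrespondedShape:
        return CorrespondedShape(self.nodes[self.surface_index].copy(), self.subject_id)

    def elements_of(self, *labels: str) -> np.ndarray:
        """Element indices whose structure label is one of ``labels``."""
        mask = np.isin(self.structure_label.astype(str), labels)
        return np.flatnonzero(mask)

    def label_histogram(self) -> dict:
        labels, counts = np.unique(self.structure_label.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def with_nodes(self, nodes: np.ndarray, subject_id: str | None = None) -> "VolumetricMesh":
        """New mesh with replaced node positions; connectivity/labels shared."""
        return replace(
            self,
            nodes=np.asarray(nodes, dtype=float),
            subject_id=self.subject_id if subject_id is None else subject_id,
        )

    def copy(self) -> "VolumetricMesh":
        return VolumetricMesh(
            self.nodes.copy(),
            self.hexahedra.copy(),
            self.structure_label.copy(),
            self.surface_index.copy(),
            self.subject_id,
        )
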