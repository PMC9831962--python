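"""Shared fixtures: small phantom cohorts and simple box meshes."""

import numpy as np
import pytest

from spineshape.geometry import CorrespondedShape, VolumetricMesh
from spineshape.phantom import PhantomSpec, build_mean_phantom, generate_cohort


@pytest.fixture(scope="session")
def phantom_cohort():
    """Small, noisy phantom cohort shared by read-only tests."""
    spec = PhantomSpec(t=12, p=1300, latent_dim=4, seed=7)
    shapes, meshes, truth = generate_cohort(spec)
    return spec, shapes, meshes, truth


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Phantom cohort with zero noise and zero size spread (exact latent rank)."""
    spec = PhantomSpec(t=15, p=1300, latent_dim=3, seed=3, noise_sd=0.0, size_sd=0.0)
    shapes, meshes, truth = generate_cohort(spec)
    return spec, shapes, meshes, truth


@pytest.fixture(scope="session")
def mean_phantom():
    spec = PhantomSpec(t=5, p=1300, latent_dim=4, seed=0)
    mesh, geom = build_mean_phantom(spec)
    return mesh, geom


def make_box_mesh(nx=2, ny=2, nz=2, lengths=(10.0, 10.0, 10.0), label="cancellous"):
    """Axis-aligned structured box of hexahedra (for solver tests)."""
    xs = np.linspace(0, lengths[0], nx + 1)
    ys = np.linspace(0, lengths[1], ny + 1)
    zs = np.linspace(0, lengths[2], nz + 1)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return k * (ny + 1) * (nx + 1) + j * (nx + 1) + i

    hexes = [
        [nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
         nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
         nid(i, j + 1, k + 1)]
        for k in range(nz) for j in range(ny) for i in range(nx)
    ]
    labels = np.full(len(hexes), label, dtype=object)
    return VolumetricMesh(nodes, np.asarray(hexes), labels, np.arange(len(nodes)))


@pytest.fixture
def box_mesh():
    return make_box_mesh()


def random_shapes(t=8, p=20, seed=0, scale=5.0):
    """Generic random corresponded shapes (no phantom structure)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(p, 3)) * scale
    return [
        CorrespondedShape(base + rng.normal(size=(p, 3)), f"s{i}") for i in range(t)
    ]
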