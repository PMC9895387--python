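"""Synthetic cortical meshes and network atlases.

The source space is a triangulated sphere (icosphere) strictly inside the
innermost shell of the spherical head model, with one dipole per vertex
oriented along the outward surface normal.  The atlas partitions the
vertices into eight labelled patches by nearest seed direction -- a
stand-in geometry for the usual resting-state network parcellations
(seven cortical networks plus a deep-structure compartment), adequate for
planted-source recovery experiments though not anatomically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import trimesh

__all__ = ["CorticalMesh", "NetworkAtlas", "make_icosphere_mesh", "make_synthetic_atlas",
           "NETWORK_NAMES"]

NETWORK_NAMES = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default",
    "deep",
)

# seed directions (x right, y anterior, z superior); roughly: visual
# posterior-inferior, somatomotor superior, attention lateral, limbic
# inferior-anterior, frontoparietal lateral-frontal, default medial-frontal,
# deep inferior.
_SEEDS = np.array([
    [0.0, -1.0, -0.2],   # visual
    [0.0, 0.1, 1.0],     # somatomotor
    [0.7, -0.6, 0.5],    # dorsal attention
    [0.9, 0.2, -0.1],    # ventral attention
    [0.0, 0.6, -0.8],    # limbic
    [-0.9, 0.4, 0.3],    # frontoparietal
    [0.0, 0.9, 0.4],     # default
    [-0.5, -0.4, -0.8],  # deep
])


@dataclass
class CorticalMesh:
    """Vertex positions, unit normals, and binary vertex adjacency."""

    vertices: np.ndarray  # (V, 3)
    normals: np.ndarray  # (V, 3), unit rows
    adjacency: sp.csr_matrix  # (V, V) symmetric, zero diagonal

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        n = np.asarray(self.normals, dtype=float)
        if v.shape != n.shape or v.ndim != 2 or v.shape[1] != 3:
            raise ValueError("vertices/normals must both be (V, 3)")
        norms = np.linalg.norm(n, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit vectors")
        a = sp.csr_matrix(self.adjacency)
        if a.shape != (len(v), len(v)):
            raise ValueError("adjacency shape mismatch")
        if (abs(a - a.T)).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        self.vertices, self.normals, self.adjacency = v, n, a

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class NetworkAtlas:
    """Per-vertex network labels in 1..n_networks."""

    labels: np.ndarray  # (V,) int
    names: tuple[str, ...] = NETWORK_NAMES

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min() < 1 or self.labels.max() > len(self.names):
            raise ValueError("labels must lie in 1..n_networks")
        present = np.unique(self.labels)
        missing = set(range(1, len(self.names) + 1)) - set(present.tolist())
        if missing:
            raise ValueError(f"empty networks: {sorted(missing)}")

    @property
    def n_networks(self) -> int:
        return len(self.names)

    def vertices_of(self, network: int | str) -> np.ndarray:
        if isinstance(network, str):
            network = self.names.index(network) + 1
        return np.flatnonzero(self.labels == network)


def make_icosphere_mesh(subdivisions: int = 3, radius: float = 0.8) -> CorticalMesh:
    """Deterministic icosphere source space with radial dipole normals.

    ``subdivisions`` 2/3/4 give 162/642/2562 vertices.  The default radius
    keeps all dipoles strictly inside the innermost (brain) shell of the
    standard head model.
    """
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    v = np.asarray(m.vertices, dtype=float)
    normals = v / np.linalg.norm(v, axis=1, keepdims=True)
    edges = np.asarray(m.edges_unique)
    n = len(v)
    a = sp.coo_matrix(
        (np.ones(len(edges) * 2), (np.concatenate([edges[:, 0], edges[:, 1]]),
                                   np.concatenate([edges[:, 1], edges[:, 0]]))),
        shape=(n, n),
    ).tocsr()
    a.data[:] = 1.0
    return CorticalMesh(vertices=v, normals=normals, adjacency=a)


def make_synthetic_atlas(mesh: CorticalMesh, names: tuple[str, ...] = NETWORK_NAMES) -> NetworkAtlas:
    """Partition vertices by nearest seed direction (cosine similarity)."""
    seeds = _SEEDS[: len(names)]
    seeds = seeds / np.linalg.norm(seeds, axis=1, keepdims=True)
    u = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    labels = np.argmax(u @ seeds.T, axis=1) + 1
    return NetworkAtlas(labels=labels, names=names)
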