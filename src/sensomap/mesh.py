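"""Synthetic cortical source spaces.

A source space is a closed triangulated surface whose vertices carry
orientation-constrained current dipoles along the outward normal.  The
synthetic surface is a radially modulated ("wrinkled") sphere: on a perfect
sphere every outward normal is radial, and a radial dipole inside a spherical
conductor produces no external magnetic field, so a constrained source model
on an unperturbed sphere would be magnetically silent.  The low-order
spherical-harmonic bumps tilt the normals away from radial, mimicking the
folding that makes real cortical sources visible to MEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import trimesh
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.special import sph_harm_y


@dataclass
class SourceSpace:
    """Triangulated cortical surface with outward unit normals.

    Parameters
    ----------
    vertices : (n, 3) float array, metres, head frame.
    triangles : (m, 3) int array of vertex indices.
    normals : (n, 3) float array, outward unit normals (|n| = 1 +- 1e-6).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    normals: np.ndarray
    _adjacency: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self.normals = np.asarray(self.normals, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (m, 3)")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("normals must be unit length to 1e-6")
        adj = self.adjacency
        if (adj != adj.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        n_comp, _ = connected_components(adj, directed=False)
        if n_comp != 1:
            raise ValueError("mesh must be connected")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def adjacency(self) -> sp.csr_matrix:
        """First-order vertex adjacency (symmetric, boolean CSR)."""
        if self._adjacency is None:
            tri = self.triangles
            i = np.concatenate([tri[:, 0], tri[:, 1], tri[:, 2]])
            j = np.concatenate([tri[:, 1], tri[:, 2], tri[:, 0]])
            data = np.ones(i.size, dtype=np.int8)
            a = sp.coo_matrix((data, (i, j)), shape=(self.n_vertices,) * 2)
            a = a + a.T
            a.data[:] = 1
            a.setdiag(0)
            a.eliminate_zeros()
            self._adjacency = a.tocsr()
        return self._adjacency

    def graph_distance(self, source: int) -> np.ndarray:
        """Geodesic edge count from ``source`` to every vertex (BFS)."""
        d = dijkstra(self.adjacency, directed=False, unweighted=True,
                     indices=source)
        return d

    def nearest_vertices(self, center: int, k: int) -> np.ndarray:
        """``k`` vertices nearest to ``center`` in edge distance.

        Includes ``center`` itself; ties broken by lower vertex index.
        """
        d = self.graph_distance(center)
        order = np.lexsort((np.arange(self.n_vertices), d))
        return order[:k]


def make_cortical_mesh(subdivisions: int = 3, radius: float = 0.07,
                       bump_amplitude: float = 0.15,
                       bump_seed: int = 7) -> SourceSpace:
    """Build a wrinkled-sphere source space.

    Parameters
    ----------
    subdivisions : icosphere subdivision level (2 -> 162 vertices,
        3 -> 642, 4 -> 2562).
    radius : mean surface radius in metres (cortex sits well inside the
        ~0.09 m conductor sphere).
    bump_amplitude : relative radial modulation depth; 0 gives a perfect
        sphere (magnetically silent under the orientation constraint).
    bump_seed : seed for the fixed harmonic bump pattern.  This is surface
        geometry, not simulation randomness, so it is independent of any
        cohort seed.
    """
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    verts = np.asarray(base.vertices, dtype=float)
    faces = np.asarray(base.faces, dtype=np.int64)

    unit = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    theta = np.arccos(np.clip(unit[:, 2], -1, 1))
    phi = np.arctan2(unit[:, 1], unit[:, 0])

    rng = np.random.default_rng(bump_seed)
    f = np.zeros(len(verts))
    for ell in range(6, 11):
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            f += rng.normal(scale=1.0 / ell) * y.real
            if m > 0:
                f += rng.normal(scale=1.0 / ell) * y.imag
    if bump_amplitude > 0:
        f /= np.max(np.abs(f))
    r = radius * (1.0 + bump_amplitude * f)
    new_verts = unit * r[:, None]

    mesh = trimesh.Trimesh(vertices=new_verts, faces=faces, process=False)
    normals = np.asarray(mesh.vertex_normals, dtype=float)
    normals = normals / np.linalg.norm(normals, axis=1, keepdims=True)
    # enforce outward orientation regardless of face winding
    flip = np.sign(np.sum(normals * new_verts, axis=1))
    flip[flip == 0] = 1.0
    normals = normals * flip[:, None]
    return SourceSpace(new_verts, faces, normals)


def edge_distance(space: SourceSpace, a: int, b: int) -> int:
    """Geodesic edge count between two vertices."""
    return int(space.graph_distance(a)[b])
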