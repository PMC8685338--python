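"""Triangle-mesh data model, I/O, neighborhoods, areas, and geodesics.

Vertex indices are 0-based everywhere in memory. Coordinates are in mm
(RAS). Writers accept an ``index_base`` option where vertex indices are
emitted, because downstream tabular conventions differ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

log = logging.getLogger(__name__)

__all__ = [
    "TriangleMesh",
    "CortexMask",
    "MeshFormatError",
    "read_surface",
    "write_surface",
    "icosphere",
    "flat_grid",
    "kring_neighbors",
    "neighborhood_matrix",
    "vertex_areas",
    "geodesic_distances",
    "voxel_neighborhood_size",
]


class MeshFormatError(ValueError):
    """Raised when a surface file cannot be parsed as the named format."""


@dataclass(frozen=True)
class TriangleMesh:
    """Triangulated surface: ``vertices`` (V, 3) float mm, ``triangles`` (F, 3) int."""

    vertices: np.ndarray
    triangles: np.ndarray
    hemisphere: str = "none"  # "left" | "right" | "none"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        t = np.asarray(self.triangles, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshFormatError(f"vertices must be (V, 3), got {v.shape}")
        if t.ndim != 2 or t.shape[1] != 3:
            raise MeshFormatError(f"triangles must be (F, 3), got {t.shape}")
        if v.shape[0] == 0:
            raise MeshFormatError("empty mesh: no vertices")
        if t.size and (t.min() < 0 or t.max() >= v.shape[0]):
            raise MeshFormatError(
                f"triangle index out of range [0, {v.shape[0]}): "
                f"min={t.min()}, max={t.max()}"
            )
        if t.size and np.any(
            (t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])
        ):
            raise MeshFormatError("degenerate triangle with repeated vertex index")
        if self.hemisphere not in ("left", "right", "none"):
            raise ValueError(f"unknown hemisphere tag {self.hemisphere!r}")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with u < v."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self, weighted: bool = False) -> sp.csr_matrix:
        """Symmetric vertex adjacency; weights are Euclidean edge lengths if requested."""
        e = self.edges()
        if weighted:
            w = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)
        else:
            w = np.ones(len(e))
        a = sp.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([e[:, 0], e[:, 1]]),
                                      np.concatenate([e[:, 1], e[:, 0]]))),
            shape=(self.n_vertices, self.n_vertices),
        )
        return a.tocsr()

    def vertex_degrees(self) -> np.ndarray:
        a = self.adjacency()
        return np.asarray((a > 0).sum(axis=1)).ravel()

    def n_connected_components(self) -> int:
        n, _ = connected_components(self.adjacency(), directed=False)
        return int(n)

    def is_connected(self) -> bool:
        return self.n_connected_components() == 1

    def scaled(self, factor: float) -> "TriangleMesh":
        return TriangleMesh(self.vertices * factor, self.triangles, self.hemisphere)


@dataclass(frozen=True)
class CortexMask:
    """Boolean keep-flags per vertex; True marks a cortical (analyzed) vertex."""

    keep: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.keep, dtype=bool)
        if k.ndim != 1:
            raise ValueError("mask must be one-dimensional")
        if not k.any():
            raise ValueError("mask keeps no vertices")
        object.__setattr__(self, "keep", k)

    @classmethod
    def full(cls, n_vertices: int) -> "CortexMask":
        return cls(np.ones(n_vertices, dtype=bool))

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def matches(self, mesh: TriangleMesh) -> bool:
        return self.keep.shape[0] == mesh.n_vertices


# ---------------------------------------------------------------------------
# I/O

def read_surface(path: str | Path, fmt: str | None = None,
                 hemisphere: str = "none") -> TriangleMesh:
    """Read a surface mesh from FreeSurfer binary geometry or GIFTI ``.surf.gii``.

    ``fmt`` is ``"freesurfer"`` or ``"gifti"``; if None it is inferred from
    the suffix (``.gii`` -> gifti, else freesurfer).
    """
    import nibabel as nib

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "gifti" if path.suffix == ".gii" else "freesurfer"
    if fmt == "freesurfer":
        try:
            coords, faces = nib.freesurfer.read_geometry(str(path))
        except Exception as exc:  # nibabel raises bare ValueError on truncation
            raise MeshFormatError(
                f"{path}: not a readable FreeSurfer geometry file ({exc})"
            ) from exc
    elif fmt == "gifti":
        try:
            img = nib.load(str(path))
            coords = img.get_arrays_from_intent("NIFTI_INTENT_POINTSET")[0].data
            faces = img.get_arrays_from_intent("NIFTI_INTENT_TRIANGLE")[0].data
        except MeshFormatError:
            raise
        except IndexError as exc:
            raise MeshFormatError(
                f"{path}: GIFTI file lacks a pointset or triangle array"
            ) from exc
        except Exception as exc:
            raise MeshFormatError(f"{path}: not a readable GIFTI file ({exc})") from exc
    else:
        raise ValueError(f"unknown surface format {fmt!r}")
    return TriangleMesh(np.asarray(coords, float), np.asarray(faces, np.int64),
                        hemisphere=hemisphere)


def write_surface(mesh: TriangleMesh, path: str | Path, fmt: str | None = None) -> None:
    """Write a mesh as FreeSurfer binary geometry or GIFTI ``.surf.gii``."""
    import nibabel as nib

    path = Path(path)
    if fmt is None:
        fmt = "gifti" if path.suffix == ".gii" else "freesurfer"
    if fmt == "freesurfer":
        nib.freesurfer.write_geometry(str(path), mesh.vertices, mesh.triangles)
    elif fmt == "gifti":
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.vertices.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        nib.save(img, str(path))
    else:
        raise ValueError(f"unknown surface format {fmt!r}")


# ---------------------------------------------------------------------------
# Construction

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array([
    [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
    [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
    [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
], dtype=float)
_ICO_FACES = np.array([
    [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
    [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
    [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
    [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
], dtype=np.int64)


def icosphere(subdivisions: int, radius: float = 1.0,
              hemisphere: str = "none") -> TriangleMesh:
    """Geodesic sphere from ``subdivisions`` rounds of icosahedron 4-splitting.

    V = 10 * 4**s + 2 vertices; exactly 12 keep degree 5, the rest degree 6.
    Used as the synthetic stand-in for a standard average cortical surface.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    verts = _ICO_VERTS.copy()
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdivisions):
        verts, faces = _subdivide(verts, faces)
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangleMesh(verts * float(radius), faces, hemisphere=hemisphere)


def _subdivide(verts: np.ndarray, faces: np.ndarray):
    """Split every triangle into four; midpoint vertices are shared across faces."""
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e_sorted = np.sort(e, axis=1)
    uniq, inverse = np.unique(e_sorted, axis=0, return_inverse=True)
    mid = (verts[uniq[:, 0]] + verts[uniq[:, 1]]) / 2.0
    mid_idx = inverse.reshape(3, -1).T + len(verts)  # (F, 3): mids of 01, 12, 20
    new_verts = np.vstack([verts, mid])
    a, b, c = faces[:, 0], faces[:, 1], faces[:, 2]
    m01, m12, m20 = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    new_faces = np.vstack([
        np.column_stack([a, m01, m20]),
        np.column_stack([b, m12, m01]),
        np.column_stack([c, m20, m12]),
        np.column_stack([m01, m12, m20]),
    ])
    return new_verts, new_faces


def flat_grid(nx: int, ny: int, spacing: float = 1.0) -> TriangleMesh:
    """Planar right-triangulated grid in the z=0 plane; handy for kernel tests."""
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    verts = np.column_stack([xs.ravel() * spacing, ys.ravel() * spacing,
                             np.zeros(nx * ny)])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            v00 = i * ny + j
            v01 = v00 + 1
            v10 = v00 + ny
            v11 = v10 + 1
            faces.append([v00, v10, v01])
            faces.append([v01, v10, v11])
    return TriangleMesh(verts, np.array(faces, dtype=np.int64))


# ---------------------------------------------------------------------------
# Neighborhoods

def kring_neighbors(mesh: TriangleMesh, vertex: int, k: int = 1) -> set[int]:
    """Vertices at edge-graph distance in [1, k] from ``vertex`` (seed excluded).

    k=1 is the one-ring, k=2 the two-ring (18 vertices around a regular
    degree-6 vertex — the default neighborhood of the surface homogeneity
    statistic).
    """
    if not 0 <= vertex < mesh.n_vertices:
        raise IndexError(f"vertex {vertex} out of range [0, {mesh.n_vertices})")
    if k < 1:
        raise ValueError("k must be >= 1")
    adj = mesh.adjacency()
    frontier = {vertex}
    seen = {vertex}
    for _ in range(k):
        nxt: set[int] = set()
        for u in frontier:
            nxt.update(adj.indices[adj.indptr[u]:adj.indptr[u + 1]].tolist())
        frontier = nxt - seen
        seen |= frontier
        if not frontier:
            break
    seen.discard(vertex)
    return seen


def neighborhood_matrix(mesh: TriangleMesh, ring: int = 2,
                        include_self: bool = True) -> sp.csr_matrix:
    """Boolean (V, V) matrix whose row v flags {v} ∪ kring(v, ring).

    Built by boolean powers of the adjacency matrix; the backbone of the
    vectorized whole-surface homogeneity computation.
    """
    adj = (mesh.adjacency() > 0).astype(np.int8)
    reach = sp.identity(mesh.n_vertices, dtype=np.int8, format="csr")
    acc = sp.identity(mesh.n_vertices, dtype=np.int8, format="csr")
    for _ in range(ring):
        reach = (reach @ adj > 0).astype(np.int8)
        acc = (acc + reach > 0).astype(np.int8)
    if not include_self:
        acc = acc.tolil()
        acc.setdiag(0)
        acc = acc.tocsr()
        acc.eliminate_zeros()
    return acc.astype(np.float64)


def vertex_areas(mesh: TriangleMesh) -> np.ndarray:
    """Per-vertex area in mm²: one third of each incident triangle's area.

    Sums exactly to the total mesh surface area. Zero-area triangles
    contribute nothing (a warning is logged).
    """
    v = mesh.vertices
    t = mesh.triangles
    cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    n_degenerate = int((tri_area == 0).sum())
    if n_degenerate:
        log.warning("%d zero-area triangles contribute no vertex area", n_degenerate)
    areas = np.zeros(mesh.n_vertices)
    for col in range(3):
        np.add.at(areas, t[:, col], tri_area / 3.0)
    return areas


def geodesic_distances(mesh: TriangleMesh, seed: int,
                       cutoff: float) -> dict[int, float]:
    """Edge-graph Dijkstra distances (mm) from ``seed``, truncated at ``cutoff``.

    Edge weights are Euclidean lengths; vertices beyond the cutoff (or in
    other components) are simply absent from the returned map.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    if not 0 <= seed < mesh.n_vertices:
        raise IndexError(f"seed {seed} out of range [0, {mesh.n_vertices})")
    g = mesh.adjacency(weighted=True)
    d = dijkstra(g, directed=False, indices=seed, limit=cutoff)
    reachable = np.flatnonzero(np.isfinite(d))
    return {int(i): float(d[i]) for i in reachable}


def voxel_neighborhood_size(radius: int = 1, ndim: int = 3) -> int:
    """Lattice points within Chebyshev distance ``radius`` of a voxel, center excluded.

    The volumetric analogue of the surface neighborhoods: radius 1 in 3D
    gives the 26-voxel cube used by volume-based regional homogeneity.
    """
    if radius < 1 or ndim < 1:
        raise ValueError("radius and ndim must be >= 1")
    side = 2 * radius + 1
    return side**ndim - 1
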