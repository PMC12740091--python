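"""Per-vertex morphometrics on hippocampal-style triangle meshes.

Representations of one subject's hippocampal sheet (native, unfolded,
inner, outer, mid-thickness) share vertex indexing and face connectivity,
so cross-representation quantities (gyrification, thickness) are direct
per-vertex computations with no resampling.

Subfield labels follow the standard six-region parcellation: subiculum,
CA1–CA4 and dentate gyrus (DG).  Thickness is undefined for the DG, which
terminates the folded sheet and has no inner/outer pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix

__all__ = [
    "SUBFIELD_NAMES",
    "DG_LABEL",
    "SurfaceMesh",
    "vertex_areas",
    "boundary_vertices",
    "mean_curvature",
    "gyrification",
    "thickness",
    "sample_at_vertices",
]

SUBFIELD_NAMES = {1: "subiculum", 2: "CA1", 3: "CA2", 4: "CA3", 5: "CA4", 6: "DG"}
DG_LABEL = 6


@dataclass
class SurfaceMesh:
    """Triangulated surface with optional per-vertex labels and scalars."""

    vertices: np.ndarray  # (n, 3) world mm
    faces: np.ndarray  # (m, 3) vertex indices, consistent winding
    labels: np.ndarray | None = None  # per-vertex subfield id
    scalars: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(self.vertices):
                raise ValueError("labels length must match vertex count")
        areas = _face_areas(self.vertices, self.faces)
        if np.any(areas <= 0):
            raise ValueError(f"{int((areas <= 0).sum())} degenerate (zero-area) faces")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def same_topology(self, other: "SurfaceMesh") -> bool:
        return (
            self.n_vertices == other.n_vertices
            and self.faces.shape == other.faces.shape
            and np.array_equal(self.faces, other.faces)
        )


def _face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    e1 = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    e2 = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    return 0.5 * np.linalg.norm(np.cross(e1, e2), axis=1)


def vertex_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Barycentric per-vertex area: one third of incident face areas.

    Sums to the total mesh area (partition of unity)."""
    areas = _face_areas(mesh.vertices, mesh.faces)
    out = np.zeros(mesh.n_vertices)
    np.add.at(out, mesh.faces.ravel(), np.repeat(areas / 3.0, 3))
    return out


def boundary_vertices(mesh: SurfaceMesh) -> np.ndarray:
    """Boolean mask of vertices on an open boundary (incomplete one-ring)."""
    edges = np.sort(
        np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]),
        axis=1,
    )
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    out = np.zeros(mesh.n_vertices, dtype=bool)
    out[uniq[counts == 1].ravel()] = True
    return out


def _vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted outward vertex normals (outward for consistent
    counter-clockwise winding seen from outside)."""
    v, f = mesh.vertices, mesh.faces
    fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    out = np.zeros_like(v)
    for c in range(3):
        np.add.at(out, f[:, c], fn)
    norm = np.linalg.norm(out, axis=1)
    norm[norm == 0] = 1.0
    return out / norm[:, None]


def _mixed_voronoi_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Meyer et al. mixed Voronoi cell areas: true Voronoi area inside
    non-obtuse triangles, area/2 at the obtuse corner and area/4 at the
    others of obtuse triangles."""
    v, f = mesh.vertices, mesh.faces
    out = np.zeros(len(v))
    fa = _face_areas(v, f)
    for corner in range(3):
        i = f[:, corner]
        j = f[:, (corner + 1) % 3]
        k = f[:, (corner + 2) % 3]
        e_ij = v[j] - v[i]
        e_ik = v[k] - v[i]
        e_jk = v[k] - v[j]
        # cotangents of the angles opposite to edges from i
        cos_j = np.einsum("ij,ij->i", -e_ij, e_jk)
        sin_j = np.linalg.norm(np.cross(-e_ij, e_jk), axis=1)
        cot_j = cos_j / np.maximum(sin_j, 1e-300)  # angle at j, opposite edge ik
        cos_k = np.einsum("ij,ij->i", -e_ik, -e_jk)
        sin_k = np.linalg.norm(np.cross(-e_ik, -e_jk), axis=1)
        cot_k = cos_k / np.maximum(sin_k, 1e-300)  # angle at k, opposite edge ij
        cos_i = np.einsum("ij,ij->i", e_ij, e_ik)
        voronoi = ((e_ik**2).sum(1) * cot_j + (e_ij**2).sum(1) * cot_k) / 8.0
        obtuse_any = (cos_i < 0) | (cos_j < 0) | (cos_k < 0)
        contrib = np.where(
            obtuse_any, np.where(cos_i < 0, fa / 2.0, fa / 4.0), voronoi
        )
        np.add.at(out, i, contrib)
    return out


def _cotan_laplacian(mesh: SurfaceMesh):
    v, f = mesh.vertices, mesh.faces
    rows, cols, vals = [], [], []
    for corner in range(3):
        i = f[:, (corner + 1) % 3]
        j = f[:, (corner + 2) % 3]
        k = f[:, corner]  # apex opposite edge (i, j)
        u = v[i] - v[k]
        w = v[j] - v[k]
        cos_a = np.einsum("ij,ij->i", u, w)
        sin_a = np.linalg.norm(np.cross(u, w), axis=1)
        cot = cos_a / np.maximum(sin_a, 1e-300)
        rows.extend([i, j])
        cols.extend([j, i])
        vals.extend([0.5 * cot, 0.5 * cot])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    n = len(v)
    w_mat = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return w_mat


def mean_curvature(mesh: SurfaceMesh) -> np.ndarray:
    """Discrete mean curvature H = (k₁ + k₂)/2 in 1/mm.

    Cotangent Laplace–Beltrami applied to the coordinates with mixed
    Voronoi areas; the sign is taken against the outward vertex normal, so
    locally convex regions are positive.  Vertices with an incomplete
    one-ring (open boundary) are flagged NaN rather than silently computed.
    """
    w_mat = _cotan_laplacian(mesh)
    areas = _mixed_voronoi_areas(mesh)
    deg = np.asarray(w_mat.sum(axis=1)).ravel()
    # w_ij = (cot α + cot β)/2, so (Σ_j w_ij (x_i − x_j)) / (2 A_i) is half
    # the mean-curvature normal −Δx = 2 H n, i.e. exactly H·n
    kvec = (deg[:, None] * mesh.vertices - w_mat @ mesh.vertices) / (
        2.0 * np.maximum(areas, 1e-300)[:, None]
    )
    normals = _vertex_normals(mesh)
    h = np.einsum("ij,ij->i", kvec, normals)
    h[boundary_vertices(mesh)] = np.nan
    return h


def gyrification(
    native: SurfaceMesh, unfolded: SurfaceMesh
) -> np.ndarray:
    """Per-vertex ratio of native-space to unfolded-space barycentric area.

    A value above 1 marks folded regions compressed by the unfolding."""
    if not native.same_topology(unfolded):
        raise ValueError("native and unfolded meshes must share vertices and faces")
    a_native = vertex_areas(native)
    a_unfolded = vertex_areas(unfolded)
    if np.any(a_unfolded <= 0):
        raise ValueError("zero unfolded area at some vertices")
    return a_native / a_unfolded


def thickness(inner: SurfaceMesh, outer: SurfaceMesh) -> np.ndarray:
    """Euclidean distance between corresponding inner/outer vertices (mm).

    NaN for dentate-gyrus vertices, which have no two-layer structure."""
    if not inner.same_topology(outer):
        raise ValueError("inner and outer meshes must share vertices and faces")
    if (inner.labels is None) != (outer.labels is None):
        raise ValueError("labels present on only one representation")
    if inner.labels is not None and not np.array_equal(inner.labels, outer.labels):
        raise ValueError("labels differ between inner and outer representations")
    d = np.linalg.norm(inner.vertices - outer.vertices, axis=1)
    if inner.labels is not None:
        d = d.copy()
        d[inner.labels == DG_LABEL] = np.nan
    return d


def sample_at_vertices(
    volume: np.ndarray, affine: np.ndarray, mesh_or_vertices
) -> np.ndarray:
    """Trilinear sampling of a volumetric map at mesh vertices.

    Vertices are in world mm; the inverse affine maps them to (0-based)
    voxel coordinates.  Vertices outside the volume return NaN.
    """
    vertices = (
        mesh_or_vertices.vertices
        if isinstance(mesh_or_vertices, SurfaceMesh)
        else np.asarray(mesh_or_vertices, dtype=float)
    )
    inv = np.linalg.inv(affine)
    vox = (inv[:3, :3] @ vertices.T + inv[:3, 3:4])
    inside = np.all(
        (vox >= 0) & (vox <= (np.array(volume.shape[:3]) - 1)[:, None]), axis=0
    )
    out = np.full(len(vertices), np.nan)
    if np.any(inside):
        out[inside] = map_coordinates(
            np.asarray(volume, dtype=float), vox[:, inside], order=1, mode="nearest"
        )
    return out
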