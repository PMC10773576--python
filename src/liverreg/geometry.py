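"""Core geometric data model: meshes, labeled point clouds, rigid transforms.

All coordinates are millimetres in a single right-handed world frame; vertex,
face, node and tet indices are 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.spatial import cKDTree

#: Fixed vocabulary of anatomical point labels carried by sparse
#: intraoperative patterns: the bulk anterior surface plus the three salient
#: feature curves (falciform ligament, left and right inferior ridges).
FEATURE_LABELS = ("anterior", "falciform", "left_ridge", "right_ridge")

#: The subset of labels treated as salient features (matched patch-to-patch
#: by weighted registration); "anterior" points match the whole surface.
SALIENT_LABELS = ("falciform", "left_ridge", "right_ridge")

_ORTHO_TOL = 1e-9


class InvalidInputError(ValueError):
    """Raised when geometric inputs violate a documented precondition."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R @ x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if R.shape != (3, 3):
            raise InvalidInputError("rotation must be a 3x3 matrix")
        if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
            raise InvalidInputError("rotation matrix is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
            raise InvalidInputError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle: float, translation=None) -> "RigidTransform":
        """Rodrigues rotation about ``axis`` (normalized internally)."""
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise InvalidInputError("zero rotation axis")
        k = axis / n
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        return cls(R, t)

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        if M.shape != (4, 4):
            raise InvalidInputError("expected a 4x4 homogeneous matrix")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (n, 3) point array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform ``self o other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def apply_rigid(transform: RigidTransform, points: np.ndarray) -> np.ndarray:
    """Functional form of :meth:`RigidTransform.apply`."""
    if not isinstance(transform, RigidTransform):
        raise InvalidInputError("transform must be a RigidTransform")
    return transform.apply(points)


def sample_random_rigid(seed, translation_range: float = 100.0) -> RigidTransform:
    """Draw a random pose: uniform axis-angle rotation and uniform translation.

    The rotation axis is drawn componentwise uniform in [-1, 1] and
    normalized (zero draws are redrawn), the angle uniform in [0, 2*pi), and
    each translation component uniform in [-translation_range,
    translation_range] mm.  ``seed`` may be an int or a Generator.
    """
    rng = np.random.default_rng(seed)
    while True:
        axis = rng.uniform(-1.0, 1.0, size=3)
        if np.linalg.norm(axis) > 1e-12:
            break
    angle = rng.uniform(0.0, 2.0 * np.pi)
    t = rng.uniform(-translation_range, translation_range, size=3)
    return RigidTransform.from_axis_angle(axis, angle, t)


# ---------------------------------------------------------------------------
# Surface mesh
# ---------------------------------------------------------------------------


@dataclass
class TriSurfaceMesh:
    """Triangulated organ surface with optional named face regions.

    ``face_regions`` maps a region name (e.g. ``"anterior"``, ``"falciform"``)
    to an integer array of face indices belonging to that region.
    """

    vertices: np.ndarray
    faces: np.ndarray
    face_regions: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InvalidInputError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InvalidInputError("faces must be (m, 3)")
        if len(self.faces) == 0:
            raise InvalidInputError("mesh has no faces")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise InvalidInputError("face index out of range")
        if np.any(self.face_areas <= 0):
            raise InvalidInputError("mesh contains zero-area faces")
        for name, idx in self.face_regions.items():
            idx = np.asarray(idx, dtype=np.int64)
            if len(idx) and (idx.min() < 0 or idx.max() >= len(self.faces)):
                raise InvalidInputError(f"region {name!r} face index out of range")
            self.face_regions[name] = idx

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @cached_property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    @cached_property
    def face_normals(self) -> np.ndarray:
        tri = self.triangles
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    @cached_property
    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return 0.5 * np.linalg.norm(n, axis=1)

    @cached_property
    def face_centroids(self) -> np.ndarray:
        return self.triangles.mean(axis=1)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    @cached_property
    def _centroid_tree(self) -> cKDTree:
        return cKDTree(self.face_centroids)

    @cached_property
    def _max_face_radius(self) -> float:
        # max distance from a face centroid to its corners; used to bound
        # the candidate search in closest-point queries
        d = np.linalg.norm(self.triangles - self.face_centroids[:, None, :], axis=2)
        return float(d.max())

    def submesh(self, face_indices: np.ndarray) -> "TriSurfaceMesh":
        """Mesh restricted to the given faces (vertex array shared)."""
        face_indices = np.asarray(face_indices, dtype=np.int64)
        if len(face_indices) == 0:
            raise InvalidInputError("submesh with no faces")
        return TriSurfaceMesh(self.vertices, self.faces[face_indices])

    def region_submesh(self, name: str) -> "TriSurfaceMesh":
        if name not in self.face_regions or len(self.face_regions[name]) == 0:
            raise InvalidInputError(f"mesh has no face region {name!r}")
        return self.submesh(self.face_regions[name])

    def transformed(self, T: RigidTransform) -> "TriSurfaceMesh":
        return TriSurfaceMesh(T.apply(self.vertices), self.faces, dict(self.face_regions))

    def with_vertices(self, vertices: np.ndarray) -> "TriSurfaceMesh":
        return TriSurfaceMesh(vertices, self.faces, dict(self.face_regions))

    def as_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query.

    points: (n, 3); tri: (n, k, 3, 3).  Returns feet (n, k, 3).
    Solves the unconstrained barycentric projection and falls back to the
    three edge segments when the projection lies outside the triangle.
    """
    a, b, c = tri[..., 0, :], tri[..., 1, :], tri[..., 2, :]
    p = points[:, None, :]
    ab = b - a
    ac = c - a
    ap = p - a
    d00 = np.einsum("...i,...i", ab, ab)
    d01 = np.einsum("...i,...i", ab, ac)
    d11 = np.einsum("...i,...i", ac, ac)
    d20 = np.einsum("...i,...i", ap, ab)
    d21 = np.einsum("...i,...i", ap, ac)
    denom = d00 * d11 - d01 * d01
    denom = np.where(np.abs(denom) < 1e-300, 1.0, denom)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    inside = (v >= 0) & (w >= 0) & (v + w <= 1)
    foot_in = a + v[..., None] * ab + w[..., None] * ac

    def _seg(p0, p1):
        d = p1 - p0
        L2 = np.einsum("...i,...i", d, d)
        L2 = np.where(L2 < 1e-300, 1.0, L2)
        t = np.clip(np.einsum("...i,...i", p - p0, d) / L2, 0.0, 1.0)
        return p0 + t[..., None] * d

    feet_edges = np.stack([_seg(a, b), _seg(b, c), _seg(c, a)], axis=-2)
    d_edges = np.linalg.norm(feet_edges - p[..., None, :], axis=-1)
    best_edge = np.argmin(d_edges, axis=-1)
    foot_out = np.take_along_axis(
        feet_edges, best_edge[..., None, None], axis=-2
    )[..., 0, :]
    return np.where(inside[..., None], foot_in, foot_out)


def closest_point(query: np.ndarray, mesh: TriSurfaceMesh, k: int = 32):
    """Closest surface point(s) on a triangle mesh.

    Returns ``(feet, face_indices, normals, distances)``.  For a single
    3-vector query the leading axis is squeezed.  Candidate faces come from a
    KD-tree over face centroids; the exhaustive set is used whenever the
    pruning bound cannot certify the candidate answer.  Ties between
    equidistant faces resolve to the lowest face index.
    """
    q = np.atleast_2d(np.asarray(query, dtype=float))
    single = np.asarray(query).ndim == 1
    m = mesh.n_faces
    kq = min(k, m)
    _, cand = mesh._centroid_tree.query(q, k=kq)
    cand = np.atleast_2d(cand)
    feet = _closest_on_triangles(q, mesh.triangles[cand])
    d = np.linalg.norm(feet - q[:, None, :], axis=2)
    # lowest-face-index tie-break: argmin over (distance, face index)
    order = np.argsort(cand, axis=1)
    d_sorted = np.take_along_axis(d, order, axis=1)
    cand_sorted = np.take_along_axis(cand, order, axis=1)
    feet_sorted = np.take_along_axis(feet, order[:, :, None], axis=1)
    best = np.argmin(d_sorted, axis=1)
    rows = np.arange(len(q))
    best_d = d_sorted[rows, best]
    best_face = cand_sorted[rows, best]
    best_foot = feet_sorted[rows, best]

    if kq < m:
        # pruning certificate: any face with centroid further than
        # best_d + max_face_radius cannot beat the candidate.  Queries far
        # from the surface (several face radii away) skip the exhaustive
        # fallback: there the centroid candidates determine the closest face
        # up to a distance error of order R^2 / d, which is negligible.
        far_centroid = np.take_along_axis(
            np.linalg.norm(mesh.face_centroids[cand] - q[:, None, :], axis=2),
            np.full((len(q), 1), kq - 1),
            axis=1,
        )[:, 0]
        unsure = (far_centroid < best_d + mesh._max_face_radius) & (
            best_d <= 5.0 * mesh._max_face_radius
        )
        if np.any(unsure):
            qi = q[unsure]
            all_tri = np.broadcast_to(
                mesh.triangles[None], (len(qi),) + mesh.triangles.shape
            )
            feet_all = _closest_on_triangles(qi, all_tri)
            d_all = np.linalg.norm(feet_all - qi[:, None, :], axis=2)
            b = np.argmin(d_all, axis=1)  # argmin returns first (lowest) index
            r = np.arange(len(qi))
            best_d[unsure] = d_all[r, b]
            best_face[unsure] = b
            best_foot[unsure] = feet_all[r, b]

    normals = mesh.face_normals[best_face]
    if single:
        return best_foot[0], int(best_face[0]), normals[0], float(best_d[0])
    return best_foot, best_face, normals, best_d


# ---------------------------------------------------------------------------
# Volume mesh
# ---------------------------------------------------------------------------


@dataclass
class TetVolumeMesh:
    """Tetrahedral organ volume with an optional boundary surface map.

    ``surface`` is the boundary :class:`TriSurfaceMesh`;
    ``surface_vertex_map[i]`` gives the volume-node index of surface vertex
    ``i``.  ``tet_segments`` optionally carries per-tet anatomical segment
    ids (Couinaud-style stand-ins).
    """

    nodes: np.ndarray
    tets: np.ndarray
    surface: TriSurfaceMesh | None = None
    surface_vertex_map: np.ndarray | None = None
    tet_segments: np.ndarray | None = None

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise InvalidInputError("tets must be (m, 4)")
        if self.tets.min() < 0 or self.tets.max() >= len(self.nodes):
            raise InvalidInputError("tet node index out of range")
        # consistent orientation: swap two nodes of negatively oriented tets
        vol = self._signed_volumes()
        flip = vol < 0
        if np.any(flip):
            t = self.tets.copy()
            t[flip, 0], t[flip, 1] = self.tets[flip, 1], self.tets[flip, 0]
            self.tets = t
            vol = self._signed_volumes()
        if np.any(vol <= 0):
            raise InvalidInputError("degenerate (zero-volume) tetrahedron")

    def _signed_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ij,ij->i", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @cached_property
    def volumes(self) -> np.ndarray:
        return self._signed_volumes()

    @property
    def total_volume(self) -> float:
        return float(self.volumes.sum())

    @cached_property
    def centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    @cached_property
    def _edge_inverses(self) -> np.ndarray:
        """(m, 3, 3) inverse edge matrices used by linear-tet interpolation."""
        x = self.nodes[self.tets]
        D = np.stack([x[:, 1] - x[:, 0], x[:, 2] - x[:, 0], x[:, 3] - x[:, 0]], axis=2)
        return np.linalg.inv(D)


# ---------------------------------------------------------------------------
# Feature point cloud
# ---------------------------------------------------------------------------


@dataclass
class FeaturePointCloud:
    """Sparse intraoperative points with per-point anatomical labels."""

    points: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise InvalidInputError("points must be (n, 3)")
        if len(self.points) == 0:
            raise InvalidInputError("point cloud is empty")
        if len(self.labels) != len(self.points):
            raise InvalidInputError("one label per point required")
        bad = set(np.unique(self.labels)) - set(FEATURE_LABELS)
        if bad:
            raise InvalidInputError(f"unknown labels {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.points)

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def count(self, label: str) -> int:
        return int(np.count_nonzero(self.mask(label)))

    @property
    def label_counts(self) -> dict:
        return {lab: self.count(lab) for lab in FEATURE_LABELS if self.count(lab)}

    def subset(self, mask: np.ndarray) -> "FeaturePointCloud":
        return FeaturePointCloud(self.points[mask], self.labels[mask])

    def transformed(self, T: RigidTransform) -> "FeaturePointCloud":
        return FeaturePointCloud(T.apply(self.points), self.labels.copy())


# ---------------------------------------------------------------------------
# Surface-coverage extent
# ---------------------------------------------------------------------------


def default_alpha(points: np.ndarray) -> float:
    """Default coverage radius: 2.5x the median nearest-neighbour spacing."""
    pts = np.asarray(points, dtype=float)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    med = float(np.median(d[:, 1]))
    if med <= 0:
        raise InvalidInputError("degenerate point cloud (duplicate points)")
    return 2.5 * med


def data_extent(
    cloud: FeaturePointCloud | np.ndarray,
    mesh: TriSurfaceMesh,
    alpha: float | None = None,
) -> float:
    """Percentage of the organ surface area covered by the sparse pattern.

    A surface-projected alpha criterion is used: a face counts as covered
    when its centroid lies within ``alpha`` of some data point, and the
    extent is the covered area over the total area, in percent.  Monotone
    non-decreasing in the point set for fixed ``alpha``.
    """
    pts = cloud.points if isinstance(cloud, FeaturePointCloud) else np.asarray(cloud, float)
    if pts.ndim != 2 or len(pts) < 3:
        raise InvalidInputError("extent needs at least 3 points")
    if alpha is None:
        alpha = default_alpha(pts)
    if alpha <= 0:
        raise InvalidInputError("alpha must be positive")
    tree = cKDTree(pts)
    d, _ = tree.query(mesh.face_centroids, k=1)
    covered = d <= alpha
    return float(mesh.face_areas[covered].sum() / mesh.total_area * 100.0)
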