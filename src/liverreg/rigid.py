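"""Rigid registration comparators.

Three strategies are provided, mirroring the standard comparator ladder for
sparse-data organ registration:

* :func:`point_based_rigid` -- the optimal weighted point-based rigid
  registration between paired point sets (SVD / Kabsch solution), the best
  achievable rigid alignment when correspondences are known;
* :func:`icp` / :func:`icp_multistart` -- iterative closest point against a
  surface mesh; the multi-start wrapper stands in for manual initialization
  and re-initialization by trying a deterministic set of starting poses and
  keeping the best final fit;
* :func:`wicp` -- fully automatic salient-feature weighted ICP: labeled
  feature points (falciform ligament, inferior ridges) are matched only to
  their corresponding surface patches, with a feature weight that decays
  exponentially toward 1 over the iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    SALIENT_LABELS,
    FeaturePointCloud,
    InvalidInputError,
    RigidTransform,
    TriSurfaceMesh,
    closest_point,
)


@dataclass(frozen=True)
class Correspondence:
    """A single source-point-to-target pairing with a non-negative weight."""

    source_index: int
    target_point: np.ndarray
    weight: float = 1.0


@dataclass
class IcpConfig:
    """Iteration controls shared by ICP and wICP.

    ``feature_weight0`` and ``feature_decay`` define the wICP schedule
    ``w(k) = 1 + (w0 - 1) * decay**k``: features dominate early iterations
    and relax to ordinary closest-point weighting as the pose converges.
    """

    max_iterations: int = 100
    translation_tol: float = 1e-4  # mm change in translation
    rotation_tol: float = 1e-6  # radians change in rotation
    n_starts: int = 8
    feature_weight0: float = 10.0
    feature_decay: float = 0.9
    trim_fraction: float = 0.0  # optional distance-percentile rejection, off

    def __post_init__(self):
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")
        if self.translation_tol <= 0 or self.rotation_tol <= 0:
            raise InvalidInputError("convergence tolerances must be positive")
        if not (0.0 < self.feature_decay < 1.0):
            raise InvalidInputError("feature_decay must lie in (0, 1)")
        if not (0.0 <= self.trim_fraction < 1.0):
            raise InvalidInputError("trim_fraction must lie in [0, 1)")

    def feature_weight(self, iteration: int) -> float:
        return 1.0 + (self.feature_weight0 - 1.0) * self.feature_decay**iteration


@dataclass
class IcpResult:
    transform: RigidTransform
    rms: float
    n_iterations: int
    converged: bool
    rms_trace: list = field(default_factory=list)


def point_based_rigid(
    source: np.ndarray, target: np.ndarray, weights: np.ndarray | None = None
) -> RigidTransform:
    """Optimal (weighted) rigid registration between paired point sets.

    Returns the proper rigid transform minimizing
    ``sum_i w_i * ||R s_i + t - d_i||^2`` via the SVD of the weighted
    cross-covariance; a reflection branch is corrected by flipping the sign
    of the smallest singular direction.
    """
    s = np.asarray(source, dtype=float)
    d = np.asarray(target, dtype=float)
    if s.shape != d.shape or s.ndim != 2 or s.shape[1] != 3:
        raise InvalidInputError("source and target must be matching (n, 3) arrays")
    if weights is None:
        w = np.ones(len(s))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(s),) or np.any(w < 0) or not np.all(np.isfinite(w)):
            raise InvalidInputError("weights must be non-negative, one per pair")
    if np.count_nonzero(w) < 3:
        raise InvalidInputError("need at least 3 non-zero-weight pairs")
    wsum = w.sum()
    cs = (w[:, None] * s).sum(axis=0) / wsum
    cd = (w[:, None] * d).sum(axis=0) / wsum
    s0 = s - cs
    d0 = d - cd
    H = (w[:, None] * s0).T @ d0
    # collinearity check: a valid rigid solve needs rank >= 2 spread
    sv = np.linalg.svd(s0 * np.sqrt(w)[:, None], compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1e-300):
        raise InvalidInputError("source points are collinear (rigid pose ambiguous)")
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    t = cd - R @ cs
    return RigidTransform(R, t)


def _rms(values: np.ndarray, weights: np.ndarray | None = None) -> float:
    if weights is None:
        return float(np.sqrt(np.mean(values**2)))
    return float(np.sqrt(np.sum(weights * values**2) / np.sum(weights)))


def icp(
    cloud: FeaturePointCloud | np.ndarray,
    mesh: TriSurfaceMesh,
    init: RigidTransform | None = None,
    config: IcpConfig | None = None,
) -> IcpResult:
    """Iterative closest point registration of a point cloud to a mesh.

    Alternates closest-point correspondence with a full point-based rigid
    re-solve, so the RMS correspondence distance is non-increasing.
    """
    config = config or IcpConfig()
    pts = cloud.points if isinstance(cloud, FeaturePointCloud) else np.asarray(cloud, float)
    T = init or RigidTransform.identity()
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        moved = T.apply(pts)
        feet, _, _, dist = closest_point(moved, mesh)
        w = None
        if config.trim_fraction > 0:
            cutoff = np.quantile(dist, 1.0 - config.trim_fraction)
            w = (dist <= cutoff).astype(float)
        trace.append(_rms(dist, w))
        T_new = point_based_rigid(pts, feet, w)
        dT = T_new.compose(T.inverse())
        if (
            np.linalg.norm(dT.translation) < config.translation_tol
            and dT.rotation_angle() < config.rotation_tol
        ):
            T = T_new
            converged = True
            break
        T = T_new
    moved = T.apply(pts)
    _, _, _, dist = closest_point(moved, mesh)
    trace.append(_rms(dist))
    return IcpResult(T, trace[-1], it, converged, trace)


def _principal_axes(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    c = points.mean(axis=0)
    _, _, Vt = np.linalg.svd(points - c, full_matrices=False)
    V = Vt.T
    if np.linalg.det(V) < 0:
        V[:, 2] = -V[:, 2]
    return c, V


def multistart_poses(
    cloud_points: np.ndarray, mesh: TriSurfaceMesh, n_starts: int = 8
) -> list[RigidTransform]:
    """Deterministic initial poses: centroid alignment with axis flips plus
    principal-axis alignment with flips (up to 8 distinct proper rotations)."""
    cc, Vc = _principal_axes(cloud_points)
    cm, Vm = _principal_axes(mesh.vertices)
    rotations = [np.eye(3)]
    # 180-degree flips about world axes
    for ax in range(3):
        f = -np.eye(3)
        f[ax, ax] = 1.0
        rotations.append(f)
    # principal-axis alignment and its in-plane flips
    R_pca = Vm @ Vc.T
    rotations.append(R_pca)
    for ax in range(3):
        f = -np.eye(3)
        f[ax, ax] = 1.0
        rotations.append(Vm @ f @ Vc.T)
    poses = []
    for R in rotations[:n_starts]:
        t = cm - R @ cc
        poses.append(RigidTransform(R, t))
    return poses


def icp_multistart(
    cloud: FeaturePointCloud | np.ndarray,
    mesh: TriSurfaceMesh,
    config: IcpConfig | None = None,
) -> IcpResult:
    """ICP from a deterministic bank of starting poses; the run with the
    lowest final RMS wins.  Emulates manual initialization/re-initialization
    without interaction."""
    config = config or IcpConfig()
    pts = cloud.points if isinstance(cloud, FeaturePointCloud) else np.asarray(cloud, float)
    # coarse screening of the pose bank, then full refinement of the winner
    coarse = IcpConfig(
        max_iterations=min(30, config.max_iterations),
        translation_tol=config.translation_tol,
        rotation_tol=config.rotation_tol,
        trim_fraction=config.trim_fraction,
    )
    results = [
        icp(cloud, mesh, pose, coarse)
        for pose in multistart_poses(pts, mesh, config.n_starts)
    ]
    results.sort(key=lambda r: r.rms)
    # refine the two best coarse basins; they can swap rank after refinement
    refined = [icp(cloud, mesh, r.transform, config) for r in results[:2]]
    return min(refined, key=lambda r: r.rms)


def _feature_centroid_init(
    cloud: FeaturePointCloud, mesh: TriSurfaceMesh, present: list[str]
) -> RigidTransform:
    """Automatic coarse pose from salient-feature centroid pairings.

    Each labeled feature's point centroid is paired with the area centroid
    of the matching mesh patch; with three non-collinear features this
    resolves the global orientation without interaction.  Returns ``None``
    when fewer than three features are available (the caller then screens a
    deterministic pose bank instead).
    """
    src, dst = [], []
    for lab in present:
        m = cloud.mask(lab)
        src.append(cloud.points[m].mean(axis=0))
        faces = mesh.face_regions[lab]
        areas = mesh.face_areas[faces]
        dst.append((mesh.face_centroids[faces] * areas[:, None]).sum(axis=0)
                   / areas.sum())
    if len(src) >= 3:
        try:
            return point_based_rigid(np.asarray(src), np.asarray(dst))
        except InvalidInputError:
            pass
    return None


def wicp(
    cloud: FeaturePointCloud,
    mesh: TriSurfaceMesh,
    config: IcpConfig | None = None,
    init: RigidTransform | None = None,
) -> IcpResult:
    """Salient-feature weighted ICP.

    Points labeled with a salient feature are matched only against the
    same-label patch of the mesh, with weight ``w(k) = 1 + (w0-1)*decay**k``
    at iteration ``k``; anterior points match the whole surface with unit
    weight.  Fully automatic: the default start is centroid alignment.
    """
    if not isinstance(cloud, FeaturePointCloud):
        raise InvalidInputError("wicp requires a labeled FeaturePointCloud")
    config = config or IcpConfig()
    present = [lab for lab in SALIENT_LABELS if cloud.count(lab)]
    if not present:
        raise InvalidInputError("wicp needs at least one salient-feature point")
    patches = {}
    for lab in present:
        if lab not in mesh.face_regions or len(mesh.face_regions[lab]) == 0:
            raise InvalidInputError(f"mesh is missing feature patch {lab!r}")
        patches[lab] = mesh.region_submesh(lab)

    pts = cloud.points
    if init is None:
        init = _feature_centroid_init(cloud, mesh, present)
        if init is None:
            # not enough features for a centroid pose: screen the same
            # deterministic pose bank used by multistart ICP, keeping the
            # feature weighting, and refine the best coarse fit
            coarse = IcpConfig(
                max_iterations=min(20, config.max_iterations),
                translation_tol=config.translation_tol,
                rotation_tol=config.rotation_tol,
                feature_weight0=config.feature_weight0,
                feature_decay=config.feature_decay,
            )
            best = None
            for pose in multistart_poses(pts, mesh, config.n_starts):
                r = wicp(cloud, mesh, coarse, init=pose)
                if best is None or r.rms < best.rms:
                    best = r
            init = best.transform
    T = init
    anterior_mask = cloud.mask("anterior")
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        moved = T.apply(pts)
        feet = np.empty_like(pts)
        dist = np.empty(len(pts))
        weights = np.ones(len(pts))
        if np.any(anterior_mask):
            f, _, _, d = closest_point(moved[anterior_mask], mesh)
            feet[anterior_mask] = f
            dist[anterior_mask] = d
        wk = config.feature_weight(it - 1)
        for lab in present:
            m = cloud.mask(lab)
            f, _, _, d = closest_point(moved[m], patches[lab])
            feet[m] = f
            dist[m] = d
            weights[m] = wk
        trace.append(_rms(dist, weights))
        T_new = point_based_rigid(pts, feet, weights)
        dT = T_new.compose(T.inverse())
        if (
            np.linalg.norm(dT.translation) < config.translation_tol
            and dT.rotation_angle() < config.rotation_tol
            and wk - 1.0 <= 0.05 * (config.feature_weight0 - 1.0 + 1e-12)
        ):
            T = T_new
            converged = True
            break
        T = T_new
    moved = T.apply(pts)
    _, _, _, dist = closest_point(moved, mesh)
    trace.append(_rms(dist))
    return IcpResult(T, trace[-1], it, converged, trace)
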