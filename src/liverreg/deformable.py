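"""Deformable registration by Kelvinlet boundary-condition reconstruction.

The registration estimates the surface loads that, under the analytic
Kelvinlet elastic model, best explain a sparse intraoperative point cloud.
The objective is a weighted least-squares cost over the data features plus a
strain-energy penalty,

    C(f, t, theta) = sum_F (w_F / N_F) sum_i d_i^2  +  w_E * fE^2,

where ``d_i`` is the model-to-data error of point ``i`` in feature ``F``
(signed surface-normal distance for bulk anterior points, same-patch
closest-point distance for salient features), and ``fE`` is the strain
energy of the nonrigid field normalized by (shear modulus x organ volume) so
that it is dimensionless (a mean-squared-strain scale).  Kelvinlet force
vectors and the rigid pose (translation + axis-angle rotation, composed left
of the nonrigid field) are optimized concurrently in a Levenberg-Marquardt
loop with exactly re-evaluated acceptance, so the reported objective trace
is non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import DisplacementField
from .geometry import (
    SALIENT_LABELS,
    FeaturePointCloud,
    InvalidInputError,
    RigidTransform,
    TetVolumeMesh,
    TriSurfaceMesh,
    closest_point,
)
from .kelvinlet import (
    DeformationParameters,
    KelvinletControlSet,
    evaluate_nonrigid,
)


@dataclass
class ObjectiveConfig:
    """Weights and optimizer controls for the reconstruction objective."""

    feature_weights: dict = field(
        default_factory=lambda: {lab: 1.0 for lab in
                                 ("anterior",) + SALIENT_LABELS}
    )
    energy_weight: float = 1000.0
    residual_model: dict = field(
        default_factory=lambda: {"anterior": "normal",
                                 **{lab: "closest_point" for lab in SALIENT_LABELS}}
    )
    max_iterations: int = 100
    objective_tol: float = 1e-6  # relative objective change
    lm_damping0: float = 1e-3
    lm_factor: float = 10.0
    max_damping_retries: int = 8

    def __post_init__(self):
        if any(w < 0 for w in self.feature_weights.values()):
            raise InvalidInputError("feature weights must be non-negative")
        if not any(w > 0 for w in self.feature_weights.values()):
            raise InvalidInputError("at least one feature weight must be positive")
        if self.energy_weight < 0:
            raise InvalidInputError("energy weight must be non-negative")
        if self.max_iterations < 1:
            raise InvalidInputError("max_iterations must be >= 1")


@dataclass
class RegistrationResult:
    """Outcome of a deformable registration run."""

    parameters: DeformationParameters
    displacement_field: DisplacementField
    objective_trace: list
    converged: bool
    n_iterations: int

    @property
    def final_objective(self) -> float:
        return self.objective_trace[-1]


def _rotvec_to_matrix(w: np.ndarray) -> np.ndarray:
    theta = np.linalg.norm(w)
    if theta < 1e-300:
        return np.eye(3)
    k = w / theta
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def _matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.from_matrix(R).as_rotvec()


class _Correspondences:
    """Frozen per-point correspondence data for one linearization."""

    __slots__ = ("ref_feet", "directions", "distances", "scales")

    def __init__(self, ref_feet, directions, distances, scales):
        self.ref_feet = ref_feet  # (n, 3) on the *reference* surface
        self.directions = directions  # (n, 3) unit vectors, intraop frame
        self.distances = distances  # (n,) current model-data distances
        self.scales = scales  # (n,) sqrt(w_F / N_F)


def _reference_feet(surface: TriSurfaceMesh, deformed_vertices: np.ndarray,
                    query: np.ndarray, faces_subset=None):
    """Closest points on the deformed surface, pulled back to reference
    coordinates via the barycentric coordinates of the foot in its face."""
    if faces_subset is None:
        mesh_def = TriSurfaceMesh(deformed_vertices, surface.faces)
        faces = surface.faces
    else:
        mesh_def = TriSurfaceMesh(deformed_vertices, surface.faces[faces_subset])
        faces = surface.faces[faces_subset]
    feet, fidx, normals, dist = closest_point(np.atleast_2d(query), mesh_def)
    tri_def = deformed_vertices[faces[fidx]]
    tri_ref = surface.vertices[faces[fidx]]
    # barycentric coords of the foot in the deformed face
    v0 = tri_def[:, 1] - tri_def[:, 0]
    v1 = tri_def[:, 2] - tri_def[:, 0]
    v2 = feet - tri_def[:, 0]
    d00 = np.einsum("ij,ij->i", v0, v0)
    d01 = np.einsum("ij,ij->i", v0, v1)
    d11 = np.einsum("ij,ij->i", v1, v1)
    d20 = np.einsum("ij,ij->i", v2, v0)
    d21 = np.einsum("ij,ij->i", v2, v1)
    denom = np.maximum(d00 * d11 - d01 * d01, 1e-300)
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    ref = (
        tri_ref[:, 0]
        + v[:, None] * (tri_ref[:, 1] - tri_ref[:, 0])
        + w[:, None] * (tri_ref[:, 2] - tri_ref[:, 0])
    )
    return ref, feet, normals, dist


def _build_correspondences(
    surface: TriSurfaceMesh,
    deformed_vertices: np.ndarray,
    data: FeaturePointCloud,
    config: ObjectiveConfig,
) -> _Correspondences:
    n = len(data)
    ref_feet = np.zeros((n, 3))
    directions = np.zeros((n, 3))
    distances = np.zeros(n)
    scales = np.zeros(n)
    for lab in np.unique(data.labels):
        w_f = config.feature_weights.get(lab, 1.0)
        mask = data.mask(lab)
        nf = int(np.count_nonzero(mask))
        if nf == 0 or w_f == 0.0:
            continue
        subset = None
        if lab in SALIENT_LABELS and lab in surface.face_regions \
                and len(surface.face_regions[lab]):
            subset = surface.face_regions[lab]
        ref, feet, normals, dist = _reference_feet(
            surface, deformed_vertices, data.points[mask], subset
        )
        model = config.residual_model.get(lab, "closest_point")
        if model == "normal":
            direction = normals
            signed = np.einsum("ij,ij->i", data.points[mask] - feet, normals)
            distances[mask] = signed
        else:
            gap = data.points[mask] - feet
            norm = np.linalg.norm(gap, axis=1)
            direction = np.where(
                norm[:, None] > 1e-12, gap / np.maximum(norm, 1e-300)[:, None], normals
            )
            distances[mask] = norm
        ref_feet[mask] = ref
        directions[mask] = direction
        scales[mask] = np.sqrt(w_f / nf)
    return _Correspondences(ref_feet, directions, distances, scales)


class _EnergyModel:
    """Precomputed quadratic form: strain energy = 0.5 f^T Q f.

    ``f`` is the stacked (3m,) force vector.  The energy used in the
    objective is normalized by (shear modulus x mesh volume).
    """

    def __init__(self, controls: KelvinletControlSet, mesh: TetVolumeMesh,
                 chunk: int = 512):
        m = len(controls)
        lam = controls.material.lame_lambda
        mu = controls.material.shear_modulus
        Q = np.zeros((3 * m, 3 * m))
        eye = np.eye(3)
        for lo in range(0, mesh.n_tets, chunk):
            hi = min(lo + chunk, mesh.n_tets)
            cent = mesh.centroids[lo:hi]
            vol = mesh.volumes[lo:hi]
            G = controls.gradient_tensors(cent)  # (e, m, 3, 3, 3)
            Gsym = 0.5 * (G + np.swapaxes(G, 2, 3))
            S = Gsym.transpose(0, 2, 3, 1, 4).reshape(hi - lo, 9, 3 * m)
            T = np.einsum("emiik->emk", Gsym).reshape(hi - lo, 3 * m)
            Sw = (S * np.sqrt(vol)[:, None, None]).reshape(-1, 3 * m)
            Tw = T * np.sqrt(vol)[:, None]
            Q += 2.0 * mu * (Sw.T @ Sw)
            Q += lam * (Tw.T @ Tw)
        self.Q = Q
        self.norm = mu * mesh.total_volume

    def energy(self, f: np.ndarray) -> float:
        """Normalized (dimensionless) strain energy."""
        return float(0.5 * f @ (self.Q @ f)) / self.norm

    def energy_gradient(self, f: np.ndarray) -> np.ndarray:
        return (self.Q @ f) / self.norm


def residuals(
    params: DeformationParameters,
    controls: KelvinletControlSet,
    mesh: TriSurfaceMesh,
    data: FeaturePointCloud,
    config: ObjectiveConfig | None = None,
    volume: TetVolumeMesh | None = None,
) -> np.ndarray:
    """Scaled residual vector whose squared norm equals the objective C.

    One entry ``sqrt(w_F/N_F) * d_i`` per data point plus, when an energy
    weight and volume mesh are given, one entry ``sqrt(w_E) * fE``.
    """
    config = config or ObjectiveConfig()
    deformed = _deformed_vertices(params, controls, mesh)
    corr = _build_correspondences(mesh, deformed, data, config)
    r = corr.scales * corr.distances
    if config.energy_weight > 0 and volume is not None:
        from .kelvinlet import strain_energy

        mu = controls.material.shear_modulus
        fE = strain_energy(params, controls, volume) / (mu * volume.total_volume)
        r = np.append(r, np.sqrt(config.energy_weight) * fE)
    return r


def objective_value(*args, **kwargs) -> float:
    """Objective C = ||residuals||^2."""
    r = residuals(*args, **kwargs)
    return float(r @ r)


def _deformed_vertices(
    params: DeformationParameters, controls: KelvinletControlSet,
    mesh: TriSurfaceMesh,
) -> np.ndarray:
    u_nl = evaluate_nonrigid(controls, params.forces, mesh.vertices)
    T = params.rigid_transform()
    return T.apply(mesh.vertices + u_nl)


def register_deformable(
    surface: TriSurfaceMesh,
    volume: TetVolumeMesh,
    data: FeaturePointCloud,
    init: RigidTransform | None = None,
    controls: KelvinletControlSet | None = None,
    config: ObjectiveConfig | None = None,
) -> RegistrationResult:
    """Reconstruct boundary loads and pose from a sparse labeled pattern.

    ``init`` (e.g. a wICP result) seeds the rigid parameters; forces start
    at zero.  Returns the dense displacement field over the volume nodes
    (rigid composed with nonrigid), the fitted parameters, and the objective
    trace of accepted Levenberg-Marquardt steps.
    """
    from .kelvinlet import build_control_set

    config = config or ObjectiveConfig()
    controls = controls or build_control_set(surface)
    m = len(controls)
    energy_model = _EnergyModel(controls, volume) if config.energy_weight > 0 else None

    R = np.eye(3) if init is None else init.rotation.copy()
    t = np.zeros(3) if init is None else init.translation.copy()
    f = np.zeros(3 * m)

    def pack_params() -> DeformationParameters:
        return DeformationParameters(
            f.reshape(m, 3), t.copy(), _matrix_to_rotvec(R)
        )

    def full_objective(Rc, tc, fc):
        u_nl = evaluate_nonrigid(controls, fc.reshape(m, 3), surface.vertices)
        deformed = (surface.vertices + u_nl) @ Rc.T + tc
        corr = _build_correspondences(surface, deformed, data, config)
        C = float(np.sum((corr.scales * corr.distances) ** 2))
        if energy_model is not None:
            fE = energy_model.energy(fc)
            C += config.energy_weight * fE**2
        return C, corr

    C, corr = full_objective(R, t, f)
    trace = [C]
    lam = config.lm_damping0
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        # --- linearize about the current state with frozen correspondences
        x_c = corr.ref_feet
        u_nl_c = evaluate_nonrigid(controls, f.reshape(m, 3), x_c)
        y = (x_c + u_nl_c) @ R.T  # model points minus translation
        n_pts = len(x_c)
        A = controls.response_matrices(x_c)  # (n, m, 3, 3)
        uhat = corr.directions
        uR = uhat @ R  # R^T u per point
        # residual r_i = uhat . (d_i - m_i);  dr/dp = -uhat . dm/dp
        J_f = -np.einsum("ni,nmij->nmj", uR, A).reshape(n_pts, 3 * m)
        J_t = -uhat
        J_w = np.cross(uhat, y)  # dm/domega = -[y]x (left-perturbed rotation)
        J = np.concatenate([J_w, J_t, J_f], axis=1) * corr.scales[:, None]
        r = corr.scales * corr.distances
        if energy_model is not None:
            fE = energy_model.energy(f)
            gE = energy_model.energy_gradient(f)
            rowE = np.concatenate(
                [np.zeros(6), np.sqrt(config.energy_weight) * gE]
            )
            J = np.vstack([J, rowE])
            r = np.append(r, np.sqrt(config.energy_weight) * fE)

        # --- scaled damped normal equations
        JtJ = J.T @ J
        g = J.T @ r
        scale = np.sqrt(np.maximum(np.diag(JtJ), 1e-12))
        accepted = False
        for _ in range(config.max_damping_retries + 1):
            Aeq = JtJ / np.outer(scale, scale) + lam * np.eye(len(scale))
            try:
                delta = -np.linalg.solve(Aeq, g / scale) / scale
            except np.linalg.LinAlgError:
                lam *= config.lm_factor
                continue
            R_try = _rotvec_to_matrix(delta[:3]) @ R
            t_try = t + delta[3:6]
            f_try = f + delta[6:]
            C_try, corr_try = full_objective(R_try, t_try, f_try)
            if C_try < C:
                R, t, f = R_try, t_try, f_try
                C, corr = C_try, corr_try
                lam = max(lam / config.lm_factor, 1e-12)
                accepted = True
                break
            lam *= config.lm_factor
        if not accepted:
            break
        trace.append(C)
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) <= \
                config.objective_tol * max(trace[-2], 1e-300):
            converged = True
            break

    params = pack_params()
    u_nodes = evaluate_nonrigid(controls, params.forces, volume.nodes)
    total = (volume.nodes + u_nodes) @ R.T + t - volume.nodes
    return RegistrationResult(
        parameters=params,
        displacement_field=DisplacementField(total),
        objective_trace=trace,
        converged=converged,
        n_iterations=it,
    )
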