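"""Displacement fields on tet meshes and their differential measures.

A displacement field is stored nodewise; linear (P1) interpolation over each
tetrahedron yields a constant displacement gradient per element, from which
the Green strain norm and the deformation Jacobian determinant are computed
elementwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import InvalidInputError, TetVolumeMesh


@dataclass
class DisplacementField:
    """Per-node displacement vectors (mm), ordered like the mesh nodes."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise InvalidInputError("displacement values must be (n, 3)")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("displacement field contains non-finite values")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ElementGradientSet:
    """Per-element displacement gradient tensors du_i/dx_j (dimensionless)."""

    tensors: np.ndarray

    def __post_init__(self):
        self.tensors = np.ascontiguousarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise InvalidInputError("gradients must be (m, 3, 3)")
        if not np.all(np.isfinite(self.tensors)):
            raise InvalidInputError("gradient set contains non-finite values")

    def __len__(self) -> int:
        return len(self.tensors)


def element_displacement_gradients(
    mesh: TetVolumeMesh, field: DisplacementField
) -> ElementGradientSet:
    """Constant per-tet gradient of the P1 interpolant of a nodal field."""
    if len(field) != mesh.n_nodes:
        raise InvalidInputError("field length does not match mesh node count")
    u = field.values[mesh.tets]
    dU = np.stack([u[:, 1] - u[:, 0], u[:, 2] - u[:, 0], u[:, 3] - u[:, 0]], axis=2)
    # u(x) = u0 + dU @ Dinv @ (x - x0)  =>  grad = dU @ Dinv
    grads = dU @ mesh._edge_inverses
    return ElementGradientSet(grads)


def green_strain_tensors(grads: ElementGradientSet) -> np.ndarray:
    """Green-Lagrange strain E = (grad u + grad u^T + grad u^T grad u) / 2."""
    G = grads.tensors
    return 0.5 * (G + np.swapaxes(G, 1, 2) + np.einsum("eki,ekj->eij", G, G))


def green_strain_norm(grads: ElementGradientSet, norm: str = "spectral") -> np.ndarray:
    """Per-element norm of the rotation-invariant Green strain tensor.

    ``norm`` selects the matrix L2 norm flavour: ``"spectral"`` (induced
    2-norm; for the symmetric strain this is the largest absolute
    eigenvalue) or ``"frobenius"``.
    """
    E = green_strain_tensors(grads)
    if norm == "spectral":
        w = np.linalg.eigvalsh(E)
        return np.abs(w).max(axis=1)
    if norm == "frobenius":
        return np.linalg.norm(E, axis=(1, 2))
    raise InvalidInputError(f"unknown matrix norm {norm!r}")


def jacobian_determinant(grads: ElementGradientSet) -> np.ndarray:
    """Per-element |J| = det(grad u + I): the local volume-change factor."""
    F = grads.tensors + np.eye(3)
    return np.linalg.det(F)


def locate_points(
    mesh: TetVolumeMesh, points: np.ndarray, k: int = 32, tol: float = 1e-9
):
    """Find the containing tet (and barycentric coords) for each point.

    Points outside every tet are assigned to the element with the least
    barycentric violation (nearest-element extrapolation) and reported in
    the returned ``outside`` mask.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    tree = cKDTree(mesh.centroids)
    kq = min(k, mesh.n_tets)
    _, cand = tree.query(pts, k=kq)
    cand = np.atleast_2d(cand)
    n = len(pts)
    tet_ids = np.empty(n, dtype=np.int64)
    bary = np.empty((n, 4))
    outside = np.zeros(n, dtype=bool)
    inv = mesh._edge_inverses
    x = mesh.nodes[mesh.tets]
    for i in range(n):
        c = cand[i]
        local = np.einsum("tij,tj->ti", inv[c], pts[i] - x[c, 0])
        lam = np.column_stack([1.0 - local.sum(axis=1), local])
        worst = lam.min(axis=1)
        j = int(np.argmax(worst))
        if worst[j] < -tol:
            # fall back to exhaustive search before declaring outside
            local_all = np.einsum("tij,tj->ti", inv, pts[i] - x[:, 0])
            lam_all = np.column_stack([1.0 - local_all.sum(axis=1), local_all])
            worst_all = lam_all.min(axis=1)
            j_all = int(np.argmax(worst_all))
            tet_ids[i] = j_all
            bary[i] = lam_all[j_all]
            outside[i] = worst_all[j_all] < -tol
        else:
            tet_ids[i] = c[j]
            bary[i] = lam[j]
    return tet_ids, bary, outside


def interpolate_displacement(
    mesh: TetVolumeMesh,
    field: DisplacementField,
    targets: np.ndarray,
    outside_tol: float = 1e-6,
) -> np.ndarray:
    """Linear barycentric interpolation of a nodal field at target points.

    Targets marginally outside the mesh (surface round-off) are extrapolated
    from the nearest element with a warning.
    """
    if len(field) != mesh.n_nodes:
        raise InvalidInputError("field length does not match mesh node count")
    pts = np.atleast_2d(np.asarray(targets, dtype=float))
    tet_ids, bary, _ = locate_points(mesh, pts, tol=outside_tol)
    n_out = int(np.count_nonzero(bary.min(axis=1) < -outside_tol))
    if n_out:
        warnings.warn(
            f"{n_out} target(s) outside the tet mesh; extrapolating from the "
            "nearest element",
            stacklevel=2,
        )
    u = field.values[mesh.tets[tet_ids]]
    out = np.einsum("pk,pki->pi", bary, u)
    return out if np.asarray(targets).ndim == 2 else out[0]
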