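"""P1 finite-element assembly on a :class:`~invasim.meshing.TriMesh`.

The weak form of the dispersal equation with zero-flux boundaries produces
the semi-discrete system

    M du/dt + A u + B u = F(u),

with mass, stiffness and transport matrices

    M_ij = int phi_j phi_i,
    A_ij = int (nu grad phi_j) . grad phi_i,
    B_ij = int (b . grad phi_j) phi_i,

and the nonlinear reaction load F_i(u) = int (gamma - u_h) u_h phi_i
(+ int f phi_i for an external source).

Quadrature choices: P1 products in M are integrated exactly by the closed
form (|T|/12) [[2,1,1],[1,2,1],[1,1,2]]; nu and b are sampled at element
centroids (gradients of P1 basis functions are constant per element, so a
one-point rule is exact whenever the coefficient is); the reaction integrand
is cubic when gamma and u are P1 fields, so a 4-point degree-3 triangle rule
integrates it exactly.  The mass matrix is consistent by default; a lumped
(row-sum) variant is available for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .errors import CoefficientError, DimensionError, GeometryError
from .meshing import TriMesh

# degree-3 rule on the reference triangle: exact for cubic polynomials
_Q_BARY = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [0.6, 0.2, 0.2],
        [0.2, 0.6, 0.2],
        [0.2, 0.2, 0.6],
    ]
)
_Q_W = np.array([-27 / 48, 25 / 48, 25 / 48, 25 / 48])


def _geometry(mesh: TriMesh):
    """Areas and constant P1 basis gradients per triangle.

    Returns ``(areas (M,), grads (M, 3, 2))`` where ``grads[e, k]`` is the
    gradient of the basis function of local vertex k on element e.
    """
    p = mesh.nodes[mesh.triangles]
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    areas = 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])
    tiny = np.abs(areas) < 1e-14
    if tiny.any():
        k = int(np.argmax(tiny))
        raise GeometryError(f"degenerate triangle {k} (area {areas[k]:.3e})")
    grads = np.empty((len(areas), 3, 2))
    for k in range(3):
        pj = p[:, (k + 1) % 3]
        pk = p[:, (k + 2) % 3]
        grads[:, k, 0] = (pj[:, 1] - pk[:, 1]) / (2 * areas)
        grads[:, k, 1] = (pk[:, 0] - pj[:, 0]) / (2 * areas)
    return areas, grads


def _scatter(mesh: TriMesh, elem: np.ndarray) -> sp.csr_matrix:
    """Accumulate per-element 3x3 blocks into a global CSR matrix."""
    t = mesh.triangles
    rows = np.repeat(t, 3, axis=1).ravel()
    cols = np.tile(t, (1, 3)).ravel()
    mat = sp.coo_matrix(
        (elem.ravel(), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    )
    return mat.tocsr()


def _centroid_scalar(mesh: TriMesh, spec, t: float) -> np.ndarray:
    """Coefficient value per element centroid.

    Accepts a scalar, a nodal array (averaged to centroids — exact for P1
    data) or a callable ``f(points, t)`` evaluated at centroids.
    """
    centroids = mesh.nodes[mesh.triangles].mean(axis=1)
    if callable(spec):
        return np.asarray(spec(centroids, t), dtype=float)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return np.full(mesh.n_triangles, float(arr))
    if arr.shape == (mesh.n_nodes,):
        return arr[mesh.triangles].mean(axis=1)
    raise DimensionError(f"cannot interpret scalar coefficient of shape {arr.shape}")


def _centroid_vector(mesh: TriMesh, spec, t: float) -> np.ndarray:
    centroids = mesh.nodes[mesh.triangles].mean(axis=1)
    if callable(spec):
        return np.asarray(spec(centroids, t), dtype=float).reshape(mesh.n_triangles, 2)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return np.full((mesh.n_triangles, 2), float(arr))
    if arr.shape == (2,):
        return np.broadcast_to(arr, (mesh.n_triangles, 2)).copy()
    if arr.shape == (mesh.n_nodes, 2):
        return arr[mesh.triangles].mean(axis=1)
    raise DimensionError(f"cannot interpret vector coefficient of shape {arr.shape}")


def _nodal_scalar(mesh: TriMesh, spec, t: float) -> np.ndarray:
    if callable(spec):
        return np.asarray(spec(mesh.nodes, t), dtype=float)
    arr = np.asarray(spec, dtype=float)
    if arr.ndim == 0:
        return np.full(mesh.n_nodes, float(arr))
    if arr.shape == (mesh.n_nodes,):
        return arr
    raise DimensionError(f"cannot interpret nodal coefficient of shape {arr.shape}")


def assemble_mass(mesh: TriMesh, lumped: bool = False) -> sp.csr_matrix:
    """Mass matrix; element block (|T|/12) [[2,1,1],[1,2,1],[1,1,2]]."""
    areas, _ = _geometry(mesh)
    base = np.array([[2.0, 1.0, 1.0], [1.0, 2.0, 1.0], [1.0, 1.0, 2.0]]) / 12.0
    elem = areas[:, None, None] * base[None]
    M = _scatter(mesh, elem)
    if lumped:
        M = sp.diags(np.asarray(M.sum(axis=1)).ravel()).tocsr()
    return M


def assemble_stiffness(mesh: TriMesh, nu, t: float = 0.0) -> sp.csr_matrix:
    """Stiffness matrix with the diffusivity sampled at element centroids."""
    areas, grads = _geometry(mesh)
    nu_c = _centroid_scalar(mesh, nu, t)
    if (nu_c < 0).any():
        k = int(np.argmax(nu_c < 0))
        raise CoefficientError(f"negative diffusivity {nu_c[k]:.3e} at element {k}")
    gg = np.einsum("eid,ejd->eij", grads, grads)
    elem = (nu_c * areas)[:, None, None] * gg
    return _scatter(mesh, elem)


def assemble_transport(mesh: TriMesh, b, t: float = 0.0) -> sp.csr_matrix:
    """Transport matrix; b at centroids, int_T phi_i = |T|/3 exactly."""
    areas, grads = _geometry(mesh)
    b_c = _centroid_vector(mesh, b, t)
    bg = np.einsum("ed,ejd->ej", b_c, grads)  # b . grad phi_j per element
    elem = (areas / 3.0)[:, None, None] * np.broadcast_to(
        bg[:, None, :], (mesh.n_triangles, 3, 3)
    )
    return _scatter(mesh, elem)


def reaction_load(mesh: TriMesh, u: np.ndarray, gamma, f=0.0, t: float = 0.0) -> np.ndarray:
    """Nonlinear load F_i = int (gamma - u_h) u_h phi_i + int f phi_i.

    gamma and f are interpolated to P1 nodal fields; the resulting cubic
    integrand is integrated by the 4-point degree-3 rule.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (mesh.n_nodes,):
        raise DimensionError(f"state length {u.shape} != number of nodes {mesh.n_nodes}")
    areas, _ = _geometry(mesh)
    g_nodal = _nodal_scalar(mesh, gamma, t)
    f_nodal = _nodal_scalar(mesh, f, t)
    t_idx = mesh.triangles
    u_q = u[t_idx] @ _Q_BARY.T          # (M, 4) values at quadrature points
    g_q = g_nodal[t_idx] @ _Q_BARY.T
    f_q = f_nodal[t_idx] @ _Q_BARY.T
    integrand = (g_q - u_q) * u_q + f_q  # (M, 4)
    # contribution to local vertex k: sum_q w_q * integrand_q * lambda_k(q)
    local = np.einsum("mq,q,qk->mk", integrand, _Q_W, _Q_BARY) * areas[:, None]
    out = np.zeros(mesh.n_nodes)
    np.add.at(out, t_idx.ravel(), local.ravel())
    return out


@dataclass
class AssembledSystem:
    """Sparse operators of the semi-discrete system on one mesh."""

    M: sp.csr_matrix
    A: sp.csr_matrix
    B: sp.csr_matrix
    n_nodes: int
    symmetric: bool  # True when the transport matrix is exactly zero

    @classmethod
    def assemble(cls, mesh: TriMesh, coeffs, t: float = 0.0) -> "AssembledSystem":
        """Assemble M, A, B from a :class:`~invasim.coefficients.CoefficientSet`."""
        M = assemble_mass(mesh)
        A = assemble_stiffness(mesh, coeffs.nu_nodal(t), t)
        if coeffs.has_transport:
            B = assemble_transport(mesh, coeffs.b_nodal(t), t)
            symmetric = B.nnz == 0 or not np.any(B.data)
        else:
            B = sp.csr_matrix((mesh.n_nodes, mesh.n_nodes))
            symmetric = True
        return cls(M=M, A=A, B=B, n_nodes=mesh.n_nodes, symmetric=symmetric)


def lumped_areas(mesh: TriMesh) -> np.ndarray:
    """Row sums of the mass matrix: the area share owned by each node."""
    return np.asarray(assemble_mass(mesh).sum(axis=1)).ravel()
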