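"""Semi-implicit (IMEX) time integration of the dispersal model.

Each step solves

    (M + dt A + dt B) u^{n+1} = M u^n + dt F(u^n),

treating diffusion and transport implicitly and the nonlinear reaction
explicitly.  Without transport the system matrix is symmetric positive
definite and is solved by preconditioned conjugate gradients (incomplete-LU
preconditioner, relative residual 1e-10); with transport it is nonsymmetric
and BiCGStab is used under the same residual contract.  The matrix and its
preconditioner are factored once and reused across steps whenever the
coefficients are time independent.

Outputs are density snapshots at a configurable stride, per-probe time
series (P1 interpolation inside the containing triangle) and the nodal
arrival-time field: the first time the density crosses the threshold,
located by linear interpolation between the bracketing steps.  Nodes never
reaching the threshold keep the sentinel +inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .coefficients import CoefficientSet
from .errors import ConfigError, DimensionError, NumericalError, ParameterError
from .fem import AssembledSystem, reaction_load
from .meshing import TriMesh, locate_points

#: the conventional simulation step: 0.1 months expressed in years
DT_DEFAULT = 0.1 / 12.0
#: density threshold defining arrival
ARRIVAL_THRESHOLD = 1.0


@dataclass
class SimulationResult:
    """Densities, probe series and arrival times from one deterministic run."""

    times: np.ndarray                # snapshot times, years
    snapshots: np.ndarray            # (n_snapshots, n_nodes)
    arrival_time: np.ndarray         # per node, years; +inf if never reached
    probe_times: np.ndarray          # every step, years
    probes: dict[str, np.ndarray]    # name -> density series at probe_times
    dt: float
    threshold: float


def initial_condition(
    mesh: TriMesh,
    center: tuple[float, float],
    radius: float,
    amplitude: float = 10.0,
) -> np.ndarray:
    """Sharp circular colony: ``amplitude`` inside the circle, 0 outside."""
    if radius <= 0:
        raise ParameterError("colony radius must be positive")
    d = np.hypot(mesh.nodes[:, 0] - center[0], mesh.nodes[:, 1] - center[1])
    inside = d <= radius
    if not inside.any():
        raise ConfigError(
            f"no mesh node inside the colony circle (center {center}, radius {radius}); "
            "refine the mesh or enlarge the colony"
        )
    u0 = np.zeros(mesh.n_nodes)
    u0[inside] = amplitude
    return u0


class _LinearSolver:
    """Cached Krylov solve of (M + dt A + dt B) x = rhs.

    Symmetric positive-definite case (no transport): conjugate gradients with
    a symmetric diagonal (Jacobi) preconditioner — the matrix is mass
    dominated for realistic dt, so CG converges in a handful of iterations
    and the preconditioner must itself be SPD for CG to be valid.
    Nonsymmetric case: BiCGStab preconditioned by an incomplete LU factor.
    """

    def __init__(self, system: AssembledSystem, dt: float, tol: float = 1e-10,
                 maxiter: int = 2000):
        self.S = (system.M + dt * system.A + dt * system.B).tocsc()
        self.symmetric = system.symmetric
        self.tol = tol
        self.maxiter = maxiter
        n = self.S.shape[0]
        if self.symmetric:
            d = self.S.diagonal()
            if np.any(d <= 0):
                raise NumericalError("system diagonal not positive; mesh degenerate?")
            inv_d = 1.0 / d
            self.prec = spla.LinearOperator((n, n), matvec=lambda x: inv_d * x)
        else:
            try:
                ilu = spla.spilu(self.S, drop_tol=1e-5, fill_factor=10.0)
                self.prec = spla.LinearOperator((n, n), matvec=ilu.solve)
            except RuntimeError as exc:
                raise NumericalError(f"ILU preconditioner failed: {exc}") from exc

    def solve(self, rhs: np.ndarray, x0: np.ndarray | None = None) -> np.ndarray:
        method = spla.cg if self.symmetric else spla.bicgstab
        x, info = method(self.S, rhs, x0=x0, rtol=self.tol, atol=0.0,
                         maxiter=self.maxiter, M=self.prec)
        if info != 0:
            res = np.linalg.norm(self.S @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise NumericalError(
                f"linear solver did not converge (info={info}, relative residual {res:.3e})"
            )
        return x


def imex_step(
    system: AssembledSystem,
    u_n: np.ndarray,
    dt: float,
    load: np.ndarray,
    solver: _LinearSolver | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """One IMEX step.  ``load`` is F(u^n) already evaluated.

    Building the factorization every call is wasteful inside a loop; pass a
    cached ``_LinearSolver`` (as :func:`run_simulation` does) to amortize it.
    """
    if dt <= 0:
        raise ParameterError("dt must be positive")
    u_n = np.asarray(u_n, dtype=float)
    if u_n.shape != (system.n_nodes,):
        raise DimensionError("state vector does not match the assembled system")
    if solver is None:
        solver = _LinearSolver(system, dt, tol=tol)
    rhs = system.M @ u_n + dt * np.asarray(load, dtype=float)
    return solver.solve(rhs, x0=u_n)


def _probe_matrix(mesh: TriMesh, probes: dict[str, tuple[float, float]]):
    if not probes:
        return None, []
    names = list(probes)
    pts = np.array([probes[k] for k in names], dtype=float)
    tri_idx, bary = locate_points(mesh, pts)
    rows = np.repeat(np.arange(len(names)), 3)
    cols = mesh.triangles[tri_idx].ravel()
    P = sp.coo_matrix((bary.ravel(), (rows, cols)), shape=(len(names), mesh.n_nodes)).tocsr()
    return P, names


def run_simulation(
    mesh: TriMesh,
    coeffs: CoefficientSet,
    u0: np.ndarray,
    dt: float = DT_DEFAULT,
    t_end: float = 10.0,
    threshold: float = ARRIVAL_THRESHOLD,
    probes: dict[str, tuple[float, float]] | None = None,
    snapshot_stride: int = 10,
    solver_tol: float = 1e-10,
    enforce_nonnegative: bool = True,
) -> SimulationResult:
    """March the IMEX scheme from ``u0`` to ``t_end`` (years).

    ``enforce_nonnegative`` floors the density at 0 after every step.  The
    continuous model preserves u >= 0, but the consistent-mass P1 scheme has
    no discrete maximum principle: sharp fronts undershoot slightly, and for
    the logistic reaction u < 0 is an unstable direction (undershoots grow
    like exp(gamma t) and eventually blow up).  The floor removes exactly
    those unphysical negative values and is inert for nonnegative states.
    """
    if t_end <= 0 or dt <= 0:
        raise ParameterError("dt and t_end must be positive")
    u = np.asarray(u0, dtype=float).copy()
    if u.shape != (mesh.n_nodes,):
        raise DimensionError("u0 does not match the mesh")
    n_steps = int(round(t_end / dt))
    time_dep = coeffs.is_time_dependent

    system = AssembledSystem.assemble(mesh, coeffs, t=0.0)
    solver = _LinearSolver(system, dt, tol=solver_tol)

    P, probe_names = _probe_matrix(mesh, probes or {})
    probe_series = {name: np.empty(n_steps + 1) for name in probe_names}
    probe_times = np.arange(n_steps + 1) * dt

    arrival = np.full(mesh.n_nodes, np.inf)
    arrival[u >= threshold] = 0.0

    snap_times = [0.0]
    snaps = [u.copy()]
    if P is not None:
        vals = P @ u
        for k, name in enumerate(probe_names):
            probe_series[name][0] = vals[k]

    gamma_t = coeffs.gamma_nodal(0.0)
    f_t = coeffs.f_nodal(0.0)
    for n in range(n_steps):
        t_n = n * dt
        if time_dep:
            system = AssembledSystem.assemble(mesh, coeffs, t=t_n)
            solver = _LinearSolver(system, dt, tol=solver_tol)
            gamma_t = coeffs.gamma_nodal(t_n)
            f_t = coeffs.f_nodal(t_n)
        load = reaction_load(mesh, u, gamma_t, f_t, t=t_n)
        u_new = imex_step(system, u, dt, load, solver=solver)
        if enforce_nonnegative:
            np.maximum(u_new, 0.0, out=u_new)
        if not np.all(np.isfinite(u_new)):
            raise NumericalError(f"solution blow-up at step {n + 1} (t = {t_n + dt:.4f} yr)")
        crossing = (u_new >= threshold) & ~np.isfinite(arrival)
        if crossing.any():
            frac = (threshold - u[crossing]) / (u_new[crossing] - u[crossing])
            arrival[crossing] = t_n + np.clip(frac, 0.0, 1.0) * dt
        u = u_new
        if P is not None:
            vals = P @ u
            for k, name in enumerate(probe_names):
                probe_series[name][n + 1] = vals[k]
        if (n + 1) % snapshot_stride == 0 or n + 1 == n_steps:
            snap_times.append((n + 1) * dt)
            snaps.append(u.copy())

    return SimulationResult(
        times=np.array(snap_times),
        snapshots=np.array(snaps),
        arrival_time=arrival,
        probe_times=probe_times,
        probes=probe_series,
        dt=dt,
        threshold=threshold,
    )


def interpolate_field(mesh: TriMesh, values: np.ndarray, points: np.ndarray) -> np.ndarray:
    """P1 interpolation of a nodal field at arbitrary points."""
    tri_idx, bary = locate_points(mesh, points)
    return np.einsum("pk,pk->p", values[mesh.triangles[tri_idx]], bary)


def front_speed(
    result: SimulationResult,
    mesh: TriMesh,
    transect: tuple[tuple[float, float], tuple[float, float]],
    n_samples: int = 50,
) -> float:
    """Front propagation speed (deg/yr) along a straight transect.

    Samples the arrival-time field along the segment and returns the inverse
    slope of the least-squares fit of arrival time against distance.
    """
    (x0, y0), (x1, y1) = transect
    s = np.linspace(0.0, 1.0, n_samples)
    pts = np.column_stack([x0 + s * (x1 - x0), y0 + s * (y1 - y0)])
    dist = s * float(np.hypot(x1 - x0, y1 - y0))
    arr = interpolate_field(mesh, result.arrival_time, pts)
    finite = np.isfinite(arr)
    if finite.sum() < 3:
        raise NumericalError(
            f"only {int(finite.sum())} finite arrival times on the transect; need >= 3"
        )
    slope = np.polyfit(dist[finite], arr[finite], 1)[0]
    if slope <= 0:
        raise NumericalError("arrival time does not increase along the transect")
    return 1.0 / slope


def fisher_wave_speed(nu: float, gamma: float) -> float:
    """Minimal Fisher-KPP front speed 2 sqrt(nu gamma) in homogeneous media."""
    return 2.0 * float(np.sqrt(nu * gamma))


def logistic_solution(t, gamma: float, u0: float):
    """Closed-form logistic growth u' = u (gamma - u), u(0) = u0."""
    t = np.asarray(t, dtype=float)
    e = np.exp(gamma * t)
    return gamma * u0 * e / (gamma + u0 * (e - 1.0))
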