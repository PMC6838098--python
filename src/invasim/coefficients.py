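"""Model coefficients for the dispersal equation.

The density u(x, t) obeys a generalized Fisher equation

    du/dt - div(nu grad u) + b . grad u + u (u - gamma) = f

whose coefficients encode the landscape: diffusivity ``nu`` (deg^2/yr),
transport velocity ``b`` (deg/yr, e.g. rivers), carrying capacity ``gamma``
(density units) and an external source ``f`` (density/yr).  The reference
elevation law ties the carrying capacity linearly to terrain height,

    gamma(z) = alpha * (10 - z / 100),

so with alpha = 1 the capacity is 10 at sea level and crosses zero at
1000 m.  gamma < 0 is deliberately not clamped: the reaction u(u - gamma)
then actively removes population on high ground instead of leaving it
neutral, which is what makes mountain ridges true barriers.

Coefficients are stored as per-node evaluators of time; masks (lakes,
inhospitable zones) multiply nu/gamma on named node sets, with lakes forcing
gamma to exactly 0.  The reference scenario is time independent, but every
accessor takes t so periodic (seasonal) variants can be composed at the
configuration level.  The canonical time unit is years; configuration values
given in months are divided by 12 at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import CoefficientError, StateError
from .meshing import TriMesh

#: sea-level carrying capacity of the reference elevation law (density units)
GAMMA_SEA_LEVEL = 10.0
#: capacity lost per metre of elevation (density units / m)
GAMMA_SLOPE = 1.0 / 100.0
#: reference diffusivity, deg^2 / yr
NU_REFERENCE = 5.0e-4


def elevation_gamma(z, alpha: float = 1.0):
    """Carrying capacity at elevation ``z`` metres: ``alpha * (10 - z/100)``.

    Affine in z and linear in alpha; negative above the 1000 m line (hostile
    terrain, not clamped).
    """
    return alpha * (GAMMA_SEA_LEVEL - np.asarray(z, dtype=float) * GAMMA_SLOPE)


Spec = float | np.ndarray | Callable[[float], np.ndarray]


def _nodal(spec: Spec, n: int, t: float, ncomp: int = 1) -> np.ndarray:
    """Normalize a scalar / array / callable-of-t spec to a nodal array."""
    if callable(spec):
        out = np.asarray(spec(t), dtype=float)
    else:
        out = np.asarray(spec, dtype=float)
    shape = (n,) if ncomp == 1 else (n, ncomp)
    if out.ndim == 0 or (ncomp > 1 and out.shape == (ncomp,)):
        out = np.broadcast_to(out, shape).copy()
    if out.shape != shape:
        raise CoefficientError(f"coefficient shape {out.shape} incompatible with {shape}")
    return out


@dataclass
class Mask:
    """Named node set with multiplicative factors on gamma and nu.

    ``lake=True`` forces gamma to exactly 0 on the set regardless of factors.
    """

    name: str
    nodes: np.ndarray
    gamma_factor: float = 1.0
    nu_factor: float = 1.0
    lake: bool = False


@dataclass
class CoefficientSet:
    """All coefficient fields over one mesh, plus the capacity scale alpha."""

    n_nodes: int
    nu: Spec = NU_REFERENCE
    b: Spec = 0.0
    gamma: Spec = GAMMA_SEA_LEVEL
    f: Spec = 0.0
    alpha: float = 1.0
    masks: Sequence[Mask] = field(default_factory=tuple)

    def _mask_apply(self, arr: np.ndarray, which: str) -> np.ndarray:
        for m in self.masks:
            idx = np.asarray(m.nodes, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_nodes):
                raise IndexError(f"mask {m.name!r} references node outside 0..{self.n_nodes - 1}")
            if which == "gamma":
                if m.lake:
                    arr[idx] = 0.0
                else:
                    arr[idx] *= m.gamma_factor
            elif which == "nu":
                arr[idx] *= m.nu_factor
        return arr

    def nu_nodal(self, t: float = 0.0) -> np.ndarray:
        arr = _nodal(self.nu, self.n_nodes, t)
        arr = self._mask_apply(arr, "nu")
        if (arr < 0).any():
            raise CoefficientError("diffusivity nu must be non-negative")
        return arr

    def b_nodal(self, t: float = 0.0) -> np.ndarray:
        return _nodal(self.b, self.n_nodes, t, ncomp=2)

    def gamma_nodal(self, t: float = 0.0) -> np.ndarray:
        return self._mask_apply(_nodal(self.gamma, self.n_nodes, t), "gamma")

    def f_nodal(self, t: float = 0.0) -> np.ndarray:
        return _nodal(self.f, self.n_nodes, t)

    @property
    def is_time_dependent(self) -> bool:
        return any(callable(s) for s in (self.nu, self.b, self.gamma, self.f))

    @property
    def has_transport(self) -> bool:
        if callable(self.b):
            return True
        return bool(np.any(np.asarray(self.b, dtype=float) != 0.0))


def apply_masks(base: CoefficientSet, masks: Sequence[Mask]) -> CoefficientSet:
    """Return a copy of ``base`` with ``masks`` appended.

    Disjoint masks commute; overlapping multiplicative masks compose by
    multiplication in list order, and a lake always wins on gamma.
    """
    return CoefficientSet(
        n_nodes=base.n_nodes,
        nu=base.nu,
        b=base.b,
        gamma=base.gamma,
        f=base.f,
        alpha=base.alpha,
        masks=tuple(base.masks) + tuple(masks),
    )


def reference_coefficients(
    mesh: TriMesh, alpha: float = 1.0, nu0: float = NU_REFERENCE
) -> CoefficientSet:
    """Elevation-only scenario: constant nu, no transport, no source, and a
    carrying capacity depending solely on terrain height through
    :func:`elevation_gamma`.
    """
    if mesh.node_elevation is None:
        raise StateError("mesh needs elevation attached before building coefficients")
    return CoefficientSet(
        n_nodes=mesh.n_nodes,
        nu=float(nu0),
        b=0.0,
        gamma=elevation_gamma(mesh.node_elevation, alpha),
        f=0.0,
        alpha=float(alpha),
    )


def river_transport(
    mesh: TriMesh,
    polyline: np.ndarray,
    width: float,
    speed: float,
) -> np.ndarray:
    """Rasterize a river polyline into a nodal velocity field (deg/yr).

    Nodes within ``width/2`` of the polyline get velocity ``speed`` directed
    along the nearest segment (signed: negative speed flows upstream).
    Everywhere else the transport vanishes.
    """
    import shapely

    line = shapely.LineString(np.asarray(polyline, dtype=float))
    pts = shapely.points(mesh.nodes[:, 0], mesh.nodes[:, 1])
    dist = shapely.distance(line, pts)
    inside = dist <= width / 2.0
    b = np.zeros((mesh.n_nodes, 2))
    if inside.any():
        seg = np.asarray(polyline, dtype=float)
        for i in np.flatnonzero(inside):
            p = mesh.nodes[i]
            # nearest segment direction
            best, bestd = None, np.inf
            for k in range(len(seg) - 1):
                a, c = seg[k], seg[k + 1]
                ac = c - a
                tt = np.clip(np.dot(p - a, ac) / max(np.dot(ac, ac), 1e-300), 0, 1)
                d = np.linalg.norm(p - (a + tt * ac))
                if d < bestd:
                    bestd, best = d, ac
            tangent = best / np.linalg.norm(best)
            b[i] = speed * tangent
    return b
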