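"""Data-driven arbitrary Polynomial Chaos with Smolyak sparse grids.

The input distributions (here: diffusivity nu and capacity scale alpha) are
given as samples or histograms, not named families.  From the raw moments
mu_k = E[x^k] of each input we build the moment-orthonormal polynomial
family via the Cholesky factor of the Hankel matrix [mu_{i+j}], read off the
three-term recurrence, and obtain Gaussian quadrature nodes/weights as the
eigen-decomposition of the associated Jacobi matrix.  One-dimensional rules
of increasing order are combined by Smolyak's rule

    A(l, d) = sum_{l+1 <= |i| <= l+d} (-1)^{l+d-|i|} C(d-1, l+d-|i|)
              (x) tensor_k U^{i_k},

whose merged grid at level 1 in d dimensions has 2d + 1 points (5 for two
inputs).  The model is evaluated once per grid point; outputs (whole nodal
fields or probe series) are projected onto the orthonormal basis of total
degree <= level by discrete pseudo-spectral projection

    a_k = sum_i w(eta_i) psi_k(eta_i) theta_i / sum_i psi_k(eta_i)^2 theta_i,

and the cheap surrogate w(xi) ~ sum_k a_k psi_k(xi) is Monte-Carlo sampled
(bootstrap resampling of the stored input samples, independent across
dimensions) for output PDFs, moment fields and arrival-time distributions.
Smolyak weights may be negative; they are used only for projection, never to
build PDFs directly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import cholesky, eigh_tridiagonal, hankel

from .errors import (
    ConfigError,
    DegeneracyError,
    DimensionError,
    ParameterError,
)

# ---------------------------------------------------------------------------
# inputs and moments


def raw_moments(samples: np.ndarray, upto: int) -> np.ndarray:
    """Empirical raw moments mu_k = (1/N) sum x_i^k for k = 0..upto.

    Degenerate sample sets (too few distinct values for a later quadrature
    order) are legal here — a point mass has perfectly good moments c^k; the
    degeneracy is detected where it bites, in the Hankel factorization of
    :func:`quadrature_from_moments`.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if len(x) == 0:
        raise DegeneracyError("empty sample set")
    return np.array([np.mean(x**k) for k in range(upto + 1)])


def histogram_moments(bin_edges: np.ndarray, counts: np.ndarray, upto: int) -> np.ndarray:
    """Raw moments of a histogram: bin midpoints weighted by counts."""
    edges = np.asarray(bin_edges, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(edges) != len(counts) + 1:
        raise DimensionError("need len(bin_edges) == len(counts) + 1")
    mids = 0.5 * (edges[:-1] + edges[1:])
    w = counts / counts.sum()
    return np.array([np.sum(w * mids**k) for k in range(upto + 1)])


@dataclass
class RandomInput:
    """One uncertain scalar input, described by data rather than a family."""

    name: str
    samples: np.ndarray
    moments: np.ndarray = field(default=None)  # type: ignore[assignment]
    m: int = 2  # default 1-D quadrature order

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.moments is None:
            self.moments = raw_moments(self.samples, 2 * self.m)
        self.moments = np.asarray(self.moments, dtype=float)
        if abs(self.moments[0] - 1.0) > 1e-12:
            raise DegeneracyError(f"input {self.name!r}: mu_0 must be 1")

    @classmethod
    def from_histogram(
        cls, name: str, bin_edges: np.ndarray, counts: np.ndarray, m: int = 2
    ) -> "RandomInput":
        """Histogram-backed input; samples are midpoints repeated by count."""
        edges = np.asarray(bin_edges, dtype=float)
        counts = np.asarray(counts)
        mids = 0.5 * (edges[:-1] + edges[1:])
        samples = np.repeat(mids, counts.astype(int))
        return cls(name=name, samples=samples,
                   moments=histogram_moments(edges, counts, 2 * m), m=m)


def synth_histograms(
    specs: Sequence[dict], n: int = 10_000, seed: int = 0
) -> list[RandomInput]:
    """Seeded sampling from named parametric families.

    Each spec is ``{"name": ..., "family": "normal"|"uniform", ...}`` with
    ``mean``/``std`` for normal and ``low``/``high`` for uniform.  This is
    how the package emulates field-measured histograms: the default study
    conditions are nu ~ N(5e-4, 1.2e-4) and alpha ~ U(0, 2).
    """
    if n < 100:
        raise ParameterError("need at least 100 samples per input")
    rng = np.random.default_rng(seed)
    out = []
    for spec in specs:
        family = spec["family"].lower()
        if family == "normal":
            x = rng.normal(spec["mean"], spec["std"], size=n)
        elif family == "uniform":
            x = rng.uniform(spec["low"], spec["high"], size=n)
        else:
            raise ConfigError(f"unknown distribution family {spec['family']!r}")
        out.append(RandomInput(name=spec["name"], samples=x, m=spec.get("m", 2)))
    return out


# ---------------------------------------------------------------------------
# moment-based orthonormal polynomials and Gaussian quadrature


@dataclass
class OrthonormalBasis1D:
    """Orthonormal polynomials of one moment sequence.

    Three-term recurrence (orthonormal form):
    beta_{k+1} p_{k+1}(x) = (x - alpha_k) p_k(x) - beta_k p_{k-1}(x),
    p_0 = 1 (mu_0 = 1), with alpha/beta from the Cholesky factor of the
    Hankel moment matrix.
    """

    alpha: np.ndarray  # length m
    beta: np.ndarray   # length m; beta[0] unused

    @classmethod
    def from_moments(cls, moments: np.ndarray, m: int) -> "OrthonormalBasis1D":
        moments = np.asarray(moments, dtype=float)
        if len(moments) < 2 * m + 1:
            raise DegeneracyError(f"need moments up to order {2 * m} for order {m}")
        H = hankel(moments[: m + 1], moments[m : 2 * m + 1])
        try:
            # scale for conditioning: H_ij = s^(i+j) Htilde_ij with s = scale
            scale = max(abs(moments[1]), np.sqrt(abs(moments[2])), 1e-300)
            D = scale ** np.arange(m + 1)
            R = cholesky(H / np.outer(D, D), lower=False)
        except np.linalg.LinAlgError as exc:
            raise DegeneracyError(
                "Hankel moment matrix is not positive definite; the input is "
                "degenerate or too many moments were requested — reduce the order"
            ) from exc
        alpha = np.empty(m)
        beta = np.empty(m)
        beta[0] = 0.0
        for k in range(m):
            alpha[k] = R[k, k + 1] / R[k, k] * scale
            if k > 0:
                alpha[k] -= R[k - 1, k] / R[k - 1, k - 1] * scale
                beta[k] = R[k, k] / R[k - 1, k - 1] * scale
        return cls(alpha=alpha, beta=beta)

    @property
    def max_degree(self) -> int:
        return len(self.alpha) - 1

    def eval(self, x: np.ndarray, upto: int) -> np.ndarray:
        """Values p_0..p_upto at points x, shape (n, upto + 1)."""
        if upto > self.max_degree:
            raise ParameterError(
                f"basis built for degree <= {self.max_degree}, asked for {upto}"
            )
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = np.empty((len(x), upto + 1))
        out[:, 0] = 1.0
        if upto >= 1:
            out[:, 1] = (x - self.alpha[0]) / self.beta[1]
        for k in range(1, upto):
            out[:, k + 1] = (
                (x - self.alpha[k]) * out[:, k] - self.beta[k] * out[:, k - 1]
            ) / self.beta[k + 1]
        return out


@dataclass
class QuadratureRule1D:
    """Gaussian rule matched to a moment sequence: m nodes, weights sum 1."""

    nodes: np.ndarray
    weights: np.ndarray
    order: int


def quadrature_from_moments(inp: RandomInput | np.ndarray, m: int) -> QuadratureRule1D:
    """Gaussian quadrature from raw moments (Golub-Welsch on the Jacobi matrix).

    The returned rule integrates monomials x^0..x^(2m-1) to the moment values
    exactly (up to conditioning).
    """
    if m < 1:
        raise ParameterError("quadrature order must be >= 1")
    moments = inp.moments if isinstance(inp, RandomInput) else np.asarray(inp, dtype=float)
    basis = OrthonormalBasis1D.from_moments(moments, m)
    if m == 1:
        return QuadratureRule1D(nodes=np.array([moments[1]]), weights=np.array([1.0]), order=1)
    nodes, vecs = eigh_tridiagonal(basis.alpha, basis.beta[1:m])
    weights = vecs[0] ** 2
    order = np.argsort(nodes)
    return QuadratureRule1D(nodes=nodes[order], weights=weights[order], order=m)


# ---------------------------------------------------------------------------
# Smolyak sparse grids


@dataclass
class SparseGrid:
    """Merged Smolyak grid; weights may be negative but sum to 1."""

    points: np.ndarray   # (n_points, d)
    weights: np.ndarray  # (n_points,)
    level: int
    dim: int


def smolyak_grid(rules: Sequence[Sequence[QuadratureRule1D]], level: int) -> SparseGrid:
    """Combine per-dimension rule families by Smolyak's formula.

    ``rules[j][i - 1]`` must be the i-point rule for dimension j, for every i
    up to ``level + 1``.  Duplicate points across tensor terms are merged
    with summed weights.
    """
    d = len(rules)
    if d < 1:
        raise ParameterError("need at least one dimension")
    for j, fam in enumerate(rules):
        if len(fam) < level + 1:
            raise ConfigError(
                f"dimension {j}: need 1-D rules up to {level + 1} points, got {len(fam)}"
            )
    scales = np.array(
        [max(max(abs(r.nodes).max() for r in fam), 1e-300) for fam in rules]
    )
    acc: dict[tuple, tuple[np.ndarray, float]] = {}
    for multi in itertools.product(range(1, level + 2), repeat=d):
        q = sum(multi)
        if not (level + 1 <= q <= level + d):
            continue
        coeff = (-1) ** (level + d - q) * comb(d - 1, level + d - q)
        sel = [rules[j][multi[j] - 1] for j in range(d)]
        for combo in itertools.product(*(range(r.order) for r in sel)):
            pt = np.array([sel[j].nodes[combo[j]] for j in range(d)])
            w = coeff * float(np.prod([sel[j].weights[combo[j]] for j in range(d)]))
            key = tuple(np.round(pt / scales, 10))
            if key in acc:
                acc[key] = (acc[key][0], acc[key][1] + w)
            else:
                acc[key] = (pt, w)
    items = sorted(acc.items())
    points = np.array([v[0] for _, v in items])
    weights = np.array([v[1] for _, v in items])
    keep = np.abs(weights) > 1e-14
    return SparseGrid(points=points[keep], weights=weights[keep], level=level, dim=d)


def tensor_grid(rules: Sequence[QuadratureRule1D]):
    """Full tensor-product grid (the brute-force reference for Smolyak)."""
    nodes = [r.nodes for r in rules]
    weights = [r.weights for r in rules]
    pts = np.array(list(itertools.product(*nodes)))
    ws = np.array([float(np.prod(w)) for w in itertools.product(*weights)])
    return pts, ws


# ---------------------------------------------------------------------------
# PCE projection and surrogate


def total_degree_indices(dim: int, level: int) -> list[tuple[int, ...]]:
    """Multi-indices of total degree <= level, graded lexicographic order."""
    idx = [
        mi
        for mi in itertools.product(range(level + 1), repeat=dim)
        if sum(mi) <= level
    ]
    return sorted(idx, key=lambda mi: (sum(mi), mi))


@dataclass
class PCExpansion:
    """Truncated chaos expansion w(xi) ~ sum_k a_k psi_k(xi)."""

    bases: list[OrthonormalBasis1D]
    multi_indices: list[tuple[int, ...]]
    coefficients: np.ndarray  # (n_basis, ...) — trailing axes are output shape
    grid: SparseGrid

    def basis_matrix(self, xi: np.ndarray) -> np.ndarray:
        xi = np.atleast_2d(np.asarray(xi, dtype=float))
        deg = max(max(mi) for mi in self.multi_indices)
        per_dim = [b.eval(xi[:, j], deg) for j, b in enumerate(self.bases)]
        cols = [
            np.prod([per_dim[j][:, mi[j]] for j in range(len(self.bases))], axis=0)
            for mi in self.multi_indices
        ]
        return np.column_stack(cols)

    def evaluate(self, xi: np.ndarray) -> np.ndarray:
        psi = self.basis_matrix(xi)
        flat = self.coefficients.reshape(len(self.multi_indices), -1)
        out = psi @ flat
        return out.reshape((len(psi),) + self.coefficients.shape[1:])

    @property
    def mean(self) -> np.ndarray:
        """Surrogate mean = coefficient of psi_0 (orthonormality)."""
        return self.coefficients[0]


def pce_project(
    evaluations: np.ndarray,
    grid: SparseGrid,
    bases: Sequence[OrthonormalBasis1D],
    level: int | None = None,
) -> PCExpansion:
    """Discrete pseudo-spectral projection of model outputs on the grid.

    ``evaluations`` holds one output (scalar or array) per grid point, shape
    ``(n_points, ...)``.  The projection denominator uses psi_k squared (the
    discrete norm of the basis function on the signed grid).
    """
    ev = np.asarray(evaluations, dtype=float)
    if len(ev) != len(grid.points):
        raise DimensionError(
            f"{len(ev)} evaluations for {len(grid.points)} grid points"
        )
    level = grid.level if level is None else level
    mis = total_degree_indices(grid.dim, level)
    exp = PCExpansion(
        bases=list(bases), multi_indices=mis,
        coefficients=np.zeros((len(mis),) + ev.shape[1:]), grid=grid,
    )
    psi = exp.basis_matrix(grid.points)  # (n_points, n_basis)
    theta = grid.weights
    flat = ev.reshape(len(ev), -1)
    num = psi.T @ (theta[:, None] * flat)          # (n_basis, n_out)
    den = (psi**2 * theta[:, None]).sum(axis=0)    # (n_basis,)
    if np.any(np.abs(den) < 1e-12):
        raise DegeneracyError("vanishing discrete norm: grid too coarse for the basis")
    coeffs = num / den[:, None]
    exp.coefficients = coeffs.reshape((len(mis),) + ev.shape[1:])
    return exp


def bootstrap_samples(
    inputs: Sequence[RandomInput], n_samples: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_samples, d) draws resampled independently from each input's pool."""
    cols = []
    for inp in inputs:
        if len(inp.samples) == 0:
            raise DegeneracyError(f"input {inp.name!r} has an empty sample pool")
        cols.append(rng.choice(inp.samples, size=n_samples, replace=True))
    return np.column_stack(cols)


@dataclass
class UQResult:
    """Monte-Carlo statistics of the surrogate model."""

    times: np.ndarray                    # snapshot times, years
    mean_field: np.ndarray               # (n_snap, n_nodes)
    std_field: np.ndarray                # (n_snap, n_nodes), >= 0
    probe_times: np.ndarray
    probe_mean: dict[str, np.ndarray]
    probe_std: dict[str, np.ndarray]
    probe_pdfs: dict[str, tuple[np.ndarray, np.ndarray]]    # (bin_edges, density)
    arrival_pdfs: dict[str, tuple[np.ndarray, np.ndarray]]  # (bin_edges, density)
    n_runs: int
    n_mc: int


def _pdf(values: np.ndarray, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    values = values[np.isfinite(values)]
    if len(values) == 0:
        return np.array([0.0, 1.0]), np.array([0.0])
    if np.ptp(values) < 1e-300:
        v = float(values[0])
        edges = np.array([v - 0.5, v + 0.5])
        return edges, np.array([1.0])
    density, edges = np.histogram(values, bins=n_bins, density=True)
    return edges, density


def surrogate_mc(
    expansion: PCExpansion,
    inputs: Sequence[RandomInput],
    n_samples: int = 100_000,
    seed: int = 0,
    probe_expansions: dict[str, "PCExpansion"] | None = None,
    times: np.ndarray | None = None,
    probe_times: np.ndarray | None = None,
    threshold: float = 1.0,
    n_bins: int = 40,
    n_runs: int = 0,
) -> UQResult:
    """Monte-Carlo the surrogate(s) for output distributions and moments.

    ``expansion`` carries the snapshot fields (n_snap, n_nodes);
    ``probe_expansions`` map probe names to series expansions (n_times,).
    Deterministic for a fixed seed.
    """
    if n_samples < 1_000:
        raise ParameterError("use at least 1000 surrogate samples")
    rng = np.random.default_rng(seed)
    xi = bootstrap_samples(inputs, n_samples, rng)
    psi = expansion.basis_matrix(xi)  # (n_samples, K)
    # field mean/std through the basis moments: with w = Psi a, the MC mean
    # and covariance of w follow from the MC mean/covariance of Psi — exact
    # same estimator as realizing every field sample, at a fraction of memory
    e_psi = psi.mean(axis=0)
    cov_psi = np.cov(psi.T, bias=True).reshape(len(e_psi), len(e_psi))
    flat = expansion.coefficients.reshape(len(e_psi), -1)
    mean_flat = e_psi @ flat
    var_flat = np.einsum("kd,kl,ld->d", flat, cov_psi, flat)
    mean_field = mean_flat.reshape(expansion.coefficients.shape[1:])
    std_field = np.sqrt(np.clip(var_flat, 0.0, None)).reshape(mean_field.shape)

    probe_mean: dict[str, np.ndarray] = {}
    probe_std: dict[str, np.ndarray] = {}
    probe_pdfs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    arrival_pdfs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if probe_expansions:
        if probe_times is None:
            raise ConfigError("probe_times required with probe expansions")
        batch = max(1, min(n_samples, 20_000_000 // max(len(probe_times), 1)))
        for name, pex in probe_expansions.items():
            C = pex.coefficients.reshape(len(e_psi), -1)  # (K, n_t)
            # series mean/std follow from the MC moments of the basis —
            # identical estimator to realizing every series, without the
            # (n_mc, n_t) array
            probe_mean[name] = e_psi @ C
            probe_std[name] = np.sqrt(
                np.clip(np.einsum("kt,kl,lt->t", C, cov_psi, C), 0.0, None)
            )
            probe_pdfs[name] = _pdf(psi @ C[:, -1], n_bins)
            # arrival times need per-realization series: batch over samples
            arr = np.full(n_samples, np.inf)
            for lo in range(0, n_samples, batch):
                series = psi[lo : lo + batch] @ C  # (b, n_t)
                above = series >= threshold
                reached = above.any(axis=1)
                first = np.argmax(above, axis=1)
                hit = reached & (first > 0)
                if hit.any():
                    i1 = first[hit]
                    rows = np.flatnonzero(hit)
                    u0 = series[rows, i1 - 1]
                    u1 = series[rows, i1]
                    frac = np.clip(
                        (threshold - u0) / np.where(u1 != u0, u1 - u0, 1.0), 0, 1
                    )
                    arr[lo + rows] = probe_times[i1 - 1] + frac * (
                        probe_times[i1] - probe_times[i1 - 1]
                    )
                zero = reached & (first == 0)
                arr[lo + np.flatnonzero(zero)] = probe_times[0]
            arrival_pdfs[name] = _pdf(arr, n_bins)

    n_snap = expansion.coefficients.shape[1] if expansion.coefficients.ndim > 1 else 1
    return UQResult(
        times=np.asarray(times) if times is not None else np.arange(n_snap, dtype=float),
        mean_field=mean_field,
        std_field=std_field,
        probe_times=np.asarray(probe_times) if probe_times is not None else np.array([]),
        probe_mean=probe_mean,
        probe_std=probe_std,
        probe_pdfs=probe_pdfs,
        arrival_pdfs=arrival_pdfs,
        n_runs=n_runs,
        n_mc=n_samples,
    )


def run_uq(
    model: Callable[[dict[str, float]], "object"],
    inputs: Sequence[RandomInput],
    level: int = 1,
    n_mc: int = 100_000,
    seed: int = 0,
    n_bins: int = 40,
) -> tuple[UQResult, dict]:
    """Full chaos pipeline around a deterministic simulation.

    ``model`` maps ``{input name: value}`` to an object with ``times``,
    ``snapshots``, ``probe_times``, ``probes`` and ``threshold`` attributes
    (a :class:`~invasim.solver.SimulationResult`).  At level 1 with two
    inputs this costs exactly 5 deterministic runs.
    """
    d = len(inputs)
    rules = [
        [quadrature_from_moments(inp, i) for i in range(1, level + 2)]
        for inp in inputs
    ]
    grid = smolyak_grid(rules, level)
    bases = [OrthonormalBasis1D.from_moments(inp.moments, level + 1) for inp in inputs]

    results = []
    for pt in grid.points:
        params = {inp.name: float(pt[j]) for j, inp in enumerate(inputs)}
        results.append(model(params))
    first = results[0]
    fields = np.array([r.snapshots for r in results])  # (P, n_snap, n_nodes)
    field_exp = pce_project(fields, grid, bases, level)
    probe_exps = {
        name: pce_project(
            np.array([r.probes[name] for r in results]), grid, bases, level
        )
        for name in first.probes
    }
    uq = surrogate_mc(
        field_exp,
        inputs,
        n_samples=n_mc,
        seed=seed,
        probe_expansions=probe_exps,
        times=first.times,
        probe_times=first.probe_times,
        threshold=first.threshold,
        n_bins=n_bins,
        n_runs=len(grid.points),
    )
    diagnostics = {
        "grid": grid,
        "bases": bases,
        "field_expansion": field_exp,
        "probe_expansions": probe_exps,
        "n_runs": len(grid.points),
        "dim": d,
    }
    return uq, diagnostics
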