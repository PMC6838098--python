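"""Moment quadrature, Smolyak combination, PCE projection and surrogate MC."""

import itertools

import numpy as np
import pytest

from invasim.apc import (
    OrthonormalBasis1D,
    RandomInput,
    SparseGrid,
    histogram_moments,
    pce_project,
    quadrature_from_moments,
    raw_moments,
    run_uq,
    smolyak_grid,
    surrogate_mc,
    synth_histograms,
    tensor_grid,
    total_degree_indices,
)
from invasim.errors import ConfigError, DegeneracyError, DimensionError, ParameterError

# exact raw moments
U02 = np.array([1.0, 1.0, 4 / 3, 2.0, 16 / 5])            # U(0, 2)
MU, SD = 5e-4, 1.2e-4
NORM = np.array([1.0, MU, MU**2 + SD**2, MU**3 + 3 * MU * SD**2,
                 MU**4 + 6 * MU**2 * SD**2 + 3 * SD**4])   # N(mu, sd)


class TestRawMoments:
    def test_two_point_symmetric(self):
        m = raw_moments(np.array([-1.0, 1.0]), 2)
        assert m[0] == 1.0 and m[1] == 0.0 and m[2] == 1.0

    def test_uniform_sample_moments(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 2, 1_000_000)
        m = raw_moments(x, 2)
        se1 = np.std(x) / 1000.0
        assert abs(m[1] - 1.0) < 3 * se1
        assert abs(m[2] - 4 / 3) < 3 * np.std(x**2) / 1000.0

    def test_constant_samples_point_mass_moments(self):
        m = raw_moments(np.full(50, 3.0), 3)
        assert np.allclose(m, [1.0, 3.0, 9.0, 27.0])
        # the degeneracy bites at quadrature construction, not here
        with pytest.raises(DegeneracyError):
            quadrature_from_moments(raw_moments(np.full(50, 3.0), 4), 2)

    def test_histogram_vs_sample_moments(self):
        """Histogram-midpoint moments match empirical moments of the
        midpoint-expanded sample (the two paths agree by construction)."""
        edges = np.linspace(0, 2, 21)
        counts = np.arange(1, 21)
        mids = 0.5 * (edges[:-1] + edges[1:])
        expanded = np.repeat(mids, counts)
        assert np.allclose(
            histogram_moments(edges, counts, 4), raw_moments(expanded, 4)
        )


class TestQuadratureFromMoments:
    def test_one_point_rule_is_mean(self):
        r = quadrature_from_moments(U02, 1)
        assert r.nodes == pytest.approx([1.0]) and r.weights == pytest.approx([1.0])

    def test_uniform_two_point_gauss_legendre(self):
        r = quadrature_from_moments(U02, 2)
        assert np.allclose(r.nodes, [1 - 1 / np.sqrt(3), 1 + 1 / np.sqrt(3)], atol=1e-10)
        assert np.allclose(r.weights, [0.5, 0.5], atol=1e-12)

    def test_normal_two_point_gauss_hermite(self):
        r = quadrature_from_moments(NORM, 2)
        assert np.allclose(r.nodes, [MU - SD, MU + SD], rtol=1e-9)
        assert np.allclose(r.weights, [0.5, 0.5], atol=1e-10)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_exactness_to_2m_minus_1(self, m):
        rng = np.random.default_rng(4)
        x = rng.gamma(3.0, 1.0, 20_000)
        moments = raw_moments(x, 2 * m)
        r = quadrature_from_moments(moments, m)
        assert r.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(r.nodes) > 0)
        assert r.nodes.min() >= x.min() and r.nodes.max() <= x.max()
        for k in range(2 * m):
            assert np.sum(r.weights * r.nodes**k) == pytest.approx(
                moments[k], rel=1e-8, abs=1e-12
            )

    def test_degenerate_moments_rejected(self):
        bad = np.array([1.0, 1.0, 1.0, 1.0, 1.0])  # point mass: singular Hankel
        with pytest.raises(DegeneracyError):
            quadrature_from_moments(bad, 2)


class TestOrthonormalBasis:
    def test_discrete_orthonormality(self):
        """Basis orthonormal under a dense quadrature of its own measure."""
        rng = np.random.default_rng(8)
        x = rng.beta(2, 5, 50_000) * 3
        m = 4
        moments = raw_moments(x, 2 * m)
        basis = OrthonormalBasis1D.from_moments(moments, m)
        rule = quadrature_from_moments(moments, m)
        P = basis.eval(rule.nodes, m - 1)
        G = (P * rule.weights[:, None]).T @ P
        assert np.allclose(G, np.eye(m), atol=1e-8)

    def test_psi0_is_one(self):
        basis = OrthonormalBasis1D.from_moments(U02, 2)
        assert np.allclose(basis.eval(np.array([0.3, 1.9]), 0)[:, 0], 1.0)


class TestSmolyak:
    def _rules(self, moments, upto):
        return [quadrature_from_moments(moments, i) for i in range(1, upto + 1)]

    def test_level1_two_inputs_five_points_cross_weights(self):
        g = smolyak_grid([self._rules(NORM, 2), self._rules(U02, 2)], 1)
        assert len(g.points) == 5
        assert g.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert sorted(np.round(g.weights, 10)) == pytest.approx([-1.0, 0.5, 0.5, 0.5, 0.5])
        # cross shape: one centre point, two per axis
        centre = np.array([MU, 1.0])
        d = np.abs(g.points - centre)
        assert ((d > 1e-12).sum(axis=1) <= 1).all()

    def test_level1_one_input_collapses_to_two_point_rule(self):
        g = smolyak_grid([self._rules(U02, 2)], 1)
        r = quadrature_from_moments(U02, 2)
        assert np.allclose(np.sort(g.points.ravel()), r.nodes)
        assert np.allclose(g.weights, [0.5, 0.5])

    @pytest.mark.parametrize("d", [1, 2, 3, 4, 5])
    def test_point_count_law_against_tensor_union_oracle(self, d):
        fams = [self._rules(U02, 2)] * d
        g = smolyak_grid(fams, 1)
        # centre point + 2 per axis; in 1-D the combination collapses to the
        # plain 2-point rule, so no centre point appears
        assert len(g.points) == (2 if d == 1 else 2 * d + 1)
        # brute-force oracle: union of tensor grids with combination weights
        from math import comb

        acc = {}
        for multi in itertools.product((1, 2), repeat=d):
            q = sum(multi)
            if not (2 <= q <= 1 + d):
                continue
            coeff = (-1) ** (1 + d - q) * comb(d - 1, 1 + d - q)
            pts, ws = tensor_grid([fams[j][multi[j] - 1] for j in range(d)])
            for p, w in zip(pts, ws):
                key = tuple(np.round(p, 10))
                acc[key] = acc.get(key, 0.0) + coeff * w
        oracle = {k: v for k, v in acc.items() if abs(v) > 1e-14}
        assert len(oracle) == len(g.points)
        for p, w in zip(g.points, g.weights):
            assert oracle[tuple(np.round(p, 10))] == pytest.approx(w, abs=1e-12)

    def test_missing_rule_order(self):
        with pytest.raises(ConfigError):
            smolyak_grid([self._rules(U02, 1)], 1)


def _level1_setup():
    rules = [
        [quadrature_from_moments(NORM, i) for i in (1, 2)],
        [quadrature_from_moments(U02, i) for i in (1, 2)],
    ]
    grid = smolyak_grid(rules, 1)
    bases = [OrthonormalBasis1D.from_moments(NORM, 2),
             OrthonormalBasis1D.from_moments(U02, 2)]
    return grid, bases


class TestPCEProjection:
    def test_constant_model(self):
        grid, bases = _level1_setup()
        exp = pce_project(np.full(len(grid.points), 3.7), grid, bases)
        assert exp.coefficients[0] == pytest.approx(3.7, abs=1e-12)
        assert np.abs(exp.coefficients[1:]).max() < 1e-12
        assert exp.mean == pytest.approx(3.7)

    def test_degree1_model_reproduced_at_random_points(self):
        grid, bases = _level1_setup()
        a, b, c = 1.5, 2000.0, -0.75
        w = a + b * grid.points[:, 0] + c * grid.points[:, 1]
        exp = pce_project(w, grid, bases)
        rng = np.random.default_rng(17)
        xi = np.column_stack([rng.normal(MU, SD, 100), rng.uniform(0, 2, 100)])
        assert np.allclose(exp.evaluate(xi), a + b * xi[:, 0] + c * xi[:, 1],
                           rtol=1e-10, atol=1e-10)

    def test_surrogate_mean_is_linear_expectation(self):
        grid, bases = _level1_setup()
        a, b, c = 2.0, 1e3, 0.5
        w = a + b * grid.points[:, 0] + c * grid.points[:, 1]
        exp = pce_project(w, grid, bases)
        assert exp.mean == pytest.approx(a + b * MU + c * 1.0, rel=1e-10)

    def test_fieldwise_projection(self):
        grid, bases = _level1_setup()
        w = np.outer(grid.points[:, 1], np.array([1.0, 2.0, 3.0]))  # (P, 3)
        exp = pce_project(w, grid, bases)
        assert exp.coefficients.shape[1:] == (3,)
        assert np.allclose(exp.mean, [1.0, 2.0, 3.0], rtol=1e-10)

    def test_size_mismatch(self):
        grid, bases = _level1_setup()
        with pytest.raises(DimensionError):
            pce_project(np.zeros(3), grid, bases)

    def test_total_degree_truncation_count(self):
        assert len(total_degree_indices(2, 1)) == 3
        assert len(total_degree_indices(3, 2)) == 10


class TestSurrogateMC:
    def _inputs(self, n=20_000, seed=1):
        return synth_histograms(
            [{"name": "nu", "family": "normal", "mean": MU, "std": SD},
             {"name": "alpha", "family": "uniform", "low": 0.0, "high": 2.0}],
            n=n, seed=seed,
        )

    def test_uniform_linear_output_std(self):
        """w(xi) = xi_2 with xi_2 ~ U(0,2): sigma within 2% of 1/sqrt(3)."""
        inputs = self._inputs(n=100_000)
        rules = [[quadrature_from_moments(i_, k) for k in (1, 2)] for i_ in inputs]
        grid = smolyak_grid(rules, 1)
        bases = [OrthonormalBasis1D.from_moments(i_.moments, 2) for i_ in inputs]
        exp = pce_project(grid.points[:, 1].copy(), grid, bases)
        res = surrogate_mc(exp, inputs, n_samples=100_000, seed=3)
        assert res.std_field == pytest.approx(1 / np.sqrt(3), rel=0.02)

    def test_zero_variance_inputs(self):
        nu = RandomInput("nu", np.full(1000, 2.0),
                         moments=np.array([1.0, 2.0, 4.0, 8.0, 16.0]))
        exp_coeffs = np.array([5.0])
        grid = SparseGrid(points=np.array([[2.0]]), weights=np.array([1.0]),
                          level=0, dim=1)
        from invasim.apc import PCExpansion

        exp = PCExpansion(bases=[OrthonormalBasis1D(np.array([2.0]), np.array([0.0]))],
                          multi_indices=[(0,)], coefficients=exp_coeffs, grid=grid)
        res = surrogate_mc(exp, [nu], n_samples=2000, seed=0)
        assert res.std_field == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_for_fixed_seed(self):
        inputs = self._inputs()
        rules = [[quadrature_from_moments(i_, k) for k in (1, 2)] for i_ in inputs]
        grid = smolyak_grid(rules, 1)
        bases = [OrthonormalBasis1D.from_moments(i_.moments, 2) for i_ in inputs]
        exp = pce_project(grid.points[:, 0] * 1e3 + grid.points[:, 1], grid, bases)
        r1 = surrogate_mc(exp, inputs, n_samples=5000, seed=7)
        r2 = surrogate_mc(exp, inputs, n_samples=5000, seed=7)
        assert np.array_equal(r1.mean_field, r2.mean_field)
        assert np.array_equal(r1.std_field, r2.std_field)


class TestSynthHistograms:
    def test_reference_distributions(self):
        inputs = synth_histograms(
            [{"name": "nu", "family": "normal", "mean": MU, "std": SD},
             {"name": "alpha", "family": "uniform", "low": 0.0, "high": 2.0}],
            n=10_000, seed=5,
        )
        nu, alpha = inputs
        assert abs(nu.samples.mean() - MU) < 3 * SD / 100.0
        assert alpha.samples.min() >= 0.0 and alpha.samples.max() <= 2.0

    def test_reproducible(self):
        spec = [{"name": "a", "family": "uniform", "low": 0, "high": 1}]
        a = synth_histograms(spec, n=500, seed=2)[0]
        b = synth_histograms(spec, n=500, seed=2)[0]
        assert np.array_equal(a.samples, b.samples)

    def test_unknown_family(self):
        with pytest.raises(ConfigError):
            synth_histograms([{"name": "x", "family": "cauchy"}], n=200)

    def test_too_few_samples(self):
        with pytest.raises(ParameterError):
            synth_histograms([{"name": "x", "family": "uniform", "low": 0, "high": 1}], n=10)


class TestApcVsMonteCarlo:
    def test_logistic_ode_reduction_mean(self):
        """Level-1 aPC mean of u(T) vs direct MC on the logistic closed form.

        Reduced model: uniform fields, u(T) from the logistic solution with
        gamma = 10 alpha and growth insensitive to nu — approximately linear
        in (nu, alpha) over a narrow alpha range around 1.
        """
        from invasim.solver import logistic_solution

        T, u0 = 0.2, 0.5
        inputs = synth_histograms(
            [{"name": "nu", "family": "normal", "mean": MU, "std": SD},
             {"name": "alpha", "family": "uniform", "low": 0.9, "high": 1.1}],
            n=100_000, seed=9,
        )

        def model(nu, alpha):
            return logistic_solution(T, 10.0 * alpha, u0)

        rules = [[quadrature_from_moments(i_, k) for k in (1, 2)] for i_ in inputs]
        grid = smolyak_grid(rules, 1)
        bases = [OrthonormalBasis1D.from_moments(i_.moments, 2) for i_ in inputs]
        evals = np.array([model(*pt) for pt in grid.points])
        exp = pce_project(evals, grid, bases)
        direct = np.array([model(n_, a_) for n_, a_ in
                           zip(inputs[0].samples, inputs[1].samples)])
        se = direct.std() / np.sqrt(len(direct))
        assert abs(float(exp.mean) - direct.mean()) < 3 * se


class TestRunUQ:
    def test_five_runs_and_insensitivity(self, unit_square_mesh):
        """alpha zero-variance: std vanishes where output ignores nu."""
        from invasim.coefficients import CoefficientSet
        from invasim.solver import run_simulation

        calls = []

        def model(params):
            calls.append(params)
            co = CoefficientSet(n_nodes=unit_square_mesh.n_nodes,
                                nu=params["nu"], gamma=10.0 * params["alpha"])
            u0 = np.full(unit_square_mesh.n_nodes, 0.1)
            return run_simulation(unit_square_mesh, co, u0, dt=0.02, t_end=0.1,
                                  probes={"c": (0.5, 0.5)})

        inputs = synth_histograms(
            [{"name": "nu", "family": "normal", "mean": MU, "std": SD},
             {"name": "alpha", "family": "uniform", "low": 0.0, "high": 2.0}],
            n=2000, seed=1,
        )
        uq, diag = run_uq(model, inputs, level=1, n_mc=2000, seed=4)
        assert diag["n_runs"] == 5
        assert len(calls) == 5
        assert (uq.std_field >= 0).all()
        for edges, density in uq.probe_pdfs.values():
            assert np.sum(density * np.diff(edges)) == pytest.approx(1.0, abs=1e-9)
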