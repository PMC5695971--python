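"""KDE, entropy and mutual-information estimator tests.

Expected values come from closed forms (Gaussian entropies/MI), hand
evaluation of the kernel sums, or independent brute-force oracles
(double-loop density sums, central finite differences).
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qpatmi import mi_core as mc
from qpatmi.exceptions import (
    DegenerateDistributionError,
    GridCoverageError,
    InvalidBandwidthError,
    ShapeError,
)


def _pinned(samples, q=64, margin=4.0):
    """Fixed grids and bandwidths for a (K, M) sample matrix."""
    hs = tuple(mc.silverman_bandwidth(row) for row in samples)
    grids = tuple(mc.EvaluationGrid.for_samples(row, h, q, margin)
                  for row, h in zip(samples, hs))
    return grids, hs


class TestBandwidth:
    def test_normal_reference_coefficient_is_1_06(self):
        assert round(mc.silverman_coefficient(1), 2) == 1.06

    def test_direct_evaluation(self):
        samples = 2.0 * np.random.default_rng(0).standard_normal(1000)
        sigma = np.std(samples, ddof=1)
        expected = (4.0 / 3000.0) ** 0.2 * sigma
        assert mc.silverman_bandwidth(samples) == pytest.approx(expected, rel=1e-12)

    def test_constant_field_is_degenerate(self):
        with pytest.raises(DegenerateDistributionError):
            mc.silverman_bandwidth(np.full(50, 3.3))


class TestKernel:
    def test_peak_value(self):
        assert mc.gaussian_kernel(0.0, 1.0) == pytest.approx(1 / math.sqrt(2 * math.pi))

    @pytest.mark.parametrize("x", [0.3, 1.7, -2.2, 5.0])
    def test_even_symmetry(self, x):
        assert mc.gaussian_kernel(x, 0.8) == mc.gaussian_kernel(-x, 0.8)

    @pytest.mark.parametrize("h", [0.25, 1.0, 3.0])
    def test_unit_mass_by_quadrature(self, h):
        x = np.linspace(-8 * h, 8 * h, 20001)
        mass = np.trapezoid(mc.gaussian_kernel(x, h), x)
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_invalid_bandwidth(self):
        with pytest.raises(InvalidBandwidthError):
            mc.gaussian_kernel(0.0, 0.0)
        with pytest.raises(InvalidBandwidthError):
            mc.kernel_derivative(1.0, -1.0)

    def test_derivative_values(self):
        assert mc.kernel_derivative(0.0, 1.0) == 0.0
        assert mc.kernel_derivative(1.0, 1.0) == pytest.approx(
            mc.gaussian_kernel(1.0, 1.0))

    def test_derivative_matches_finite_difference(self):
        # d kappa(xi - c)/dc at several offsets, h values
        rng = np.random.default_rng(1)
        for _ in range(20):
            xi, c = rng.normal(size=2)
            h = 0.3 + rng.random()
            eps = 1e-6
            fd = (mc.gaussian_kernel(xi - (c + eps), h)
                  - mc.gaussian_kernel(xi - (c - eps), h)) / (2 * eps)
            assert mc.kernel_derivative(xi - c, h) == pytest.approx(fd, abs=1e-7)


class TestDensities:
    def test_single_kernel_peak(self):
        grid = mc.EvaluationGrid(np.linspace(-4, 6, 64))
        d = mc.estimate_marginal_pdf(np.array([1.0, 1.0]), grid, 0.7)
        q = np.argmin(np.abs(grid.points - 1.0))
        # both samples coincide, so the density at the closest grid point is
        # kappa evaluated at that offset
        assert d.values[q] == pytest.approx(
            mc.gaussian_kernel(grid.points[q] - 1.0, 0.7))

    def test_two_sample_hand_value(self):
        # M=2 samples {0, 1}, h=0.5, xi=0.5 -> kappa(0.5)
        grid = mc.EvaluationGrid(np.linspace(-2.5, 3.5, 25))  # hits 0.5 exactly
        d = mc.estimate_marginal_pdf(np.array([0.0, 1.0]), grid, 0.5)
        q = np.argmin(np.abs(grid.points - 0.5))
        assert grid.points[q] == pytest.approx(0.5, abs=1e-12)
        assert d.values[q] == pytest.approx(mc.gaussian_kernel(0.5, 0.5), rel=1e-12)
        assert d.values[q] == pytest.approx(0.48394, abs=5e-6)

    def test_direct_equals_loop_oracle(self, rng):
        samples = rng.standard_normal(60)
        h = mc.silverman_bandwidth(samples)
        grid = mc.EvaluationGrid.for_samples(samples, h, 48)
        d = mc.estimate_marginal_pdf(samples, grid, h).values
        oracle = np.array([
            sum(mc.gaussian_kernel(xi - c, h) for c in samples) / samples.size
            for xi in grid.points])
        np.testing.assert_allclose(d, oracle, rtol=1e-12)

    def test_fft_equals_direct_marginal(self, rng):
        samples = rng.standard_normal(100)
        h = mc.silverman_bandwidth(samples)
        grid = mc.EvaluationGrid.for_samples(samples, h, 64)
        dd = mc.estimate_marginal_pdf(samples, grid, h, "direct").values
        df = mc.estimate_marginal_pdf(samples, grid, h, "fft").values
        assert np.max(np.abs(dd - df)) / dd.max() < 1e-6

    def test_fft_equals_direct_joint(self, rng):
        samples = rng.standard_normal((2, 100))
        grids, hs = _pinned(samples)
        dd = mc.estimate_joint_pdf(samples, grids, hs, "direct").values
        df = mc.estimate_joint_pdf(samples, grids, hs, "fft").values
        assert np.max(np.abs(dd - df)) / dd.max() < 1e-6

    def test_joint_single_sample_product(self):
        a, b = 0.7, -1.2
        grids = (mc.EvaluationGrid(np.linspace(a - 3, a + 3, 31)),
                 mc.EvaluationGrid(np.linspace(b - 3, b + 3, 31)))
        sm = np.array([[a, a], [b, b]])
        d = mc.estimate_joint_pdf(sm, grids, (0.5, 0.8)).values
        qa = np.argmin(np.abs(grids[0].points - a))
        qb = np.argmin(np.abs(grids[1].points - b))
        assert d[qa, qb] == pytest.approx(
            mc.gaussian_kernel(0.0, 0.5) * mc.gaussian_kernel(0.0, 0.8), rel=1e-12)

    def test_marginalizing_joint_recovers_marginal(self, rng):
        samples = rng.standard_normal((2, 50))
        grids, hs = _pinned(samples, q=96, margin=6.0)
        joint = mc.estimate_joint_pdf(samples, grids, hs).values
        marg1 = mc.estimate_marginal_pdf(samples[0], grids[0], hs[0]).values
        recovered = joint.sum(axis=1) * grids[1].spacing
        assert np.max(np.abs(recovered - marg1)) < 1e-6

    def test_mass_near_unity(self, rng):
        samples = rng.standard_normal(200)
        h = mc.silverman_bandwidth(samples)
        grid = mc.EvaluationGrid.for_samples(samples, h)
        d = mc.estimate_marginal_pdf(samples, grid, h)
        assert 0.99 <= d.mass() <= 1.0 + 1e-9

    def test_coverage_error(self):
        grid = mc.EvaluationGrid(np.linspace(0, 1, 32))
        with pytest.raises(GridCoverageError):
            mc.estimate_marginal_pdf(np.array([0.5, 2.0]), grid, 0.1)

    def test_joint_shape_error(self, rng):
        samples = rng.standard_normal((3, 20))
        grids, hs = _pinned(samples[:2])
        with pytest.raises(ShapeError):
            mc.estimate_joint_pdf(samples, grids, hs)


class TestEntropy:
    def test_uniform_density_entropy_is_log_length(self):
        length = 4.0
        grid = mc.EvaluationGrid(np.linspace(0, length, 81))
        d = mc.DensityEstimate((grid,), np.full(81, 1 / length), (1.0,))
        assert mc.entropy(d) == pytest.approx(math.log(length), rel=1e-12)

    def test_gaussian_entropy_closed_form(self, rng):
        samples = rng.standard_normal(10_000)
        h = mc.silverman_bandwidth(samples)
        grid = mc.EvaluationGrid.for_samples(samples, h)
        d = mc.estimate_marginal_pdf(samples, grid, h)
        assert mc.entropy(d) == pytest.approx(0.5 * math.log(2 * math.pi * math.e),
                                              abs=0.05)

    def test_zero_bins_are_finite(self):
        grid = mc.EvaluationGrid(np.linspace(0, 1, 16))
        values = np.zeros(16)
        values[[4, 10]] = 1.0
        d = mc.DensityEstimate((grid,), values, (1.0,))
        assert math.isfinite(mc.entropy(d))

    def test_factorized_joint_adds_marginal_entropies(self):
        l1, l2 = 2.0, 5.0
        g1 = mc.EvaluationGrid(np.linspace(0, l1, 41))
        g2 = mc.EvaluationGrid(np.linspace(0, l2, 51))
        joint = np.full((41, 51), 1 / (l1 * l2))
        d = mc.DensityEstimate((g1, g2), joint, (1.0, 1.0))
        assert mc.joint_entropy(d) == pytest.approx(math.log(l1) + math.log(l2),
                                                    abs=1e-9)

    def test_independent_normals_joint_entropy(self, rng):
        samples = rng.standard_normal((2, 5000))
        grids, hs = _pinned(samples)
        d = mc.estimate_joint_pdf(samples, grids, hs)
        assert mc.joint_entropy(d) == pytest.approx(math.log(2 * math.pi * math.e),
                                                    abs=0.1)

    def test_joint_entropy_equals_loop_oracle(self, rng):
        samples = rng.standard_normal((2, 30))
        grids, hs = _pinned(samples, q=24)
        d = mc.estimate_joint_pdf(samples, grids, hs)
        w1 = np.ones(24); w1[0] = w1[-1] = 0.5
        vol = grids[0].spacing * grids[1].spacing
        terms = []
        for i in range(24):
            for j in range(24):
                rho = d.values[i, j]
                if rho > 1e-300:
                    terms.append(-w1[i] * w1[j] * rho * math.log(rho) * vol)
        assert mc.joint_entropy(d) == pytest.approx(math.fsum(terms), rel=1e-13)


class TestMutualInformation:
    def test_independent_samples_have_near_zero_mi(self, rng):
        samples = rng.standard_normal((2, 5000))
        assert abs(mc.mutual_information(samples).mi) < 0.05

    def test_correlated_gaussian_closed_form(self, rng):
        rho = 0.8
        cov = [[1.0, rho], [rho, 1.0]]
        samples = rng.multivariate_normal([0, 0], cov, size=5000).T
        expected = -0.5 * math.log(1 - rho ** 2)
        assert mc.mutual_information(samples).mi == pytest.approx(expected, abs=0.08)

    def test_permutation_symmetry_is_bit_exact(self, rng):
        samples = rng.multivariate_normal([0, 0], [[1, .6], [.6, 1]], size=800).T
        a = mc.mutual_information(samples)
        b = mc.mutual_information(samples[::-1])
        assert a.mi == b.mi
        assert a.marginal_entropies == b.marginal_entropies[::-1]

    def test_identity_holds_as_stored(self, rng):
        samples = rng.standard_normal((2, 300))
        r = mc.mutual_information(samples)
        assert r.mi == math.fsum(r.marginal_entropies) - r.joint_entropy

    def test_identity_violation_rejected(self):
        with pytest.raises(ShapeError):
            mc.MIResult((1.0, 1.0), 1.5, 0.7)

    def test_degenerate_chromophore_raises(self):
        samples = np.vstack([np.full(40, 2.0), np.arange(40.0)])
        with pytest.raises(DegenerateDistributionError):
            mc.mutual_information(samples)

    def test_mi_increases_with_correlation(self):
        # estimated MI is monotone in |rho| on average over seeds
        rhos = [0.0, 0.3, 0.6, 0.9]
        means = []
        for rho in rhos:
            vals = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                s = r.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=5000).T
                vals.append(mc.mutual_information(s).mi)
            means.append(np.mean(vals))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestMIGradient:
    def test_matches_finite_differences(self, rng):
        samples = rng.standard_normal((2, 40))
        grids, hs = _pinned(samples)
        gan = mc.mi_gradient(samples, grids=grids, bandwidths=hs)
        eps = 1e-5
        gfd = np.zeros_like(gan)
        for k in range(2):
            for m in range(40):
                p = samples.copy(); p[k, m] += eps
                q = samples.copy(); q[k, m] -= eps
                gfd[k, m] = (mc.mutual_information(p, grids=grids, bandwidths=hs).mi
                             - mc.mutual_information(q, grids=grids, bandwidths=hs).mi
                             ) / (2 * eps)
        assert np.max(np.abs(gan - gfd)) / np.max(np.abs(gfd)) < 1e-4

    def test_mirror_symmetric_samples_give_antisymmetric_gradient(self):
        # c1 symmetric about 0, c2 constant-pattern symmetric under the mirror
        c1 = np.array([-2.0, -1.0, -0.25, 0.25, 1.0, 2.0])
        c2 = np.array([0.5, -0.5, 1.5, 1.5, -0.5, 0.5])
        samples = np.vstack([c1, c2])
        grids, hs = _pinned(samples, q=128)
        # use mirror-symmetric grid for chromophore 1
        g1 = mc.EvaluationGrid(np.linspace(-c1.max() - 4 * hs[0],
                                           c1.max() + 4 * hs[0], 129))
        g = mc.mi_gradient(samples, grids=(g1, grids[1]), bandwidths=hs)
        # mirror pairs (i, 5-i): gradient w.r.t. c1 flips sign
        np.testing.assert_allclose(g[0], -g[0][::-1], atol=1e-9)

    def test_far_isolated_sample_has_negligible_gradient(self):
        rng = np.random.default_rng(7)
        c1 = np.concatenate([rng.standard_normal(40), [15.0]])
        c2 = np.concatenate([rng.standard_normal(40), [0.3]])
        samples = np.vstack([c1, c2])
        hs = (0.45, 0.45)
        # generous margin so no kernel tail is truncated at the grid ends
        grids = tuple(mc.EvaluationGrid.for_samples(row, h, 512, margin=8.0)
                      for row, h in zip(samples, hs))
        g = mc.mi_gradient(samples, grids=grids, bandwidths=hs)
        assert abs(g[0, -1]) < 1e-10

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(10, 25))
    def test_gradient_property_random_instances(self, seed, m):
        rng = np.random.default_rng(seed)
        samples = rng.multivariate_normal(
            [0, 0], [[1.0, 0.4], [0.4, 1.0]], size=m).T
        grids, hs = _pinned(samples, q=48)
        gan = mc.mi_gradient(samples, grids=grids, bandwidths=hs)
        eps = 1e-5
        idx = rng.integers(0, m, size=6)
        devs = []
        for k in (0, 1):
            for j in idx:
                p = samples.copy(); p[k, j] += eps
                q = samples.copy(); q[k, j] -= eps
                fd = (mc.mutual_information(p, grids=grids, bandwidths=hs).mi
                      - mc.mutual_information(q, grids=grids, bandwidths=hs).mi
                      ) / (2 * eps)
                devs.append(abs(fd - gan[k, j]))
        assert max(devs) / max(np.max(np.abs(gan)), 1e-12) < 1e-4
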