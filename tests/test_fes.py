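"""Reweighting, FES construction, block errors, Delta G and metrics."""

import math

import numpy as np
import pytest

from watercv import (FESCurve, FunnelGeometry, STANDARD_CONC_NM3, ThermoParams,
                     block_error, combine_replicas, cylindrical_density,
                     delta_g_standard, fes_from_prob, reweight_histogram,
                     sampl_metrics)
from watercv.frames import Frame
from watercv.sampl5 import OAME_TABLE


class TestReweightHistogram:
    def test_zero_bias_equals_plain_histogram(self, rng):
        x = rng.normal(size=2000)
        edges = np.linspace(-3, 3, 31)
        p = reweight_histogram(x, np.ones_like(x), edges)
        ref, _ = np.histogram(x, bins=edges)
        assert np.allclose(p, ref / ref.sum())
        assert p.sum() == pytest.approx(1.0)

    def test_constant_bias_cancels(self, rng, thermo):
        x = rng.normal(size=2000)
        edges = np.linspace(-3, 3, 31)
        w = np.full_like(x, math.exp(thermo.beta * 2.5))
        assert np.allclose(
            reweight_histogram(x, w, edges),
            reweight_histogram(x, np.ones_like(x), edges),
        )

    def test_gaussian_bias_recovers_unbiased_moments(self, rng, thermo):
        """Samples from e^{-beta(U+V)} with harmonic U and known V reweight
        back to the unbiased Gaussian mean (closed-form moments oracle)."""
        k, kv = 2.0, -0.8  # U = k/2 x^2, V = kv/2 x^2 + x (softens + tilts)
        k_tot = k + kv
        mu_b = -1.0 / k_tot  # biased ensemble mean from completing the square
        x = rng.normal(mu_b, math.sqrt(thermo.kT / k_tot), size=40_000)
        v = 0.5 * kv * x**2 + x
        w = np.exp(thermo.beta * (v - v.max()))
        mean = np.sum(w * x) / np.sum(w)
        n_eff = np.sum(w) ** 2 / np.sum(w**2)
        sigma_est = math.sqrt(thermo.kT / k) / math.sqrt(n_eff)
        assert abs(mean - 0.0) < 3 * sigma_est  # unbiased mean is 0

    def test_all_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            reweight_histogram(np.array([10.0]), np.array([1.0]),
                               np.linspace(0, 1, 5))


class TestFesFromProb:
    def test_uniform_probability_flat_fes(self, thermo):
        p = np.full(10, 0.1)
        curve = fes_from_prob(p, np.arange(10), thermo)
        assert np.allclose(curve.values, 0.0)

    def test_probability_ratio_e_gives_kt_gap(self, thermo):
        p = np.array([1.0, math.exp(-1.0)])
        p /= p.sum()
        curve = fes_from_prob(p, np.array([0, 1]), thermo)
        assert curve.values[1] - curve.values[0] == pytest.approx(thermo.kT)

    def test_min_is_zero_and_empty_bins_masked(self, thermo):
        p = np.array([0.5, 0.0, 0.5])
        curve = fes_from_prob(p, np.arange(3), thermo)
        assert np.nanmin(curve.values) == 0.0
        assert np.isnan(curve.values[1])

    def test_gaussian_probability_quadratic_fes(self, thermo):
        grid = np.linspace(-1, 1, 81)
        sigma = 0.4
        p = np.exp(-0.5 * (grid / sigma) ** 2)
        p /= p.sum()
        curve = fes_from_prob(p, grid, thermo)
        coeff = np.polyfit(grid, curve.values, 2)[0]
        assert coeff == pytest.approx(thermo.kT / (2 * sigma**2), rel=1e-6)


class TestBlockError:
    @staticmethod
    def _mean(x, w):
        return np.sum(w * x) / np.sum(w)

    def test_constant_series_zero_error(self):
        assert block_error(np.full(100, 3.3), None, self._mean) == 0.0

    def test_iid_normal_matches_standard_error(self, rng):
        errs = [
            block_error(rng.standard_normal(10_000), None, self._mean, 10)
            for _ in range(5)
        ]
        assert np.mean(errs) == pytest.approx(0.01, rel=0.5)

    def test_doubling_series_shrinks_error_sqrt2(self, rng):
        x = rng.standard_normal(5000)
        e1 = block_error(x, None, self._mean, 10)
        e2 = block_error(np.concatenate([x, x]), None, self._mean, 20)
        assert e2 == pytest.approx(e1 / math.sqrt(2), rel=0.25)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            block_error(np.arange(3), None, self._mean, 5)


def _analytic_two_basin(thermo, depth_b=0.0, depth_u=0.0):
    """FES with two Gaussian basins of known depths on a dense grid."""
    z = np.linspace(-2.0, 2.5, 4001)
    f = np.minimum(
        depth_b + 0.5 * 80 * (z + 1) ** 2,
        depth_u + 0.5 * 80 * (z - 1) ** 2,
    )
    return FESCurve(z, f - f.min())


class TestDeltaG:
    GEOM = FunnelGeometry(r_cyl=0.3)

    def test_symmetric_basins_unit_factor(self, thermo):
        """Identical basins with C0*pi*R^2*integral-factor arranged to 1 give
        exactly the free energy of confining to the cylinder area."""
        curve = _analytic_two_basin(thermo)
        dg = delta_g_standard(curve, (-2.0, 0.0), (0.5, 1.5), self.GEOM, thermo)
        # bound integral of e^{-beta(F-F_U)}: F_U averages the unbound window
        z = curve.grid
        in_b = (z >= -2.0) & (z <= 0.0)
        in_u = (z >= 0.5) & (z <= 1.5)
        f_u = curve.values[in_u].mean()
        integral = np.trapezoid(
            np.exp(-thermo.beta * (curve.values[in_b] - f_u)), z[in_b]
        )
        expected = -thermo.kT * math.log(
            STANDARD_CONC_NM3 * math.pi * self.GEOM.r_cyl**2 * integral
        )
        assert dg == pytest.approx(expected, rel=1e-12)

    def test_matches_dense_quadrature_oracle(self, thermo):
        """Two-Gaussian-basin FES: trapezoid on the working grid matches a
        10^5-point quadrature within 0.01 kcal/mol."""
        coarse = _analytic_two_basin(thermo)
        sub = FESCurve(coarse.grid[::10], coarse.values[::10])
        dg_coarse = delta_g_standard(sub, (-2.0, 0.0), (0.5, 1.5), self.GEOM, thermo)
        zf = np.linspace(-2.0, 2.5, 100_001)
        fine = FESCurve(zf, np.interp(zf, coarse.grid, coarse.values))
        dg_fine = delta_g_standard(fine, (-2.0, 0.0), (0.5, 1.5), self.GEOM, thermo)
        assert dg_coarse == pytest.approx(dg_fine, abs=0.01)

    def test_deepening_bound_basin_shifts_dg(self, thermo):
        base = _analytic_two_basin(thermo)
        shift = thermo.kT
        shifted_vals = base.values.copy()
        shifted_vals[base.grid <= 0.0] -= shift
        shifted = FESCurve(base.grid, shifted_vals - shifted_vals.min())
        dg0 = delta_g_standard(base, (-2.0, 0.0), (0.5, 1.5), self.GEOM, thermo)
        dg1 = delta_g_standard(shifted, (-2.0, 0.0), (0.5, 1.5), self.GEOM, thermo)
        assert dg1 - dg0 == pytest.approx(-shift, abs=1e-3)

    def test_doubling_radius_shifts_dg_by_kt_ln4(self, thermo):
        curve = _analytic_two_basin(thermo)
        dg1 = delta_g_standard(curve, (-2, 0), (0.5, 1.5),
                               FunnelGeometry(r_cyl=0.3), thermo)
        dg2 = delta_g_standard(curve, (-2, 0), (0.5, 1.5),
                               FunnelGeometry(r_cyl=0.6), thermo)
        assert dg1 - dg2 == pytest.approx(thermo.kT * math.log(4), rel=1e-10)

    def test_overlapping_windows_rejected(self, thermo):
        curve = _analytic_two_basin(thermo)
        with pytest.raises(ValueError, match="disjoint"):
            delta_g_standard(curve, (-2, 1), (0.5, 1.5), self.GEOM, thermo)


class TestCombineReplicas:
    def test_single_replica_identity(self):
        assert combine_replicas([(-5.0, 0.2)]) == (-5.0, 0.2)

    def test_equal_errors_average(self):
        dg, err = combine_replicas([(-5.0, 0.1), (-6.0, 0.1)])
        assert dg == pytest.approx(-5.5)
        assert err == pytest.approx(0.1 / math.sqrt(2))

    def test_three_replicas_inverse_variance_formula(self):
        vals = [(-5.0, 0.1), (-5.5, 0.2), (-4.8, 0.4)]
        w = np.array([1 / 0.01, 1 / 0.04, 1 / 0.16])
        expected = np.sum(w * [-5.0, -5.5, -4.8]) / w.sum()
        dg, err = combine_replicas(vals)
        assert dg == pytest.approx(expected, rel=1e-12)
        assert err == pytest.approx(1 / math.sqrt(w.sum()), rel=1e-12)
        assert err <= max(e for _, e in vals)

    def test_degenerate_zero_errors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            combine_replicas([(-5.0, 0.0), (-6.0, 0.0)])


class TestSamplMetrics:
    def test_perfect_agreement(self):
        x = [-6.0, -5.0, -4.0, -3.0]
        m = sampl_metrics(x, x)
        assert m["rmse"] == 0.0
        assert m["r2"] == pytest.approx(1.0)
        assert m["slope"] == pytest.approx(1.0)
        assert m["kendall_tau"] == pytest.approx(1.0)

    def test_reversed_ranking_gives_tau_minus_one(self):
        exp = [-6.0, -5.0, -4.0, -3.0]
        m = sampl_metrics(list(reversed(exp)), exp)
        assert m["kendall_tau"] == pytest.approx(-1.0)

    def test_kendall_matches_pair_counting_oracle(self, rng):
        a, b = rng.normal(size=8), rng.normal(size=8)
        concordant = discordant = 0
        for i in range(8):
            for j in range(i + 1, 8):
                sign = (a[i] - a[j]) * (b[i] - b[j])
                concordant += sign > 0
                discordant += sign < 0
        tau_a = (concordant - discordant) / (8 * 7 / 2)
        assert sampl_metrics(a, b)["kendall_tau"] == pytest.approx(tau_a)

    def test_shift_invariances(self):
        calc = OAME_TABLE["calc"].to_numpy()
        exp = OAME_TABLE["exp"].to_numpy()
        m0 = sampl_metrics(calc, exp)
        m1 = sampl_metrics(calc + 3.0, exp + 3.0)
        assert m1["rmse"] == pytest.approx(m0["rmse"])
        assert m1["kendall_tau"] == pytest.approx(m0["kendall_tau"])
        # tau invariant under strictly monotone transforms of both lists
        m2 = sampl_metrics(np.exp(calc / 2), np.exp(exp / 2))
        assert m2["kendall_tau"] == pytest.approx(m0["kendall_tau"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sampl_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCylindricalDensity:
    def _uniform_frames(self, rng, n_frames=40, n_w=2000):
        frames = []
        for _ in range(n_frames):
            coords = rng.uniform(-1.0, 1.0, size=(n_w, 3))
            frames.append(Frame(elements=["OW"] * n_w, coords=coords))
        return frames

    def test_uniform_bath_is_flat(self, rng):
        frames = self._uniform_frames(rng)
        z_edges = np.linspace(-0.8, 0.8, 5)
        r_edges = np.linspace(0.0, 0.8, 5)
        dens = cylindrical_density(frames, z_edges, r_edges)
        assert np.all(np.abs(dens - 1.0) < 0.15)

    def test_interior_empty_when_water_only_in_corner(self):
        coords = np.array([[0.75, 0.0, 0.75], [0.0, 0.75, 0.75]])
        fr = Frame(elements=["OW", "OW"], coords=coords)
        dens = cylindrical_density([fr], np.linspace(-0.8, 0.8, 3),
                                   np.linspace(0, 0.8, 3))
        assert dens[-1, -1] == pytest.approx(1.0)
        assert dens[0, 0] == 0.0

    def test_duplicating_frames_leaves_histogram_unchanged(self, rng):
        frames = self._uniform_frames(rng, n_frames=10)
        d1 = cylindrical_density(frames, np.linspace(-0.8, 0.8, 4),
                                 np.linspace(0, 0.8, 4))
        d2 = cylindrical_density(frames * 2, np.linspace(-0.8, 0.8, 4),
                                 np.linspace(0, 0.8, 4))
        assert np.allclose(d1, d2)

    def test_empty_corner_rejected(self):
        fr = Frame(elements=["OW"], coords=np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(ValueError, match="reference bin"):
            cylindrical_density([fr], np.linspace(-1, 1, 3), np.linspace(0, 1, 3))
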