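"""Coefficient rotation, SO(3) FFT correlation and group alignment."""

import numpy as np
import pytest

from flowshape.alignment import (
    align_group,
    align_pair,
    brute_force_correlate,
    correlate,
    rotate_coeffs,
)
from flowshape.harmonics import SHCoefficients, irf_fit, power_spectrum, sh_evaluate
from flowshape.wigner import euler_zyz, rotation_zyz


def geodesic_deg(r1, r2):
    cosang = (np.trace(r1 @ r2.T) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def random_coeffs(lmax, seed, decay=1.5):
    rng = np.random.default_rng(seed)
    c = rng.normal(size=(lmax + 1) ** 2)
    for l in range(lmax + 1):
        c[l * l : (l + 1) * (l + 1)] /= (1.0 + l) ** decay
    return SHCoefficients(lmax, c)


def rotation_grid(step_deg=20.0):
    angs = np.radians(np.arange(0, 360, step_deg))
    bets = np.radians(np.arange(10, 180, step_deg))
    return [rotation_zyz(a, b, g) for a in angs for b in bets for g in angs]


class TestRotateCoeffs:
    def test_identity_rotation(self, rng):
        c = random_coeffs(6, 0)
        np.testing.assert_allclose(
            rotate_coeffs(c, np.eye(3)).coeffs, c.coeffs, atol=1e-12
        )

    def test_norm_and_spectrum_preserved(self):
        c = random_coeffs(10, 1)
        r = rotation_zyz(0.3, 1.2, -2.0)
        out = rotate_coeffs(c, r)
        assert abs(np.linalg.norm(out.coeffs) - np.linalg.norm(c.coeffs)) < 1e-9
        np.testing.assert_allclose(
            power_spectrum(out).energies, power_spectrum(c).energies, rtol=1e-9
        )

    def test_dual_path_consistency_with_refit(self, ico3):
        # rotating coefficients == fitting the rotated samples
        c = random_coeffs(8, 2)
        r = rotation_zyz(1.1, 0.7, 2.4)
        rotated_samples = sh_evaluate(c, ico3.vertices @ r)  # f(R^T x)
        refit = irf_fit(rotated_samples, lmax=8, points=ico3.vertices)
        np.testing.assert_allclose(
            rotate_coeffs(c, r).coeffs, refit.coeffs, atol=1e-6
        )

    def test_rejects_non_rotation(self):
        c = random_coeffs(4, 3)
        with pytest.raises(ValueError):
            rotate_coeffs(c, np.diag([2.0, 1.0, 1.0]))


class TestCorrelate:
    def test_autocorrelation_peaks_at_identity(self):
        f = random_coeffs(8, 4)
        est = correlate(f, f, bandwidth=32)
        assert geodesic_deg(est.rotation, np.eye(3)) < 180.0 / 32
        assert abs(est.correlation - 1.0) < 1e-3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_known_rotation_recovery(self, seed):
        f = random_coeffs(10, 10 + seed)
        rng = np.random.default_rng(seed)
        a, b, g = rng.uniform(0, 2 * np.pi), rng.uniform(0.2, np.pi - 0.2), rng.uniform(0, 2 * np.pi)
        r0 = rotation_zyz(a, b, g)
        est = correlate(f, rotate_coeffs(f, r0), bandwidth=32)
        assert geodesic_deg(est.rotation, r0) < 2.0 * 180.0 / 32

    def test_recovery_improves_with_bandwidth(self):
        f = random_coeffs(8, 21)
        r0 = rotation_zyz(0.9, 1.0, -1.3)
        g = rotate_coeffs(f, r0)
        errs = [
            geodesic_deg(correlate(f, g, bandwidth=b).rotation, r0) for b in (32, 64)
        ]
        assert errs[1] <= errs[0] + 1e-9

    def test_matches_brute_force_oracle(self):
        from flowshape.alignment import _correlation_at, _residual_norms, correlation_grid

        f = random_coeffs(6, 30)
        r0 = rotation_zyz(np.radians(73), np.radians(64), np.radians(214))
        g = rotate_coeffs(f, r0)
        # values computed by the FFT agree with direct Wigner evaluation
        c, al, be, ga = correlation_grid(f, g, 32)
        den = _residual_norms(f) * _residual_norms(g)
        for (i, j, k) in [(0, 0, 0), (5, 7, 9), (40, 20, 60), (63, 30, 2)]:
            direct = _correlation_at(f, g, rotation_zyz(al[i], be[j], ga[k]))
            assert abs(c[i, j, k] / den - direct) < 1e-9
        # restricted to a subgrid of FFT grid points, the FFT peak is an
        # upper bound for the brute-force maximizer
        sub = [
            rotation_zyz(al[i], be[j], ga[k])
            for i in range(0, 64, 8)
            for j in range(0, 64, 8)
            for k in range(0, 64, 8)
        ]
        bf = brute_force_correlate(f, g, sub)
        est = correlate(f, g, bandwidth=32)
        assert est.correlation >= bf.correlation - 1e-9
        # and the coarse 20-degree oracle still lands near the truth
        bf20 = brute_force_correlate(f, g, rotation_grid(20.0))
        assert geodesic_deg(bf20.rotation, r0) < np.sqrt(3) * 20.0

    def test_mismatched_lmax_rejected(self):
        with pytest.raises(ValueError):
            correlate(random_coeffs(4, 0), random_coeffs(6, 0))


class TestBruteForce:
    def test_identity_grid_self_correlation(self):
        f = random_coeffs(5, 40)
        est = brute_force_correlate(f, f, [np.eye(3)])
        assert abs(est.correlation - 1.0) < 1e-12

    def test_grid_containing_truth_recovers_it(self):
        f = random_coeffs(5, 41)
        r0 = rotation_zyz(0.5, 0.8, 1.1)
        g = rotate_coeffs(f, r0)
        grid = rotation_grid(40.0) + [r0]
        est = brute_force_correlate(f, g, grid)
        assert geodesic_deg(est.rotation, r0) < 1e-9

    def test_empty_grid_rejected(self):
        f = random_coeffs(3, 0)
        with pytest.raises(ValueError):
            brute_force_correlate(f, f, [])


class TestAlignPair:
    def test_self_alignment_is_identity(self):
        f = random_coeffs(8, 50)
        est = align_pair(f, f, bandwidth=32)
        assert geodesic_deg(est.rotation, np.eye(3)) < 180.0 / 32
        assert est.correlation > 0.999

    def test_insensitive_to_smoothing_width(self):
        # grid-aligned true rotation: recovered rotation should not move
        # across the recommended k range
        f = random_coeffs(12, 51)
        r0 = rotation_zyz(10 * np.pi / 32, 7 * np.pi / 64, 20 * np.pi / 32)
        g = rotate_coeffs(f, r0)
        rots = [
            align_pair(f, g, k=k, bandwidth=32).rotation
            for k in (0.001, 0.005, 0.01)
        ]
        for r in rots[1:]:
            assert geodesic_deg(rots[0], r) < 2.0

    def test_correlation_scale_invariant(self):
        f = random_coeffs(8, 52)
        g = random_coeffs(8, 53)
        r1 = align_pair(f, g, bandwidth=32).correlation
        g2 = SHCoefficients(8, 7.3 * g.coeffs)
        r2 = align_pair(f, g2, bandwidth=32).correlation
        assert abs(r1 - r2) < 1e-9


class TestAlignGroup:
    def test_identical_shapes(self):
        f = random_coeffs(8, 60)
        ga = align_group([f.copy() for _ in range(4)], bandwidth=32)
        assert ga.converged
        np.testing.assert_allclose(ga.average.coeffs, f.coeffs, atol=1e-6)
        for est in ga.rotations:
            assert geodesic_deg(est.rotation, np.eye(3)) < 180.0 / 32

    def test_random_rotations_realign_coherently(self):
        f = random_coeffs(8, 61)
        rng = np.random.default_rng(61)
        shapes = [f]
        for _ in range(4):
            r = rotation_zyz(*rng.uniform(0, np.pi, size=3))
            shapes.append(rotate_coeffs(f, r))
        ga = align_group(shapes, bandwidth=32)
        s_avg = power_spectrum(ga.average).energies
        s_f = power_spectrum(f).energies
        keep = s_f > 1e-8
        assert np.abs(s_avg[keep] / s_f[keep] - 1.0).max() < 0.02

    def test_order_invariance_with_fixed_initial_target(self):
        rng = np.random.default_rng(62)
        shapes = [random_coeffs(6, 70 + i) for i in range(4)]
        ga1 = align_group(shapes, bandwidth=32)
        permuted = [shapes[0]] + [shapes[i] for i in (2, 3, 1)]
        ga2 = align_group(permuted, bandwidth=32)
        np.testing.assert_allclose(
            ga1.average.coeffs, ga2.average.coeffs, atol=1e-3
        )

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            align_group([random_coeffs(4, 0)])
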