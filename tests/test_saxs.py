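"""Scattering processing: Debye sums, Rg/Dmax, reduction, Guinier, p(r)."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

import aptaprobe as ap
from aptaprobe.errors import (
    GridMismatchError,
    InvalidUncertaintyError,
    NoGuinierRegionError,
)
from aptaprobe.saxs import pr_forward

from conftest import sphere_form_factor, sphere_pr


def brute_force_debye(model: ap.ParticleModel, s: np.ndarray) -> np.ndarray:
    """Independent O(n^2) double loop over all ordered pairs."""
    out = np.zeros_like(s)
    for i in range(model.n_points):
        for j in range(model.n_points):
            d = np.linalg.norm(model.points[i] - model.points[j])
            x = s * d
            term = np.ones_like(s)
            nz = x != 0
            term[nz] = np.sin(x[nz]) / x[nz]
            out += model.weights[i] * model.weights[j] * term
    return out


class TestDebyeIntensity:
    def test_single_point_is_unity(self):
        curve = ap.debye_intensity(ap.ParticleModel([[1, 2, 3]]),
                                   np.linspace(0, 5, 20))
        assert np.allclose(curve.I, 1.0)

    def test_two_point_closed_form(self, dumbbell):
        s = np.linspace(0.0, 6.0, 50)
        curve = ap.debye_intensity(dumbbell, s)
        expected = np.empty_like(s)
        expected[0] = 4.0
        expected[1:] = 2.0 + 2.0 * np.sin(s[1:]) / s[1:]
        assert np.allclose(curve.I, expected, rtol=1e-12)

    def test_matches_brute_force_oracle(self, chain):
        s = np.linspace(0.0, 6.0, 25)
        fast = ap.debye_intensity(chain, s).I
        brute = brute_force_debye(chain, s)
        assert np.max(np.abs(fast - brute) / brute) < 1e-10

    def test_zero_angle_is_total_weight_squared(self):
        rng = np.random.default_rng(5)
        model = ap.ParticleModel(rng.normal(size=(30, 3)),
                                 rng.uniform(0.5, 2.0, 30))
        i0 = ap.debye_intensity(model, np.array([0.0])).I[0]
        assert i0 == pytest.approx(model.weights.sum() ** 2, rel=1e-14)

    def test_rigid_motion_invariance(self, chain):
        s = np.linspace(0.1, 4.0, 30)
        ref = ap.debye_intensity(chain, s).I
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True)
        moved = ap.ParticleModel(rot.apply(chain.points) + [5.0, -2.0, 1.0],
                                 chain.weights)
        alt = ap.debye_intensity(moved, s).I
        assert np.max(np.abs(alt - ref) / ref) < 1e-10


class TestStructuralParameters:
    def test_rg_trivial_cases(self, dumbbell):
        assert ap.rg_from_model(ap.ParticleModel([[3, 1, 2]])) == 0.0
        assert ap.rg_from_model(dumbbell) == pytest.approx(0.5)

    def test_rg_of_uniform_sphere(self, sphere_cloud):
        expected = 5.0 * np.sqrt(3.0 / 5.0)
        assert ap.rg_from_model(sphere_cloud) == pytest.approx(expected, rel=0.01)

    def test_dmax_trivial_and_oracle(self, chain):
        assert ap.dmax_from_model(ap.ParticleModel([[0, 0, 0]])) == 0.0
        two = ap.ParticleModel([[0, 0, 0], [0, 11.5, 0]])
        assert ap.dmax_from_model(two) == pytest.approx(11.5)
        assert ap.dmax_from_model(chain) == pytest.approx(
            pdist(chain.points).max(), abs=0.0)

    def test_dmax_hull_path_matches_all_pairs(self, sphere_cloud):
        # 4000 points exceeds the exact-path limit and goes through the hull
        brute = pdist(sphere_cloud.points).max()
        assert ap.dmax_from_model(sphere_cloud) == pytest.approx(brute, abs=1e-12)


class TestRadialAverage:
    GEOM = ap.DetectorGeometry(700.0, 0.1445, (31.5, 31.5), 1.5)

    def test_flat_field(self):
        img = ap.DetectorImage(np.full((64, 64), 7.0), self.GEOM)
        curve = ap.radial_average(img, 12)
        assert np.allclose(curve.I, 7.0)
        assert np.all(curve.sigma <= 1e-12)

    def test_bright_ring_peaks_at_ring_radius(self):
        rows, cols = np.indices((64, 64))
        radius = np.hypot(rows - 31.5, cols - 31.5)
        counts = np.where(np.abs(radius - 20.0) < 1.0, 100.0, 1.0)
        curve = ap.radial_average(ap.DetectorImage(counts, self.GEOM), 30)
        s_ring = self.GEOM.s_of_pixels((64, 64))[31, int(31.5 + 20)]
        assert abs(curve.s[np.argmax(curve.I)] - s_ring) < 0.15

    def test_noiseless_round_trip_recovers_debye(self, chain):
        geom = ap.DetectorGeometry(700.0, 0.1445, (63.5, 63.5), 0.75)
        cfg = ap.GeneratorConfig(seed=2, noise_fraction=0.0)
        img = ap.simulate_detector_image(chain, geom, cfg, shape=(128, 128))
        curve = ap.radial_average(img, 60)
        truth = ap.debye_intensity(chain, curve.s).I
        rel = np.abs(curve.I - truth) / truth
        assert rel[2:-2].max() < 0.01

    def test_isotropic_average_is_unbiased(self, chain):
        # the mean over noisy replicates must match the noiseless binned
        # curve (unbiasedness of the bin mean under the noise model)
        cfg = ap.GeneratorConfig(seed=2, noise_fraction=0.05)
        from dataclasses import replace

        noiseless = ap.simulate_detector_image(
            chain, self.GEOM, replace(cfg, noise_fraction=0.0), shape=(64, 64))
        truth = ap.radial_average(noiseless, 16).I
        means = []
        for rep in range(40):
            img = ap.simulate_detector_image(chain, self.GEOM,
                                             cfg.with_seed(rep), shape=(64, 64))
            means.append(ap.radial_average(img, 16).I)
        means = np.array(means)
        z = (means.mean(axis=0) - truth) / (means.std(axis=0, ddof=1) / np.sqrt(40))
        assert np.mean(np.abs(z) < 2.0) >= 0.9


class TestBackgroundSubtraction:
    def _curve(self, i, sigma):
        s = np.linspace(0.2, 2.0, 10)
        return ap.ScatteringCurve(s, np.full_like(s, float(i)),
                                  np.full_like(s, float(sigma)))

    def test_self_subtraction_and_quadrature(self):
        out = ap.subtract_background(self._curve(5, 3), self._curve(5, 4))
        assert np.allclose(out.I, 0.0)
        assert np.allclose(out.sigma, 5.0)

    def test_round_trip_restores_sample(self):
        sample, bg = self._curve(8, 1), self._curve(3, 2)
        diff = ap.subtract_background(sample, bg)
        assert np.allclose(diff.I + bg.I, sample.I)

    def test_grid_mismatch_is_fatal(self):
        other = ap.ScatteringCurve(np.linspace(0.3, 2.1, 10), np.ones(10),
                                   np.ones(10))
        with pytest.raises(GridMismatchError):
            ap.subtract_background(self._curve(1, 1), other)


class TestGuinier:
    def test_exact_gaussian_recovers_rg(self):
        rg = 3.3
        s = np.linspace(0.05, 2.0, 200)
        curve = ap.ScatteringCurve(s, np.exp(-s * s * rg * rg / 3.0),
                                   np.full_like(s, 1e-3))
        est, i0, n = ap.guinier_fit(curve)
        assert est == pytest.approx(rg, abs=1e-6)
        assert i0 == pytest.approx(1.0, rel=1e-9)
        assert n >= 5

    def test_dumbbell_small_angle_expansion(self, dumbbell):
        s = np.linspace(0.05, 2.0, 300)
        deb = ap.debye_intensity(dumbbell, s)
        curve = ap.ScatteringCurve(s, deb.I, np.full_like(s, 1e-6))
        est, _, _ = ap.guinier_fit(curve, srg_limit=1.0)
        assert est == pytest.approx(0.5, rel=0.02)

    def test_flat_curve_has_zero_rg(self):
        s = np.linspace(0.1, 1.0, 20)
        curve = ap.ScatteringCurve(s, np.full_like(s, 2.0), np.full_like(s, 0.1))
        est, _, _ = ap.guinier_fit(curve)
        assert est == pytest.approx(0.0, abs=1e-6)

    def test_rising_curve_rejected(self):
        s = np.linspace(0.1, 1.0, 20)
        curve = ap.ScatteringCurve(s, np.exp(s * s), np.full_like(s, 1e-3))
        with pytest.raises(NoGuinierRegionError):
            ap.guinier_fit(curve)

    def test_error_shrinks_with_window(self):
        model = ap.generate_chain_model(ap.GeneratorConfig(seed=0))
        s = np.linspace(0.02, 1.5, 400)
        deb = ap.debye_intensity(model, s)
        curve = ap.ScatteringCurve(s, deb.I, np.full_like(s, deb.I.max() * 1e-6))
        true = ap.rg_from_model(model)
        errs = [abs(ap.guinier_fit(curve, srg_limit=lim)[0] - true)
                for lim in (1.3, 1.0, 0.7)]
        assert errs[0] >= errs[1] >= errs[2]


class TestPairDistributionFromModel:
    def test_two_point_single_bin(self, dumbbell):
        pr = ap.pr_from_model(dumbbell, 0.2)
        assert pr.d_max_support == pytest.approx(1.0)
        occupied = pr.r[pr.p > 0]
        assert occupied.size == 1 and abs(occupied[0] - 1.0) <= 0.1

    def test_unit_area(self, chain):
        pr = ap.pr_from_model(chain, 0.1)
        assert np.trapezoid(pr.p, pr.r) == pytest.approx(1.0, abs=1e-9)
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0

    def test_uniform_sphere_closed_form(self, sphere_cloud):
        pr = ap.pr_from_model(sphere_cloud, 0.25)
        truth = sphere_pr(pr.r, 5.0)
        rel_rms = (np.sqrt(np.mean((pr.p - truth) ** 2))
                   / np.sqrt(np.mean(truth ** 2)))
        assert rel_rms < 0.02

    def test_forward_transform_consistent_with_debye(self, chain):
        s = np.linspace(0.1, 2.0, 30)
        truth = ap.debye_intensity(chain, s).I
        self_term = float(np.sum(chain.weights ** 2))
        cross_total = chain.weights.sum() ** 2 - self_term
        for bw, tol in ((0.1, 0.02), (0.05, 0.01)):
            pr = ap.pr_from_model(chain, bw)
            cross = pr_forward(pr, s).I / (4.0 * np.pi) * cross_total
            err = np.max(np.abs(self_term + cross - truth) / truth)
            assert err < tol


class TestIndirectTransform:
    def _sphere_curve(self, radius=4.0, rel_sigma=0.01):
        s = np.linspace(0.05, 3.0, 150)
        i = sphere_form_factor(s, radius)
        # sigma floored away from the form-factor zeros, as a counting
        # floor would be in practice
        return ap.ScatteringCurve(s, i, rel_sigma * (i + 1e-3 * i.max()))

    def test_recovers_sphere_pr(self):
        curve = self._sphere_curve()
        pr = ap.pr_from_curve(curve, 8.0)
        truth = sphere_pr(pr.r, 4.0)
        rel_rms = (np.sqrt(np.mean((pr.p - truth) ** 2))
                   / np.sqrt(np.mean(truth ** 2)))
        assert rel_rms < 0.03

    def test_forward_fit_quality(self):
        pr = ap.pr_from_curve(self._sphere_curve(), 8.0)
        assert pr.fit_chi2 <= 2.0
        assert pr.fit is not None and pr.alpha is not None

    def test_fit_chi2_nondecreasing_in_alpha(self):
        curve = self._sphere_curve()
        chi2s = [ap.pr_from_curve(curve, 8.0, alpha=a).fit_chi2
                 for a in (1e-4, 1e-1, 1e2, 1e5)]
        assert all(a <= b + 1e-9 for a, b in zip(chi2s, chi2s[1:]))

    def test_sigma_required(self):
        s = np.linspace(0.05, 3.0, 50)
        curve = ap.ScatteringCurve(s, sphere_form_factor(s, 4.0))
        with pytest.raises(InvalidUncertaintyError):
            ap.pr_from_curve(curve, 8.0)

    def test_dmax_scan_finds_sphere_diameter(self):
        est, pr = ap.estimate_dmax(self._sphere_curve(), 4.0, 14.0,
                                   n_candidates=11, alpha=1.0)
        assert est == pytest.approx(8.0, abs=1.1)
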