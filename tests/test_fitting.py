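"""Robust sphere fitting: quadruple sampling, histogram initialization,
two-stage pruning, the geometric least-squares estimator and their
invariances."""

import numpy as np
import pytest

from ctwear import (
    FitConfig,
    FittingError,
    InsufficientPointsError,
    fit_sphere,
    initial_radius_estimate,
    least_squares_sphere,
    prune_landmarks,
    sample_quadruples,
)
from ctwear.extraction import SurfacePointSet
from ctwear.geometry import circumsphere

from conftest import sphere_points


def point_set(points) -> SurfacePointSet:
    return SurfacePointSet(points=np.asarray(points, dtype=float))


@pytest.fixture(scope="module")
def clean_sphere_set():
    rng = np.random.default_rng(100)
    return point_set(sphere_points(rng, (10.0, -3.0, 44.0), 27.105, 5000))


class TestSampleQuadruples:
    def test_postconditions(self):
        rng = np.random.default_rng(0)
        pts = point_set(sphere_points(rng, (0, 0, 0), 10.0, 1000))
        cfg = FitConfig(n_samples=100, rng_seed=1)
        quads = sample_quadruples(pts, cfg)
        assert quads.shape == (100, 4)
        p = pts.points[quads]
        for i in range(4):
            for j in range(i + 1, 4):
                d = np.linalg.norm(p[:, i] - p[:, j], axis=1)
                assert (d >= cfg.min_pair_separation).all()

    def test_clustered_points_rejected(self):
        rng = np.random.default_rng(1)
        pts = point_set(rng.uniform(0, 0.9, size=(200, 3)))  # inside a 1 mm ball
        with pytest.raises(InsufficientPointsError):
            sample_quadruples(pts, FitConfig(n_samples=10, rng_seed=1))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        pts = point_set(sphere_points(rng, (0, 0, 0), 15.0, 500))
        cfg = FitConfig(n_samples=200, rng_seed=7)
        assert np.array_equal(sample_quadruples(pts, cfg), sample_quadruples(pts, cfg))

    def test_only_valid_points_used(self):
        rng = np.random.default_rng(3)
        pts = point_set(sphere_points(rng, (0, 0, 0), 15.0, 500))
        pts.valid[250:] = False
        quads = sample_quadruples(pts, FitConfig(n_samples=300, rng_seed=3))
        assert quads.max() < 250


class TestInitialRadiusEstimate:
    def test_exact_sphere_within_one_bin(self):
        rng = np.random.default_rng(4)
        pts = point_set(sphere_points(rng, (5, 5, 40), 11.05, 2000))
        r0, c0 = initial_radius_estimate(pts, FitConfig(n_samples=20000, rng_seed=4))
        assert abs(r0 - 11.05) <= 0.1  # one 0.1 mm bin
        assert np.linalg.norm(c0 - (5, 5, 40)) < 0.2

    def test_hemisphere_unbiased(self):
        """Cup-style hemispherical coverage does not bias the circumsphere
        radius histogram."""
        rng = np.random.default_rng(5)
        pts = point_set(
            sphere_points(rng, (0, 0, 0), 27.1, 2000, hemisphere_axis=(0, 0, 1))
        )
        r0, _ = initial_radius_estimate(pts, FitConfig(n_samples=20000, rng_seed=5))
        assert abs(r0 - 27.1) <= 0.1

    def test_mode_robust_to_gross_outliers(self):
        rng = np.random.default_rng(6)
        inliers = sphere_points(rng, (0, 0, 0), 27.105, 1800, noise_sd=0.02)
        outliers = sphere_points(rng, (0, 0, 0), 40.0, 200, noise_sd=0.5)
        pts = point_set(np.vstack([inliers, outliers]))
        r0, _ = initial_radius_estimate(pts, FitConfig(n_samples=30000, rng_seed=6))
        assert abs(r0 - 27.105) <= 0.15


class TestPruneLandmarks:
    def test_no_pruning_on_exact_sphere(self, clean_sphere_set):
        cfg = FitConfig(n_samples=20000, rng_seed=8)
        pruned = prune_landmarks(clean_sphere_set, 27.105, cfg.coarse_tolerance, cfg)
        assert pruned.n_valid == len(clean_sphere_set)
        assert pruned.offending_count.sum() == 0

    def test_cup_like_reduction(self):
        """~15,000 cup points with hole-edge outliers prune to the
        12,500-13,000 band (relative offending mode)."""
        rng = np.random.default_rng(10)
        c = np.array([10.0, 20.0, 30.0])
        inliers = sphere_points(
            rng, c, 27.105, 12750, noise_sd=0.03, hemisphere_axis=(0, 0, 1)
        )
        v = rng.normal(size=(2250, 3))
        v[:, 2] = np.abs(v[:, 2]) * 3 + 1  # concentrated near the pole
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        edge = c + v * (27.105 - rng.uniform(2.5, 5.0, 2250))[:, None]
        pts = point_set(np.vstack([inliers, edge]))
        cfg = FitConfig(rng_seed=5, offending_fraction=0.7)
        r0, _ = initial_radius_estimate(pts, cfg)
        coarse = prune_landmarks(pts, r0, cfg.coarse_tolerance, cfg)
        fine = prune_landmarks(coarse, r0, cfg.fine_tolerance, cfg)
        assert 12500 <= coarse.n_valid <= 13000
        assert 12500 <= fine.n_valid <= 13000

    def test_head_like_reduction(self):
        """~2,000 head points, half of them off-surface clutter, prune to
        the 950-1,100 band."""
        rng = np.random.default_rng(11)
        inliers = sphere_points(rng, (0, 0, 0), 11.05, 1000, noise_sd=0.03)
        clutter = sphere_points(rng, (0, 0, 0), 20.0, 1000, noise_sd=1.0)
        pts = point_set(np.vstack([inliers, clutter]))
        cfg = FitConfig(rng_seed=5, offending_fraction=0.93)
        r0, _ = initial_radius_estimate(pts, cfg)
        assert abs(r0 - 11.05) <= 0.1
        coarse = prune_landmarks(pts, r0, cfg.coarse_tolerance, cfg)
        assert 950 <= coarse.n_valid <= 1100
        # the kept set is overwhelmingly the true surface
        assert coarse.valid[:1000].sum() > 950

    def test_monotone_valid_sets(self):
        """fine-pruned valid set is a subset of coarse-pruned, which is a
        subset of the initial set."""
        rng = np.random.default_rng(12)
        inliers = sphere_points(rng, (0, 0, 0), 20.0, 4000, noise_sd=0.05)
        outliers = rng.uniform(-30, 30, size=(1000, 3))
        pts = point_set(np.vstack([inliers, outliers]))
        cfg = FitConfig(n_samples=40000, rng_seed=12, offending_fraction=0.75)
        r0, _ = initial_radius_estimate(pts, cfg)
        coarse = prune_landmarks(pts, r0, cfg.coarse_tolerance, cfg)
        fine = prune_landmarks(coarse, r0, cfg.fine_tolerance, cfg)
        assert np.all(~coarse.valid | pts.valid)
        assert np.all(~fine.valid | coarse.valid)

    def test_all_pruned_is_fitting_error(self):
        rng = np.random.default_rng(13)
        pts = point_set(sphere_points(rng, (0, 0, 0), 15.0, 200))
        cfg = FitConfig(n_samples=5000, rng_seed=13, offending_fraction=0.01)
        # absurd target radius: every quadruple offends, every point removed
        with pytest.raises(FittingError):
            prune_landmarks(pts, 90.0, 0.5, cfg)


class TestLeastSquaresSphere:
    def test_four_exact_points_match_circumsphere(self):
        rng = np.random.default_rng(14)
        quad = sphere_points(rng, (3, 4, 5), 9.0, 4)
        ref = circumsphere(*quad)
        fit = least_squares_sphere(quad)
        assert np.linalg.norm(fit.center - ref.center) < 1e-8
        assert abs(fit.radius - ref.radius) < 1e-8

    def test_radius_bias_small_under_noise(self):
        """Monte-Carlo: radial Gaussian noise of 0.05 mm on 2,000 points
        leaves the mean radius error below 0.005 mm."""
        rng = np.random.default_rng(15)
        errs = [
            least_squares_sphere(
                sphere_points(rng, (0, 0, 0), 11.05, 2000, noise_sd=0.05)
            ).radius
            - 11.05
            for _ in range(20)
        ]
        assert abs(np.mean(errs)) < 0.005

    def test_hemisphere_center_recovery(self):
        rng = np.random.default_rng(16)
        errs = []
        for _ in range(10):
            pts = sphere_points(
                rng, (1, 2, 3), 27.1, 2000, noise_sd=0.05, hemisphere_axis=(0, 0, 1)
            )
            fit = least_squares_sphere(pts)
            errs.append(np.linalg.norm(fit.center - (1, 2, 3)))
        assert np.mean(errs) < 0.01

    def test_coplanar_raises(self):
        pts = np.column_stack(
            [np.random.default_rng(17).uniform(-5, 5, (50, 2)), np.zeros(50)]
        )
        from ctwear import DegenerateGeometryError

        with pytest.raises(DegenerateGeometryError):
            least_squares_sphere(pts)


class TestFitSphere:
    def test_exact_recovery(self, clean_sphere_set):
        cfg = FitConfig(n_samples=20000, rng_seed=18)
        model, report = fit_sphere(clean_sphere_set, cfg)
        assert np.linalg.norm(model.center - (10.0, -3.0, 44.0)) < 1e-6
        assert abs(model.radius - 27.105) < 1e-6
        assert report.n_valid_points == report.n_initial_points == 5000
        assert abs(report.initial_radius - 27.105) <= 0.1

    def test_agrees_with_direct_least_squares_when_clean(self, clean_sphere_set):
        cfg = FitConfig(n_samples=20000, rng_seed=19)
        model, _ = fit_sphere(clean_sphere_set, cfg)
        direct = least_squares_sphere(clean_sphere_set.points)
        assert np.linalg.norm(model.center - direct.center) < 1e-6
        assert abs(model.radius - direct.radius) < 1e-6

    def test_translation_equivariance_rotation_invariance(self):
        rng = np.random.default_rng(20)
        pts = sphere_points(rng, (0, 0, 0), 14.0, 3000, noise_sd=0.05)
        cfg = FitConfig(n_samples=20000, rng_seed=20)
        base, _ = fit_sphere(point_set(pts), cfg)
        t = np.array([5.0, -7.0, 11.0])
        shifted, _ = fit_sphere(point_set(pts + t), cfg)
        assert np.linalg.norm(shifted.center - (base.center + t)) < 1e-6
        assert abs(shifted.radius - base.radius) < 1e-6
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rotated, _ = fit_sphere(point_set(pts @ q.T), cfg)
        assert abs(rotated.radius - base.radius) < 1e-6

    def test_robust_to_twenty_percent_gross_outliers(self):
        rng = np.random.default_rng(21)
        inliers = sphere_points(rng, (0, 0, 0), 27.105, 4000)
        outliers = sphere_points(rng, (0, 0, 0), 40.0, 1000, noise_sd=2.0)
        pts = point_set(np.vstack([inliers, outliers]))
        cfg = FitConfig(n_samples=30000, rng_seed=21, offending_fraction=0.75)
        model, report = fit_sphere(pts, cfg)
        assert abs(model.radius - 27.105) < 0.1
        assert report.n_valid_points < len(pts)
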