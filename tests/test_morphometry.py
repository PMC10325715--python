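"""Ellipsoid moments, feature extraction, classification, census, vesicles."""

import numpy as np
import pandas as pd
import pytest

import vlconn as vl
from vlconn.generate import TRAINING_SET_MIX, rasterize_ellipsoid
from vlconn.morphometry import DegenerateMaskError


def make_mask(semi_axes, rotation=None, voxel_nm=(200, 200, 200), true_type=None):
    rot = np.eye(3) if rotation is None else rotation
    vox = rasterize_ellipsoid(np.asarray(semi_axes, dtype=float), rot, voxel_nm)
    return vl.CellBodyMask(vox, voxel_nm, true_type=true_type)


def rotation_matrix(axis, angle):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    K = np.cross(np.eye(3), axis)
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K


class TestEllipsoidFit:
    def test_ball_recovers_radius(self):
        fit = vl.fit_ellipsoid(make_mask([5.0, 5.0, 5.0]))
        np.testing.assert_allclose(fit.semi_axes_um, 5.0, rtol=0.05)

    def test_anisotropic_ellipsoid_recovered(self):
        fit = vl.fit_ellipsoid(make_mask([8.0, 4.0, 2.0]))
        np.testing.assert_allclose(fit.semi_axes_um, [8.0, 4.0, 2.0], rtol=0.05)

    def test_rotated_ellipsoid_recovered(self):
        rot = rotation_matrix([1, 1, 0], 0.7)
        fit = vl.fit_ellipsoid(make_mask([8.0, 4.0, 2.0], rotation=rot))
        np.testing.assert_allclose(fit.semi_axes_um, [8.0, 4.0, 2.0], rtol=0.05)

    def test_orientation_orthonormal(self):
        fit = vl.fit_ellipsoid(make_mask([6.0, 3.0, 2.0]))
        np.testing.assert_allclose(fit.orientation.T @ fit.orientation, np.eye(3), atol=1e-10)

    def test_coplanar_mask_raises(self):
        plane = np.array([[i, j, 0] for i in range(5) for j in range(5)])
        with pytest.raises(DegenerateMaskError, match="coplanar"):
            vl.fit_ellipsoid(vl.CellBodyMask(plane, (200, 200, 200)))

    def test_anisotropic_voxels_applied_before_covariance(self):
        # the same voxel indices at different anisotropy give scaled axes
        vox = rasterize_ellipsoid(np.array([4.0, 4.0, 4.0]), np.eye(3), (500, 500, 500))
        iso = vl.fit_ellipsoid(vl.CellBodyMask(vox, (500, 500, 500)))
        stretched = vl.fit_ellipsoid(vl.CellBodyMask(vox, (500, 500, 1000)))
        assert stretched.semi_axes_um[0] == pytest.approx(2 * iso.semi_axes_um[0], rel=0.05)


class TestFeatures:
    def test_ball_sphericity_near_one(self):
        f = vl.compute_features(make_mask([5.0, 5.0, 5.0]))
        assert 0.95 <= f.sphericity <= 1.0

    def test_thomsen_area_close_to_exact(self):
        approx = vl.ellipsoid_surface_area(8, 4, 2)
        exact = vl.ellipsoid_surface_area(8, 4, 2, exact=True)
        assert abs(approx - exact) / exact < 0.011

    def test_isotropic_scaling_contract(self):
        f1 = vl.compute_features(make_mask([4.0, 3.0, 2.0]))
        f2 = vl.compute_features(make_mask([8.0, 6.0, 4.0]))
        assert f2.volume_um3 == pytest.approx(8 * f1.volume_um3, rel=0.05)
        assert f2.surface_area_um2 == pytest.approx(4 * f1.surface_area_um2, rel=0.05)
        assert f2.sphericity == pytest.approx(f1.sphericity, rel=0.02)

    def test_rotation_invariance_volume_and_sphericity(self):
        f0 = vl.compute_features(make_mask([7.0, 3.0, 2.0]))
        rot = rotation_matrix([0, 1, 1], 1.1)
        f1 = vl.compute_features(make_mask([7.0, 3.0, 2.0], rotation=rot))
        assert f1.volume_um3 == pytest.approx(f0.volume_um3, rel=0.05)
        assert f1.sphericity == pytest.approx(f0.sphericity, rel=0.05)


@pytest.fixture(scope="module")
def training_features(default_config):
    pop = vl.generate_soma_population(default_config, TRAINING_SET_MIX, seed=21)
    return vl.features_table(pop)


class TestClassifier:
    def test_loo_error_low_and_no_ln_confusion(self, training_features):
        res = vl.cross_validate_loo(training_features, training_features["true_type"], seed=0)
        assert res["error_rate"] <= 0.10
        assert res["per_class_errors"].get("LN", 0) == 0

    def test_duplicating_training_points_keeps_predictions(self, training_features):
        y = training_features["true_type"]
        clf1 = vl.train_classifier(training_features, y, seed=0)
        doubled = pd.concat([training_features, training_features], ignore_index=True)
        clf2 = vl.train_classifier(doubled, pd.concat([y, y], ignore_index=True), seed=0)
        np.testing.assert_array_equal(
            clf1.predict(training_features), clf2.predict(training_features)
        )

    def test_shuffled_labels_near_chance(self, training_features):
        rng = np.random.default_rng(5)
        shuffled = rng.permutation(training_features["true_type"].to_numpy())
        res = vl.cross_validate_loo(training_features, shuffled, seed=0)
        assert res["error_rate"] >= 0.30  # far above the ~0 signal error

    def test_single_class_raises(self, training_features):
        with pytest.raises(ValueError, match="2 classes"):
            vl.train_classifier(training_features, ["SAM"] * len(training_features))


class TestCensus:
    def test_point_estimates_reproduce_reported_numbers(self):
        labels = ["SAM"] * 893 + ["CAM"] * 16 + ["LN"] * 6 + ["Other"] * 85
        est = vl.census(labels, total_cells=25e6, error_rate=0.0401)
        assert vl.in_millions(est.estimates["SAM"]) == 22.3
        assert vl.in_thousands(est.estimates["CAM"]) == 400
        assert vl.in_millions(est.upper_bounds["CAM"]) == 1.4

    def test_fractions_sum_to_one_and_estimates_conserve_total(self):
        labels = ["SAM"] * 40 + ["CAM"] * 7 + ["LN"] * 3
        est = vl.census(labels, total_cells=1e6)
        assert sum(est.fractions.values()) == pytest.approx(1.0)
        assert sum(est.estimates.values()) == pytest.approx(1e6)
        assert all(est.upper_bounds[k] >= est.estimates[k] for k in est.estimates)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            vl.census([])
        with pytest.raises(ValueError):
            vl.census(["SAM"], error_rate=1.5)


class TestVesicles:
    def test_two_disjoint_discs(self):
        img = np.zeros((40, 40), dtype=bool)
        yy, xx = np.mgrid[:40, :40]
        img |= (yy - 10) ** 2 + (xx - 10) ** 2 <= 25
        img |= (yy - 28) ** 2 + (xx - 28) ** 2 <= 25
        model = vl.vesicle_model(img)
        assert model.count == 2
        np.testing.assert_allclose(model.radii_px, 5.0, atol=0.5)

    def test_overlapping_discs_split_by_watershed(self):
        img = np.zeros((40, 60), dtype=bool)
        yy, xx = np.mgrid[:40, :60]
        img |= (yy - 20) ** 2 + (xx - 22) ** 2 <= 64
        img |= (yy - 20) ** 2 + (xx - 34) ** 2 <= 64  # centers 12 px apart, r=8
        model = vl.vesicle_model(img)
        assert model.count == 2

    def test_single_disc_center(self):
        img = np.zeros((30, 30), dtype=bool)
        yy, xx = np.mgrid[:30, :30]
        img |= (yy - 14) ** 2 + (xx - 17) ** 2 <= 36
        model = vl.vesicle_model(img)
        assert model.count == 1
        np.testing.assert_allclose(model.centers[0], [14, 17], atol=0.5)

    def test_empty_annotation_counts_zero(self):
        model = vl.vesicle_model(np.zeros((10, 10), dtype=bool))
        assert model.count == 0
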