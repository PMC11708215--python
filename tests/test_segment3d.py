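"""3D segmentation pipeline: blur, Otsu, morphology, labeling, measurement."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu

from ovotools import segment3d as s3
from ovotools import synthgen as sg


def brute_force_otsu(volume, nbins=256):
    """Independent oracle: exhaustive between-class-variance maximization."""
    v = np.asarray(volume, float).ravel()
    hist, edges = np.histogram(v, bins=nbins, range=(v.min(), v.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = hist.sum()
    variances = np.full(nbins - 1, -np.inf)
    for k in range(nbins - 1):
        n0 = hist[: k + 1].sum()
        n1 = n - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1 :] * centers[k + 1 :]).sum() / n1
        variances[k] = (n0 / n) * (n1 / n) * (mu0 - mu1) ** 2
    # lowest threshold within round-off of the maximum (plateaus over empty
    # bins are exact ties in exact arithmetic)
    vmax = variances.max()
    best_k = int(np.argmax(variances >= vmax - 1e-12 * abs(vmax)))
    return edges[best_k + 1]


class TestGaussianBlur:
    def test_zero_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 10, 12))
        np.testing.assert_array_equal(s3.gaussian_blur_3d(v, (0, 0, 0)), v)

    def test_constant_stack_unchanged(self):
        v = np.full((6, 8, 8), 7.0)
        np.testing.assert_allclose(s3.gaussian_blur_3d(v, (5, 5, 1)), v)

    def test_interior_blob_total_conserved(self):
        v = np.zeros((30, 30, 30))
        v[12:18, 12:18, 12:18] = 5.0
        bl = s3.gaussian_blur_3d(v, (2, 2, 1))
        assert bl.sum() == pytest.approx(v.sum(), rel=1e-6)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            s3.gaussian_blur_3d(np.zeros((3, 3, 3)), (-1, 1, 1))


class TestOtsu:
    def test_perfect_bimodal_separation(self):
        v = np.zeros((10, 10, 10))
        v.ravel()[:100] = 1000.0
        mask = s3.otsu_threshold(v)
        assert mask.sum() == 100

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            v = rng.normal(0, 1, (12, 12, 12))
            v[3:7, 3:7, 3:7] += rng.uniform(4, 10)
            assert s3.otsu_threshold_value(v) == pytest.approx(
                brute_force_otsu(v), rel=1e-12
            )

    def test_close_to_skimage_reference(self):
        rng = np.random.default_rng(3)
        v = rng.normal(0, 1, (15, 15, 15))
        v[4:10, 4:10, 4:10] += 8
        mine = s3.otsu_threshold_value(v)
        ref = threshold_otsu(v, nbins=256)
        bin_width = np.ptp(v) / 256
        assert abs(mine - ref) <= bin_width  # conventions differ by <= 1 bin

    def test_sphere_phantom_mask_recovers_sphere(self):
        v = np.zeros((24, 24, 24))
        zz, yy, xx = np.ogrid[:24, :24, :24]
        sphere = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 36
        v[sphere] = 100.0
        mask = s3.otsu_threshold(s3.gaussian_blur_3d(v, (1, 1, 1)))
        # mask may be dilated by up to ~sigma but must contain the sphere core
        assert (mask & sphere).sum() / sphere.sum() > 0.95
        assert mask.sum() <= 1.6 * sphere.sum()

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            s3.otsu_threshold(np.ones((5, 5, 5)))


class TestRefineMask:
    def test_empty_stays_empty(self):
        m = np.zeros((8, 8, 8), bool)
        assert not s3.refine_mask(m).any()

    def test_solid_cube_kept_up_to_shell(self):
        m = np.zeros((14, 14, 14), bool)
        m[2:12, 2:12, 2:12] = True
        out = s3.refine_mask(m)
        core = np.zeros_like(m)
        core[3:11, 3:11, 3:11] = True
        assert out[core].all()
        assert out.sum() <= m.sum()

    def test_interior_hole_filled(self):
        zz, yy, xx = np.ogrid[:20, :20, :20]
        r2 = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2
        m = (r2 <= 64) & (r2 > 4)  # sphere with a hollow core
        out = s3.refine_mask(m)
        assert out[10, 10, 10]


class TestLabelComponents:
    def test_two_spheres_counted_and_measured(self):
        v = np.zeros((20, 40, 20))
        zz, yy, xx = np.ogrid[:20, :40, :20]
        s1 = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 25
        s2 = (zz - 10) ** 2 + (yy - 30) ** 2 + (xx - 10) ** 2 <= 25
        v[s1 | s2] = 50.0
        lv = s3.label_components(s1 | s2, v, (1.0, 1.0, 1.0))
        assert len(lv.table) == 2
        analytic = 4 / 3 * np.pi * 125
        for vol in lv.table["volume_um3"]:
            assert vol == pytest.approx(analytic, rel=0.05)

    def test_min_voxels_filters_everything(self):
        m = np.zeros((10, 10, 10), bool)
        m[4, 4, 4] = True
        lv = s3.label_components(m, np.ones((10, 10, 10)), (1, 1, 1), min_voxels=10)
        assert len(lv.table) == 0
        assert not lv.labels.any()

    def test_volume_exactly_count_times_voxel(self):
        m = np.zeros((10, 10, 10), bool)
        m[2:6, 2:6, 2:6] = True
        lv = s3.label_components(m, np.ones_like(m, float), (3.0, 0.5, 0.5))
        assert lv.table["volume_um3"].iloc[0] == 64 * 3.0 * 0.5 * 0.5

    def test_label_count_invariant_to_intensity_rescale(self):
        rng = np.random.default_rng(2)
        m = rng.random((12, 12, 12)) > 0.8
        raw = rng.random((12, 12, 12))
        a = s3.label_components(m, raw, (1, 1, 1), min_voxels=1)
        b = s3.label_components(m, 100 * raw, (1, 1, 1), min_voxels=1)
        assert len(a.table) == len(b.table)


class TestPhantomRecovery:
    """End-to-end macro pipeline on zero-noise nurse-nucleus phantoms."""

    def test_count_volume_intensity(self, nurse_phantom):
        lv = s3.segment_nuclei(
            nurse_phantom.stack, "histone", sigma=(1.2, 1.2, 0.6)
        )
        truth = nurse_phantom.truth
        assert len(lv.table) == len(truth)
        tree = cKDTree(
            truth[["centroid_z_um", "centroid_y_um", "centroid_x_um"]]
        )
        for _, row in lv.table.iterrows():
            d, i = tree.query(
                [row["centroid_z_um"], row["centroid_y_um"], row["centroid_x_um"]]
            )
            ref = truth.iloc[i]
            assert d < 2.0
            analytic = 4 / 3 * np.pi * ref["radius_um"] ** 3
            assert row["volume_um3"] == pytest.approx(analytic, rel=0.05)
            assert row["total_intensity"] == pytest.approx(
                ref["histone_total"], rel=0.01
            )

    def test_measurements_on_raw_invariant_to_mask_path_params(self, nurse_phantom):
        # same final label set -> identical raw measurements
        a = s3.segment_nuclei(nurse_phantom.stack, "histone", sigma=(1.2, 1.2, 0.6))
        b = s3.segment_nuclei(
            nurse_phantom.stack, "histone", sigma=(1.2, 1.2, 0.6), min_voxels=20
        )
        if np.array_equal(a.labels, b.labels):
            np.testing.assert_allclose(
                a.table["total_intensity"], b.table["total_intensity"]
            )


class TestMidsectionArea:
    def test_ellipsoid_area_from_follicle_centroids(self, full_phantom):
        a, b, _ = full_phantom.geometry["semi_axes_um"]
        z, area = s3.midsection_area(full_phantom.labels)
        assert area == pytest.approx(np.pi * a * b, rel=0.10)

    def test_midsection_z_at_center_for_symmetric_chamber(self, full_phantom):
        nz = full_phantom.stack.shape[0]
        z, _ = s3.midsection_area(full_phantom.labels)
        assert abs(z - (nz - 1) / 2) <= 1.5

    def test_mask_path_close_to_analytic(self, full_phantom):
        a, b, _ = full_phantom.geometry["semi_axes_um"]
        mask = full_phantom.compartments > 0
        _, area = s3.midsection_area(mask, full_phantom.stack.voxel_size)
        assert area == pytest.approx(np.pi * a * b, rel=0.03)

    def test_calibration_scaling(self):
        # same ellipse at double resolution and half pixel pitch: same um^2
        def ellipse_mask(ny, nx, dy, dx):
            yy, xx = np.ogrid[:ny, :nx]
            return (
                ((yy * dy - ny * dy / 2) / 10) ** 2
                + ((xx * dx - nx * dx / 2) / 20) ** 2
            ) <= 1

        m1 = ellipse_mask(40, 60, 1.0, 1.0)[None]
        m2 = ellipse_mask(80, 120, 0.5, 0.5)[None]
        _, a1 = s3.midsection_area(m1, (1.0, 1.0, 1.0))
        _, a2 = s3.midsection_area(m2, (1.0, 0.5, 0.5))
        assert a2 == pytest.approx(a1, rel=0.02)

    def test_too_few_nuclei_rejected(self):
        import pandas as pd

        lv = s3.LabelVolume(
            np.zeros((3, 3, 3), np.int32),
            (1, 1, 1),
            pd.DataFrame(
                {
                    "label": [1],
                    "centroid_z_um": [1.0],
                    "centroid_y_um": [1.0],
                    "centroid_x_um": [1.0],
                }
            ),
        )
        with pytest.raises(ValueError):
            s3.midsection_area(lv)


class TestRegisterTranslation:
    def test_constructed_shift_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.random((40, 50))
        b = np.roll(a, (3, -2), axis=(0, 1))
        assert s3.register_translation(a, b) == (3, -2)

    def test_identical_frames(self):
        rng = np.random.default_rng(1)
        a = rng.random((30, 30))
        assert s3.register_translation(a, a) == (0, 0)

    def test_noisy_shift_within_one_pixel(self):
        rng = np.random.default_rng(2)
        base = np.zeros((64, 64))
        base[20:40, 25:45] = 10.0
        noise_sd = 10.0 / 5  # SNR 5
        a = base + rng.normal(0, noise_sd, base.shape)
        b = np.roll(base, (4, -3), axis=(0, 1)) + rng.normal(0, noise_sd, base.shape)
        dy, dx = s3.register_translation(a, b)
        assert abs(dy - 4) <= 1 and abs(dx + 3) <= 1

    def test_3d_frames_use_projection(self):
        rng = np.random.default_rng(3)
        a3 = rng.random((5, 30, 30))
        b3 = np.roll(a3, (2, 1), axis=(1, 2))
        assert s3.register_translation(a3, b3) == (2, 1)

    def test_constant_frames_rejected(self):
        with pytest.raises(ValueError):
            s3.register_translation(np.ones((10, 10)), np.ones((10, 10)))


class TestResampleZ:
    def test_shape_and_measurement_grid_untouched(self):
        v = np.zeros((4, 6, 6))
        v[1:3, 2:4, 2:4] = 1.0
        out = s3.resample_z(v, 3)
        assert out.shape == (12, 6, 6)
        assert v.shape == (4, 6, 6)
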