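"""Edge-detection tests: grayscale conversion, the normalised Sobel
operator, fixture-area accuracy of all three detectors, invariances, and
failure modes."""

import numpy as np
import pytest

import edgesense as es
from edgesense import detection as det

TRUE_DISK_AREA = np.pi * 9.0


def _image(pixels, scale=0.01):
    return es.AssayImage(pixels=pixels, pixel_scale=scale)


class TestToGrayscale:
    def test_gray_rgb_collapses_to_value(self):
        rgb = np.full((8, 8, 3), 0.4)
        out = es.to_grayscale(_image(rgb))
        assert np.allclose(out.pixels, 0.4)

    def test_idempotent_on_grayscale(self):
        img = _image(np.random.default_rng(0).random((8, 8)))
        assert es.to_grayscale(img) is img

    def test_red_uses_itu_weights(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 0] = 1.0
        out = es.to_grayscale(_image(rgb))
        assert np.allclose(out.pixels, 0.2989, atol=1e-4)

    def test_unsupported_channels_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            es.to_grayscale(_image(np.zeros((4, 4, 2))))


class TestSobelMagnitude:
    def test_constant_image_is_zero(self):
        assert np.all(es.sobel_magnitude(np.full((16, 16), 0.3)) == 0.0)

    def test_unit_step_response(self):
        img = np.zeros((16, 32))
        img[:, 16:] = 1.0
        mag = es.sobel_magnitude(img)
        interior = mag[4:-4]
        assert interior[:, 15:17].min() == pytest.approx(1.0)
        assert np.all(interior[:, :13] == 0.0)
        assert np.all(interior[:, 19:] == 0.0)

    @pytest.mark.parametrize("slope", [0.001, 0.005, 0.02])
    def test_ramp_response_is_twice_slope(self, slope):
        x = np.arange(64) * slope
        img = np.tile(x, (32, 1))
        mag = es.sobel_magnitude(img)
        assert np.allclose(mag[8:-8, 8:-8], 2 * slope)


class TestManualDetection:
    @pytest.mark.parametrize("S", [0.01, 0.1, 0.25, 0.5])
    def test_disk_fixture_area_within_2_percent(self, disk_image, S):
        mask = es.detect_edge_manual(disk_image, S)
        assert mask.area == pytest.approx(TRUE_DISK_AREA, rel=0.02)
        assert mask.method == "manual"
        assert mask.threshold_used == S

    def test_blank_image_raises(self):
        with pytest.raises(det.DetectionError):
            es.detect_edge_manual(_image(np.full((64, 64), 0.5)), 0.1)

    def test_threshold_out_of_range_rejected(self, disk_image):
        with pytest.raises(ValueError):
            es.detect_edge_manual(disk_image, 0.0)
        with pytest.raises(ValueError):
            es.detect_edge_manual(disk_image, 1.0)

    def test_single_connected_component(self, disk_image):
        from scipy import ndimage

        mask = es.detect_edge_manual(disk_image, 0.1)
        _, n = ndimage.label(mask.mask)
        assert n == 1

    def test_translation_invariance(self, fixture_params):
        centred = es.make_disk_fixture(2.0, fixture_params)
        shifted = es.make_disk_fixture(2.0, fixture_params, center=(0.5, -0.4))
        a = es.detect_edge_manual(centred, 0.2).area
        b = es.detect_edge_manual(shifted, 0.2).area
        assert a == pytest.approx(b, rel=1e-3)

    def test_scale_consistency(self):
        # doubling resolution changes the fixture estimate by < 1%
        coarse = es.make_disk_fixture(2.0, es.RenderParams(image_size=500))
        fine = es.make_disk_fixture(
            2.0, es.RenderParams(pixel_scale=0.005, image_size=1000)
        )
        a = es.detect_edge_manual(coarse, 0.2).area
        b = es.detect_edge_manual(fine, 0.2).area
        assert abs(a - b) / a < 0.01

    def test_area_monotone_in_threshold_on_assay_images(self, study):
        # detected area is non-increasing in S up to a 2% tolerance
        manual = study["detections"].query("method == 'manual'").dropna(subset=["area"])
        for (cond, t), grp in manual.groupby(["condition", "time"]):
            means = grp.groupby("S")["area"].mean().sort_index().to_numpy()
            assert np.all(means[1:] <= means[:-1] * 1.02), (cond, t)

    def test_72h_low_threshold_sees_more_than_high(self, study):
        manual = study["detections"].query(
            "method == 'manual' and time == 72.0"
        )
        for cond, grp in manual.groupby("condition"):
            lo = grp[np.isclose(grp["S"], 0.01)]["area"].mean()
            hi = grp[np.isclose(grp["S"], 0.50)]["area"].mean()
            assert lo > hi


class TestAutoDetection:
    def test_threshold_from_gradient_statistics(self):
        # uniform gradient magnitude m => S = 4 m
        slope = 0.01
        img = _image(np.tile(np.arange(64) * slope, (64, 1)))
        S = es.auto_threshold_gradient(img)
        assert S == pytest.approx(4 * 2 * slope, rel=0.05)  # ramp magnitude 2s

    def test_constant_image_rejected(self):
        with pytest.raises(det.DetectionError, match="no gradient"):
            es.auto_threshold_gradient(_image(np.full((32, 32), 0.7)))

    def test_fixture_threshold_in_plausible_band(self, disk_image):
        S = es.auto_threshold_gradient(disk_image)
        assert 0.01 <= S <= 0.5

    def test_matches_manual_at_same_threshold(self, disk_image):
        auto = es.detect_edge_auto(disk_image)
        manual = es.detect_edge_manual(disk_image, auto.threshold_used)
        np.testing.assert_array_equal(auto.mask, manual.mask)
        assert auto.method == "auto_gradient"

    def test_fixture_area_within_2_percent(self, disk_image):
        assert es.detect_edge_auto(disk_image).area == pytest.approx(
            TRUE_DISK_AREA, rel=0.02
        )


class TestImageJStyleDetection:
    def test_fixture_area_within_3_percent(self, disk_image):
        mask = es.detect_edge_imagej_style(disk_image)
        assert mask.area == pytest.approx(TRUE_DISK_AREA, rel=0.03)
        assert mask.threshold_used == "auto"

    def test_blank_image_raises(self):
        with pytest.raises(det.DetectionError):
            es.detect_edge_imagej_style(_image(np.full((64, 64), 0.5)))

    def test_open_contour_raises(self):
        # a half-plane edge cannot be traced into a closed region
        img = np.full((200, 200), 0.9)
        img[:, 100:] = 0.1
        with pytest.raises(det.DetectionError, match="open contour"):
            es.detect_edge_imagej_style(_image(img))


class TestRegionArea:
    def test_block_and_single_pixel(self):
        block = np.zeros((200, 200), dtype=bool)
        block[50:150, 50:150] = True
        mask = det.RegionMask(block, 0.01, 0.1, "manual")
        assert es.region_area(mask) == pytest.approx(1.0)
        single = np.zeros((10, 10), dtype=bool)
        single[5, 5] = True
        assert es.region_area(det.RegionMask(single, 0.01, 0.1, "manual")) == (
            pytest.approx(1e-4)
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            es.region_area(det.RegionMask(np.zeros((5, 5), bool), 0.01, 0.1, "manual"))

    def test_disk_fixture_mask_area(self, disk_image):
        mask = es.detect_edge_manual(disk_image, 0.2)
        assert es.region_area(mask) == pytest.approx(TRUE_DISK_AREA, rel=0.02)
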