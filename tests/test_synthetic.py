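"""Synthetic-data tests: position sampling against analytic and numeric
radial distributions, rendering geometry, determinism, and error paths."""

import numpy as np
import pytest

import edgesense as es


class TestSampleCellPositions:
    def test_uniform_disk_radial_moments(self, uniform_disk_profile):
        pos = es.sample_cell_positions(uniform_disk_profile, 200_000, seed=11)
        # uniform density on a disk of radius a: E[r] = 2a/3, P(r <= a/2) = 1/4
        assert pos.radii.mean() == pytest.approx(2.0, rel=5e-3)
        assert np.mean(pos.radii <= 1.5) == pytest.approx(0.25, abs=5e-3)
        # inverse-CDF sampling can smear one grid cell past the support edge
        assert pos.radii.max() <= 3.0 + 0.01

    def test_pde_profile_radial_cdf(self, model_profile):
        # empirical radial CDF within Kolmogorov distance 0.02 of the
        # numerically integrated CDF of the same profile
        n = 100_000
        pos = es.sample_cell_positions(model_profile, n, seed=3, time=24.0)
        r_grid = model_profile.r
        w = r_grid * model_profile.u_at(24.0)
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(r_grid))])
        cdf /= cdf[-1]
        sorted_r = np.sort(pos.radii)
        target = np.interp(sorted_r, r_grid, cdf)
        empirical = np.arange(1, n + 1) / n
        ks = np.max(np.abs(empirical - target))
        assert ks < 0.02

    def test_zero_cells_and_zero_profile(self, uniform_disk_profile):
        assert es.sample_cell_positions(uniform_disk_profile, 0, seed=1).count == 0
        zero = es.DensityProfile(
            r=uniform_disk_profile.r,
            u=np.zeros_like(uniform_disk_profile.r)[None, :],
            times=[0.0],
        )
        with pytest.raises(ValueError, match="all-zero"):
            es.sample_cell_positions(zero, 10, seed=1)

    def test_deterministic_under_seed(self, uniform_disk_profile):
        a = es.sample_cell_positions(uniform_disk_profile, 1000, seed=5)
        b = es.sample_cell_positions(uniform_disk_profile, 1000, seed=5)
        c = es.sample_cell_positions(uniform_disk_profile, 1000, seed=6)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        assert not np.array_equal(a.coordinates, c.coordinates)


class TestRenderAssayImage:
    def test_zero_cells_is_background(self):
        params = es.RenderParams(image_size=128, noise_sd=0.002, seed=9)
        img = es.render_assay_image(es.CellPositions(np.empty((0, 2))), params)
        assert img.pixels.mean() == pytest.approx(params.background_level, abs=1e-3)
        assert np.abs(img.pixels - params.background_level).max() < 0.02

    def test_single_cell_disk_geometry(self):
        params = es.RenderParams(image_size=64, noise_sd=0.0, blur_sigma=0.0)
        img = es.render_assay_image(es.CellPositions(np.array([[0.0, 0.0]])), params)
        stained = img.pixels < params.background_level
        expected_px = np.pi * params.cell_radius_px**2
        assert abs(stained.sum() - expected_px) <= 1.5  # rasterisation
        from scipy import ndimage

        _, n = ndimage.label(stained)
        assert n == 1

    def test_dense_seeding_darkens_centre_only(self, model_profile):
        params = es.RenderParams(image_size=1100)
        pos = es.sample_cell_positions(model_profile, 30000, seed=2, time=0.0)
        img = es.render_assay_image(pos, params, seed=2)
        c = params.image_size // 2
        centre = img.pixels[c - 50 : c + 50, c - 50 : c + 50]
        corner = img.pixels[:100, :100]
        assert centre.mean() < params.background_level - 0.2
        assert corner.mean() == pytest.approx(params.background_level, abs=0.01)

    def test_stained_pixel_count_scales_with_cell_count(self):
        # non-overlapping regime: sparse cells on a grid
        params = es.RenderParams(image_size=512, noise_sd=0.0, blur_sigma=0.0)
        def grid_positions(n):
            side = int(np.ceil(np.sqrt(n)))
            xs = (np.arange(side) - side / 2) * 0.2
            xx, yy = np.meshgrid(xs, xs)
            return es.CellPositions(np.column_stack([xx.ravel(), yy.ravel()])[:n])

        count = {}
        for n in (64, 128):
            img = es.render_assay_image(grid_positions(n), params)
            count[n] = (img.pixels < params.background_level).sum()
        assert count[128] / count[64] == pytest.approx(2.0, rel=0.05)

    def test_deterministic_under_seed(self, uniform_disk_profile):
        params = es.RenderParams(image_size=700)
        pos = es.sample_cell_positions(uniform_disk_profile, 500, seed=4)
        a = es.render_assay_image(pos, params, seed=8)
        b = es.render_assay_image(pos, params, seed=8)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_subpixel_cell_rejected(self):
        params = es.RenderParams(pixel_scale=0.05, image_size=64)  # 25 um = 0.5 px
        with pytest.raises(ValueError, match="finer pixel_scale"):
            es.render_assay_image(es.CellPositions(np.empty((0, 2))), params)

    def test_out_of_field_position_rejected(self):
        params = es.RenderParams(image_size=64)  # 0.64 mm field
        with pytest.raises(ValueError, match="field of view"):
            es.render_assay_image(es.CellPositions(np.array([[5.0, 0.0]])), params)

    def test_invert_flips_polarity(self):
        params = es.RenderParams(
            image_size=64, noise_sd=0.0, blur_sigma=0.0, invert=True,
            background_level=0.1, stain_intensity=0.8,
        )
        img = es.render_assay_image(es.CellPositions(np.array([[0.0, 0.0]])), params)
        assert img.pixels.max() == pytest.approx(0.9)


class TestDiskFixture:
    def test_true_area_is_exact(self, fixture_params):
        img = es.make_disk_fixture(3.025, fixture_params)
        # pixel-count area approximates pi r^2 = 28.75 closely
        stained = img.pixels < fixture_params.background_level
        measured = stained.sum() * fixture_params.pixel_scale**2
        assert measured == pytest.approx(np.pi * 3.025**2, rel=5e-3)
        assert np.pi * 3.025**2 == pytest.approx(28.75, abs=0.01)

    def test_nonpositive_radius_rejected(self, fixture_params):
        with pytest.raises(ValueError, match="radius"):
            es.make_disk_fixture(0.0, fixture_params)

    def test_must_fit_field(self, fixture_params):
        with pytest.raises(ValueError, match="fit"):
            es.make_disk_fixture(4.0, fixture_params)


class TestRenderParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(pixel_scale=0.0),
            dict(cell_diameter=-1.0),
            dict(noise_sd=-0.1),
            dict(stain_intensity=1.5),
            dict(background_level=-0.2),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            es.RenderParams(**kwargs)
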