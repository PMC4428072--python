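import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from pefskin.histoquant import (
    SectionImage,
    FiberMaps,
    collagen_mask,
    local_density,
    orientation_map,
    directional_variance,
    register_sections,
    herovici_ratio,
    blue_red_ratio_map,
    subregion_stats,
    analyze_trichrome,
)
from pefskin.synthetic import FiberImageTruth, generate_fiber_image


def solid_image(rgb_tuple, shape=(64, 64), px=1.0, stain="trichrome"):
    rgb = np.zeros(shape + (3,), dtype=np.uint8)
    rgb[:] = rgb_tuple
    return SectionImage(rgb, px, stain)


class TestCollagenMask:
    def test_ratio_decision_boundary(self):
        img = solid_image((10, 0, 30))
        assert collagen_mask(img).all()  # 30/11 = 2.7 > 2
        img = solid_image((100, 0, 150))
        assert not collagen_mask(img).any()  # ratio ~1.5

    def test_all_blue_full_mask(self):
        img = solid_image((0, 0, 255))
        assert collagen_mask(img).mean() == 1.0

    def test_zero_red_guarded(self):
        # eps = 1 keeps zero-red pixels finite: ratio 1/(0+1) = 1 < 2
        assert not collagen_mask(solid_image((0, 0, 1))).any()
        # bright blue with zero red still clears the threshold
        assert collagen_mask(solid_image((0, 0, 3))).all()

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError):
            SectionImage(np.zeros((10, 10)), 1.0)


class TestLocalDensity:
    def test_uniform_masks(self):
        ones = np.ones((64, 64), dtype=bool)
        assert np.allclose(local_density(ones, 10), 1.0)
        assert np.allclose(local_density(~ones, 10), 0.0)

    def test_half_plane_boundary_value(self):
        """On the edge of a half-plane mask the disc is half full."""
        mask = np.zeros((201, 201), dtype=bool)
        mask[:, :101] = True
        d = local_density(mask, radius_px=50)
        assert d[100, 100] == pytest.approx(0.5, abs=1.0 / 50)

    def test_border_unbiased_by_partial_disc(self):
        ones = np.ones((80, 80), dtype=bool)
        d = local_density(ones, radius_px=25)
        assert d[0, 0] == pytest.approx(1.0)  # partial disc, still all-positive

    def test_radius_validation(self):
        with pytest.raises(ValueError):
            local_density(np.ones((10, 10), dtype=bool), 0)
        with pytest.raises(ValueError):
            local_density(np.ones((10, 10), dtype=bool), 200)

    def test_known_fill_fractions_recovered(self):
        """Density on synthetic textures tracks the true fill fraction."""
        for p in (0.1, 0.3, 0.6):
            truth = FiberImageTruth(fill_fraction=p, kappa=0.0, seed=11)
            img, mask, _ = generate_fiber_image(truth, size=(256, 256))
            d = local_density(mask, radius_px=50)
            interior = d[64:192, 64:192]
            assert abs(interior.mean() - p) < 0.03


class TestOrientation:
    @staticmethod
    def stripes(axis):
        rgb = np.zeros((96, 96, 3), dtype=np.uint8)
        sl = (np.s_[::6], np.s_[:]) if axis == 0 else (np.s_[:], np.s_[::6])
        rgb[..., 2][sl] = 255
        return SectionImage(rgb, 1.0)

    def test_horizontal_stripes_zero_angle(self):
        img = self.stripes(axis=0)
        theta = orientation_map(img, np.ones((96, 96), dtype=bool))
        vals = theta[np.isfinite(theta)]
        # axial distance to 0 (mod pi)
        d = np.minimum(vals, np.pi - vals)
        assert np.median(d) < np.radians(2)

    def test_rotated_stripes_quarter_turn(self):
        img = self.stripes(axis=1)
        theta = orientation_map(img, np.ones((96, 96), dtype=bool))
        vals = theta[np.isfinite(theta)]
        assert np.median(np.abs(vals - np.pi / 2)) < np.radians(2)

    def test_generator_angle_recovered(self):
        """Synthetic fibers at 30 deg: median orientation within 2 deg."""
        truth = FiberImageTruth(
            mean_angle_rad=np.pi / 6, kappa=1e6, fill_fraction=0.25, seed=3
        )
        img, mask, _ = generate_fiber_image(truth)
        theta = orientation_map(img, mask)
        med = np.median(theta[np.isfinite(theta)])
        assert abs(med - np.pi / 6) < np.radians(2)

    def test_empty_mask_rejected(self):
        img = self.stripes(axis=0)
        with pytest.raises(ValueError):
            orientation_map(img, np.zeros((96, 96), dtype=bool))


class TestDirectionalVariance:
    def test_parallel_fibers_near_zero(self):
        ang = np.full((64, 64), 0.7)
        dv = directional_variance(ang, np.ones((64, 64), bool), radius_px=20)
        assert np.nanmax(dv) < 1e-9

    def test_orthogonal_families_cancel(self):
        """Equal orthogonal families: doubled angles are antipodal -> 1."""
        ang = np.zeros((80, 80))
        ang[:, 40:] = np.pi / 2
        dv = directional_variance(ang, np.ones((80, 80), bool), radius_px=60)
        assert dv[40, 40] == pytest.approx(1.0, abs=0.05)

    def test_uniform_angles_approach_one(self, rng):
        ang = rng.uniform(0, np.pi, (128, 128))
        dv = directional_variance(ang, np.ones((128, 128), bool), radius_px=50)
        assert np.nanmedian(dv) > 0.95

    def test_monotone_in_axial_concentration(self):
        """Measured variance decreases as kappa grows."""
        medians = []
        for kappa in (0.5, 2.0, 8.0):
            truth = FiberImageTruth(kappa=kappa, fill_fraction=0.3, seed=5)
            img, mask, _ = generate_fiber_image(truth)
            maps = analyze_trichrome(img, radius_px=30)
            medians.append(float(np.nanmedian(maps.dir_variance)))
        assert medians[0] > medians[1] > medians[2]

    def test_empty_disc_undefined(self):
        ang = np.full((64, 64), np.nan)
        dv = directional_variance(ang, np.zeros((64, 64), bool), radius_px=10)
        assert np.all(np.isnan(dv))


class TestRegistration:
    def test_identity(self, rng):
        base = rng.uniform(0, 255, (96, 96, 3)).astype(np.uint8)
        img = SectionImage(base, 1.0)
        assert register_sections(img, img) == (0.0, 0.0)

    def test_constructed_shift_recovered_exactly(self, rng):
        base = rng.uniform(0, 255, (128, 128, 3)).astype(np.uint8)
        a = SectionImage(base, 1.0)
        b = SectionImage(np.roll(base, (-5, 17), axis=(0, 1)), 1.0)
        dx, dy = register_sections(a, b)
        # applying (dx, dy) to b restores a
        restored = np.roll(b.rgb, (int(dy), int(dx)), axis=(0, 1))
        assert np.array_equal(restored, a.rgb)
        assert (dx, dy) == (-17.0, 5.0)

    def test_invariant_to_intensity_scaling(self, rng):
        base = rng.uniform(0, 200, (128, 128, 3))
        a = SectionImage(base.astype(np.uint8), 1.0)
        b_arr = np.roll(base, (3, -7), axis=(0, 1)) * 0.5
        b = SectionImage(b_arr.astype(np.uint8), 1.0)
        dx, dy = register_sections(a, b)
        assert (dx, dy) == (7.0, -3.0)

    def test_flat_image_rejected(self):
        flat = solid_image((50, 50, 50))
        with pytest.raises(ValueError, match="flat"):
            register_sections(flat, flat)

    def test_pixel_size_must_match(self, rng):
        base = rng.uniform(0, 255, (64, 64, 3)).astype(np.uint8)
        with pytest.raises(ValueError, match="pixel size"):
            register_sections(SectionImage(base, 1.0), SectionImage(base, 2.0))


class TestHeroviciRatio:
    def test_uniform_populations(self):
        mask = np.ones((32, 32), dtype=bool)
        new = solid_image((50, 0, 200), shape=(32, 32), stain="herovici")
        assert herovici_ratio(new, mask) == pytest.approx(200 / 51, rel=1e-9)
        old = solid_image((200, 0, 50), shape=(32, 32), stain="herovici")
        assert herovici_ratio(old, mask) == pytest.approx(50 / 201, rel=1e-9)

    def test_mixed_population_mean(self):
        """50/50 mix of ratio-4 and ratio-0.25 pixels -> mean 2.125."""
        rgb = np.zeros((32, 32, 3), dtype=float)
        rgb[:16] = (50, 0, 200)
        rgb[16:] = (200, 0, 50)
        img = SectionImage(rgb, 1.0, "herovici")
        got = herovici_ratio(img, np.ones((32, 32), bool), eps=0.0)
        assert got == pytest.approx((4.0 + 0.25) / 2)

    def test_empty_mask_rejected(self):
        img = solid_image((10, 10, 10), stain="herovici")
        with pytest.raises(ValueError):
            herovici_ratio(img, np.zeros((64, 64), bool))


class TestSubregionStats:
    @staticmethod
    def uniform_maps(density=0.4, dvar=0.2, shape=(200, 200), px=5.0):
        return FiberMaps(
            mask=np.ones(shape, dtype=bool),
            density=np.full(shape, density),
            orientation=np.zeros(shape),
            dir_variance=np.full(shape, dvar),
            px_size_um=px,
        )

    def test_uniform_maps_recovered(self):
        maps = self.uniform_maps()
        stats = subregion_stats(maps)  # default 300 x 700 um window
        assert stats.mean_density == pytest.approx(0.4)
        assert stats.mean_dir_variance == pytest.approx(0.2)

    def test_whole_image_region_equals_global_mean(self, rng):
        maps = self.uniform_maps()
        maps.density = rng.uniform(0, 1, maps.density.shape)
        stats = subregion_stats(maps, region_um=(0, 0, 1000, 1000))
        assert stats.mean_density == pytest.approx(maps.density.mean())

    def test_two_zone_density(self):
        """Window inside the dense zone reports that zone's truth."""
        truth = FiberImageTruth(fill_fraction=0.5, kappa=0.0, seed=2)
        img, mask, _ = generate_fiber_image(truth, size=(280, 280))
        mask = mask.copy()
        mask[:, 140:] = False  # sparse zone
        maps = FiberMaps(
            mask=mask,
            density=local_density(mask, 30),
            orientation=np.zeros_like(mask, dtype=float),
            dir_variance=np.zeros_like(mask, dtype=float),
            px_size_um=1.0,
        )
        stats = subregion_stats(maps, region_um=(40, 60, 60, 160))
        assert stats.mean_density == pytest.approx(0.5, abs=0.05)

    def test_region_outside_rejected(self):
        maps = self.uniform_maps(shape=(40, 40), px=1.0)
        with pytest.raises(ValueError, match="outside"):
            subregion_stats(maps, region_um=(0, 0, 300, 700))

    def test_herovici_mean_restricted_to_mask(self):
        maps = self.uniform_maps(px=5.0)
        maps.mask[:100, :] = False
        ratio = np.where(np.arange(200)[:, None] < 100, 99.0, 4.0) * np.ones((1, 200))
        stats = subregion_stats(maps, herovici=ratio)
        assert stats.mean_blue_red_ratio == pytest.approx(4.0)


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    rgb=hnp.arrays(np.uint8, (48, 48, 3),
                   elements=st.integers(min_value=0, max_value=255)),
)
def test_map_outputs_bounded_for_arbitrary_images(rgb):
    """Density and directional variance stay in [0,1]; orientation in
    [0, pi) wherever defined — for any valid RGB input."""
    img = SectionImage(rgb, px_size_um=1.0)
    mask = collagen_mask(img)
    d = local_density(mask, radius_px=10)
    assert np.all((d >= 0) & (d <= 1))
    if mask.any():
        theta = orientation_map(img, mask)
        finite = theta[np.isfinite(theta)]
        assert np.all((finite >= 0) & (finite < np.pi))
        dv = directional_variance(theta, mask, radius_px=10)
        finite_dv = dv[np.isfinite(dv)]
        assert np.all((finite_dv >= -1e-12) & (finite_dv <= 1 + 1e-12))
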