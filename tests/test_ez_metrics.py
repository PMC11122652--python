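import math

import numpy as np
import pytest

from ezquant.cube_model import CubeGeometry, IntensityCube
from ezquant.errors import ValidationError
from ezquant.ez_metrics import (
    AttenuationThresholds,
    EyeMetrics,
    RegionSpec,
    ThicknessMap,
    attenuation_pct,
    compute_eye_metrics,
    ez_intensity_index,
    ez_intensity_profile,
    foveal_point_thickness,
    mean_region_thickness,
    panmacular_volume,
    region_mask,
    thickness_map,
)

from conftest import make_surfaces


# ---------------------------------------------------------------------------
# independent naive oracles: explicit double loops over columns


def loop_region_stats(values, geometry, center_mm, radius_mm):
    """Brute-force mean/partial/total/area over columns whose center is in
    the circle (radius None selects everything)."""
    picked = []
    for b in range(geometry.n_bscans):
        for a in range(geometry.n_ascans):
            x = (a + 0.5) * geometry.dx_mm
            y = (b + 0.5) * geometry.dy_mm
            if radius_mm is None or (x - center_mm[0]) ** 2 + (y - center_mm[1]) ** 2 <= radius_mm ** 2:
                picked.append(values[b, a])
    picked = np.array(picked)
    return {
        "n": picked.size,
        "mean": picked.mean(),
        "partial": 100.0 * (picked <= 20.0).mean(),
        "total": 100.0 * (picked <= 0.0).mean(),
        "area": picked.size * geometry.column_area_mm2,
    }


def loop_volume(values, geometry):
    vol = 0.0
    for b in range(geometry.n_bscans):
        for a in range(geometry.n_ascans):
            vol += values[b, a] * 1e-3 * geometry.column_area_mm2
    return vol


def disc_thickness(geometry, radius_mm, background_um=30.0, center_mm=None):
    center = center_mm or geometry.center_mm
    x, y = geometry.column_centers_mm()
    t = np.full((geometry.n_bscans, geometry.n_ascans), float(background_um))
    t[(x - center[0]) ** 2 + (y - center[1]) ** 2 <= radius_mm ** 2] = 0.0
    return ThicknessMap(geometry=geometry, values=t)


# ---------------------------------------------------------------------------


class TestThicknessMap:
    def test_uniform_subtraction(self, small_geometry):
        s = make_surfaces(small_geometry, thickness_um=30.0)
        assert np.all(thickness_map(s).values == 30.0)

    def test_absent_ez_maps_to_zero(self, small_geometry):
        absent = np.zeros((small_geometry.n_bscans, small_geometry.n_ascans), bool)
        absent[3, 4] = True
        s = make_surfaces(small_geometry, 30.0, ez_absent_mask=absent)
        t = thickness_map(s)
        assert t.values[3, 4] == 0.0
        assert t.values[0, 0] == 30.0

    def test_never_negative_after_clamp(self, small_geometry):
        s = make_surfaces(small_geometry, thickness_um=0.0)
        s.ez[1, 1] = s.rpe[1, 1] + 1.0  # jitter below the RPE, clamped on build
        from ezquant.cube_model import SurfaceSet
        s2 = SurfaceSet(geometry=small_geometry, ilm=s.ilm, ez=s.ez,
                        rpe=s.rpe, bm=s.bm)
        assert (thickness_map(s2).values >= 0).all()


class TestRegionMask:
    def test_panmacular_selects_all_columns(self):
        g = CubeGeometry()
        mask, area = region_mask(RegionSpec.standard("panmacular"), g)
        assert mask.sum() == 65536
        assert mask.sum() * area == pytest.approx(36.0)

    def test_central_subfield_area_near_continuum(self):
        g = CubeGeometry()
        mask, area = region_mask(RegionSpec.standard("central_subfield"), g)
        assert mask.sum() * area == pytest.approx(math.pi * 0.25, rel=0.03)

    def test_masked_columns_match_loop_oracle(self, small_geometry):
        mask, _ = region_mask(RegionSpec.standard("central_macula"), small_geometry)
        stats = loop_region_stats(np.ones((32, 32)), small_geometry,
                                  small_geometry.center_mm, 1.0)
        assert mask.sum() == stats["n"]

    def test_larger_circle_is_strict_superset(self, small_geometry):
        m1, _ = region_mask(RegionSpec.standard("central_subfield"), small_geometry)
        m2, _ = region_mask(RegionSpec.standard("central_macula"), small_geometry)
        assert (m2 | m1).sum() == m2.sum() and m2.sum() > m1.sum()

    def test_circle_outside_footprint_rejected(self, small_geometry):
        region = RegionSpec(name="central_macula", center_mm=(0.2, 3.0),
                            diameter_mm=2.0)
        with pytest.raises(ValidationError):
            region_mask(region, small_geometry)


class TestRegionalStats:
    def test_mean_of_constant(self, small_geometry):
        t = ThicknessMap(geometry=small_geometry, values=np.full((32, 32), 30.0))
        for name in ("central_subfield", "central_macula", "panmacular"):
            assert mean_region_thickness(t, RegionSpec.standard(name)) == 30.0

    def test_regional_stats_match_loop_oracle(self, small_geometry, rng):
        values = rng.uniform(0, 60, (32, 32))
        values[values < 10] = 0.0
        t = ThicknessMap(geometry=small_geometry, values=values)
        for name, radius in [("central_subfield", 0.5), ("central_macula", 1.0),
                             ("panmacular", None)]:
            oracle = loop_region_stats(values, small_geometry,
                                       small_geometry.center_mm, radius)
            region = RegionSpec.standard(name)
            assert mean_region_thickness(t, region) == pytest.approx(
                oracle["mean"], abs=1e-9)
            partial, total = attenuation_pct(t, region)
            assert partial == pytest.approx(oracle["partial"], abs=1e-9)
            assert total == pytest.approx(oracle["total"], abs=1e-9)
        assert panmacular_volume(t) == pytest.approx(
            loop_volume(values, small_geometry), abs=1e-9)

    def test_foveal_point(self, small_geometry):
        values = np.full((32, 32), 30.0)
        # the cube center falls in column (16, 16) on a 32x32 grid
        values[16, 16] = 5.0
        t = ThicknessMap(geometry=small_geometry, values=values)
        assert foveal_point_thickness(t) == 5.0

    def test_foveal_point_is_small_region_limit(self, rng):
        # odd grid: the cube center coincides with a column center, so a
        # sub-pitch circle selects exactly that column
        g = CubeGeometry(n_ascans=31, n_bscans=31, n_depth=256)
        values = rng.uniform(10, 50, (31, 31))
        t = ThicknessMap(geometry=g, values=values)
        tiny = RegionSpec(name="central_subfield", diameter_mm=g.dx_mm * 0.9)
        assert mean_region_thickness(t, tiny) == foveal_point_thickness(t)


class TestAttenuation:
    def test_uniform_15um(self, small_geometry):
        t = ThicknessMap(geometry=small_geometry, values=np.full((32, 32), 15.0))
        partial, total = attenuation_pct(t, RegionSpec.standard("central_subfield"))
        assert (partial, total) == (100.0, 0.0)

    def test_all_zero_map(self, small_geometry):
        t = ThicknessMap(geometry=small_geometry, values=np.zeros((32, 32)))
        partial, total = attenuation_pct(t, RegionSpec.standard("panmacular"))
        assert (partial, total) == (100.0, 100.0)

    def test_centered_disc_on_fine_grid(self):
        # continuum: a 0.5 mm radius bare disc fills the central subfield
        # exactly and pi*0.25 / pi = 25% of the central macula
        g = CubeGeometry()  # 512x128 grid
        t = disc_thickness(g, radius_mm=0.5)
        _, total_cs = attenuation_pct(t, RegionSpec.standard("central_subfield"))
        _, total_cm = attenuation_pct(t, RegionSpec.standard("central_macula"))
        assert total_cs == pytest.approx(100.0, abs=3.0)
        assert total_cm == pytest.approx(25.0, abs=3.0)

    def test_thresholds_validated(self):
        with pytest.raises(ValidationError):
            AttenuationThresholds(partial_um=10.0, total_um=20.0)

    def test_total_le_partial_le_100_on_random_maps(self, small_geometry, rng):
        for _ in range(50):
            values = np.maximum(rng.normal(25, 20, (32, 32)), 0.0)
            t = ThicknessMap(geometry=small_geometry, values=values)
            for name in ("central_subfield", "central_macula", "panmacular"):
                partial, total = attenuation_pct(t, RegionSpec.standard(name))
                assert 0.0 <= total <= partial <= 100.0

    def test_nested_disc_monotonicity(self, small_geometry):
        radii = [0.3, 0.6, 1.0, 1.5, 2.0]
        prev = None
        for r in radii:
            t = disc_thickness(small_geometry, radius_mm=r)
            stats = []
            for name in ("central_subfield", "central_macula", "panmacular"):
                region = RegionSpec.standard(name)
                partial, total = attenuation_pct(t, region)
                stats.append((partial, total, -mean_region_thickness(t, region)))
            stats.append((0, 0, -panmacular_volume(t)))
            if prev is not None:
                # growing the bare disc never decreases attenuation and
                # never increases thickness or volume
                for (p0, t0, m0), (p1, t1, m1) in zip(prev, stats):
                    assert p1 >= p0 and t1 >= t0 and m1 >= m0
            prev = stats


class TestVolume:
    def test_uniform_30um_is_1p080(self):
        g = CubeGeometry()
        t = ThicknessMap(geometry=g, values=np.full((128, 512), 30.0))
        assert panmacular_volume(t) == pytest.approx(1.080, abs=1e-12)

    def test_zero_map(self, small_geometry):
        t = ThicknessMap(geometry=small_geometry, values=np.zeros((32, 32)))
        assert panmacular_volume(t) == 0.0

    def test_volume_equals_mean_times_area(self, small_geometry, rng):
        values = rng.uniform(0, 60, (32, 32))
        t = ThicknessMap(geometry=small_geometry, values=values)
        mean_mm = mean_region_thickness(t, RegionSpec.standard("panmacular")) * 1e-3
        assert panmacular_volume(t) == pytest.approx(mean_mm * 36.0, abs=1e-9)


class TestIntensity:
    def _cube_with_bands(self, geometry, ez_depth, rpe_depth, ez_val, rpe_val):
        values = np.zeros((geometry.n_bscans, geometry.n_ascans,
                           geometry.n_depth), np.uint8)
        ez_px = round(ez_depth / geometry.axial_um_per_px)
        rpe_px = round(rpe_depth / geometry.axial_um_per_px)
        values[:, :, ez_px] = ez_val
        values[:, :, rpe_px] = rpe_val
        return IntensityCube(geometry=geometry, values=values)

    def test_bright_band_sampled(self, small_geometry):
        s = make_surfaces(small_geometry, 30.0)
        cube = self._cube_with_bands(small_geometry, 270.0, 300.0, 200, 250)
        ez_i, rpe_i = ez_intensity_profile(cube, s)
        assert np.all(ez_i == 200) and np.all(rpe_i == 250)

    def test_absent_ez_reports_zero(self, small_geometry):
        absent = np.zeros((32, 32), bool)
        absent.ravel()[:10] = True
        s = make_surfaces(small_geometry, 30.0, ez_absent_mask=absent)
        cube = self._cube_with_bands(small_geometry, 270.0, 300.0, 200, 250)
        ez_i, _ = ez_intensity_profile(cube, s)
        assert (ez_i.ravel()[:10] == 0).all()
        assert (ez_i.ravel()[10:] == 200).all()

    def test_one_pixel_shift_invariance(self, small_geometry):
        s = make_surfaces(small_geometry, 30.0)
        cube = self._cube_with_bands(small_geometry, 270.0, 300.0, 200, 250)
        shifted = make_surfaces(small_geometry, 30.0)
        shift = small_geometry.axial_um_per_px
        shifted.ez += shift
        shifted.rpe += shift  # keep ordering; window +-2 px absorbs the shift
        shifted.bm += shift
        ez_a, rpe_a = ez_intensity_profile(cube, s)
        ez_b, rpe_b = ez_intensity_profile(cube, shifted)
        assert np.array_equal(ez_a, ez_b) and np.array_equal(rpe_a, rpe_b)

    def test_geometry_mismatch_rejected(self, small_geometry):
        s = make_surfaces(small_geometry, 30.0)
        other = CubeGeometry(n_ascans=16, n_bscans=16, n_depth=64)
        cube = IntensityCube(geometry=other,
                             values=np.zeros((16, 16, 64), np.uint8))
        with pytest.raises(ValidationError):
            ez_intensity_profile(cube, s)


class TestIntensityIndex:
    def test_ratio_one(self):
        ez = np.full((8, 8), 100.0)
        mean_ez, index = ez_intensity_index(ez, ez, np.ones((8, 8), bool))
        assert (mean_ez, index) == (100.0, 100.0)

    def test_half_ratio(self):
        ez = np.full((8, 8), 80.0)
        rpe = np.full((8, 8), 160.0)
        _, index = ez_intensity_index(ez, rpe, np.ones((8, 8), bool))
        assert index == pytest.approx(40.0)

    def test_zero_rpe_guard(self):
        ez = np.full((4, 4), 50.0)
        rpe = np.zeros((4, 4))
        _, index = ez_intensity_index(ez, rpe, np.ones((4, 4), bool))
        assert index == 0.0

    def test_gain_law(self, rng):
        # a uniform gain g scales the index by exactly g and leaves the
        # EZ/RPE ratio invariant
        ez = rng.uniform(50, 150, (16, 16))
        rpe = rng.uniform(100, 200, (16, 16))
        mask = np.ones((16, 16), bool)
        for g in (0.5, 1.3, 2.0):
            _, base = ez_intensity_index(ez, rpe, mask)
            _, scaled = ez_intensity_index(g * ez, g * rpe, mask)
            assert scaled == pytest.approx(g * base, rel=1e-12)
            assert np.allclose((g * ez) / (g * rpe), ez / rpe)

    def test_region_mean_mode(self):
        ez = np.array([[80.0, 120.0]])
        rpe = np.array([[160.0, 160.0]])
        mask = np.ones((1, 2), bool)
        _, per_ascan = ez_intensity_index(ez, rpe, mask)
        _, region_mean = ez_intensity_index(ez, rpe, mask, mode="region_mean")
        assert per_ascan == pytest.approx((80 * 0.5 + 120 * 0.75) / 2)
        assert region_mean == pytest.approx(100.0 * 100.0 / 160.0)


class TestComposition:
    def test_uniform_eye(self, small_geometry):
        s = make_surfaces(small_geometry, 30.0)
        m = compute_eye_metrics(s)
        for region, vals in m.per_region.items():
            assert vals["partial_attenuation_pct"] == 0.0
            assert vals["total_attenuation_pct"] == 0.0
            assert vals["mean_ez_rpe_um"] == pytest.approx(30.0)
            assert vals["ez_intensity"] is None
        assert m.ez_rpe_volume_mm3 == pytest.approx(1.080, abs=1e-12)
        assert m.foveal_point_um == 30.0

    def test_row_round_trip(self, small_geometry, rng):
        s = make_surfaces(small_geometry, rng.uniform(0, 50, (32, 32)))
        m = compute_eye_metrics(s)
        back = EyeMetrics.from_row(m.to_row())
        assert back.per_region == m.per_region
        assert back.ez_rpe_volume_mm3 == m.ez_rpe_volume_mm3

    def test_bscan_reversal_symmetry(self, small_geometry, rng):
        values = rng.uniform(0, 50, (32, 32))
        s = make_surfaces(small_geometry, values)
        s_rev = make_surfaces(small_geometry, values[::-1].copy())
        m, m_rev = compute_eye_metrics(s), compute_eye_metrics(s_rev)
        for region in m.per_region:
            for key in ("partial_attenuation_pct", "total_attenuation_pct",
                        "mean_ez_rpe_um"):
                assert m.per_region[region][key] == pytest.approx(
                    m_rev.per_region[region][key], abs=1e-12)
        assert m.ez_rpe_volume_mm3 == pytest.approx(m_rev.ez_rpe_volume_mm3)
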