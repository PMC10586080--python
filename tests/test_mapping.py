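"""Map assembly, stress-topography decoupling, depth windows, radial
profiles and line-scan statistics."""

import numpy as np
import pytest

from prestressmap import (AcquisitionConfig, ScalarMap,
                          build_maps, depth_windowed_maps, fit_map,
                          linescan_stats, make_linescan_series, make_phantom,
                          radial_profile, simulate_spectrum_image)


class TestBuildMaps:
    def test_phantom_recovery_and_topography_identity(self, clean16, hs_cfg):
        img, gt = clean16
        fit = fit_map(img, hs_cfg, gt.td)
        maps = build_maps(fit, img)
        assert set(maps) == {"stress", "modulus", "topography"}
        assert np.array_equal(maps["topography"].values, img.topography)
        s = maps["stress"].masked_values()
        ok = np.isfinite(s)
        assert np.allclose(s[ok], gt.sigma[ok], atol=1e-6)
        assert maps["stress"].units == "Pa" and maps["topography"].units == "m"
        assert maps["stress"].provenance["model"] == "hs"

    def test_stress_and_topography_decoupled(self, hs_cfg, rng):
        """Permuting the stress field with topography fixed changes the
        stress map but leaves the topography map bit-identical."""
        ph1 = make_phantom(nx=12, ny=12, seed=5)
        ph2 = make_phantom(nx=12, ny=12, seed=5)
        perm = rng.permutation(ph2.sigma1.size)
        ph2.sigma1 = ph2.sigma1.ravel()[perm].reshape(ph2.sigma1.shape)
        ph2.sigma2 = ph2.sigma1.copy()
        maps = []
        for ph in (ph1, ph2):
            img, gt = simulate_spectrum_image(ph, AcquisitionConfig(noise_rms=0.0))
            maps.append(build_maps(fit_map(img, hs_cfg, gt.td), img))
        assert np.array_equal(maps[0]["topography"].values,
                              maps[1]["topography"].values)
        assert not np.allclose(np.nan_to_num(maps[0]["stress"].values),
                               np.nan_to_num(maps[1]["stress"].values))


@pytest.fixture(scope="module")
def two_layer():
    ph = make_phantom(nx=12, ny=12, two_layer=True, sigma_cortex=40e3,
                      sigma_deep=30e3, cortex_thickness=150e-9, seed=0)
    img, gt = simulate_spectrum_image(
        ph, AcquisitionConfig(noise_rms=0.03e-9, force_threshold=None))
    return ph, img, gt


class TestDepthWindows:
    def test_full_window_equals_plain_fit(self, clean16, hs_cfg):
        img, gt = clean16
        plain = build_maps(fit_map(img, hs_cfg, gt.td), img)
        [windowed] = depth_windowed_maps(img, gt.td, hs_cfg, [900e-9])
        s0, s1 = plain["stress"].values, windowed["stress"].values
        assert np.allclose(np.nan_to_num(s0), np.nan_to_num(s1), rtol=1e-12)

    def test_shallow_window_reads_cortex(self, two_layer, hs_cfg):
        ph, img, gt = two_layer
        sets = depth_windowed_maps(img, gt.td, hs_cfg, [100e-9, 800e-9])
        nuc = ph.nucleus_mask
        shallow = np.nanmean(np.where(nuc, sets[0]["stress"].masked_values(),
                                      np.nan))
        assert shallow == pytest.approx(40e3, rel=0.10)
        # windows are labeled in provenance and discriminate the layers
        assert sets[0]["stress"].provenance["depth_window_m"] == 100e-9
        deep = np.nanmean(np.where(nuc, sets[1]["stress"].masked_values(), np.nan))
        assert abs(deep - shallow) > 1e3  # the two windows do not read alike

    def test_window_starving_a_pixel_masks_it(self, hs_cfg):
        ph = make_phantom(nx=8, ny=8, seed=0)
        img, gt = simulate_spectrum_image(ph, AcquisitionConfig(noise_rms=0.0))
        [maps] = depth_windowed_maps(img, gt.td, hs_cfg, [25e-9])
        # 10 nm sampling leaves only 3 samples below 25 nm -> all masked
        assert np.all(np.isnan(maps["stress"].values))

    def test_empty_window_list_rejected(self, clean16, hs_cfg):
        img, gt = clean16
        with pytest.raises(ValueError, match="empty"):
            depth_windowed_maps(img, gt.td, hs_cfg, [])
        with pytest.raises(ValueError, match="ascending"):
            depth_windowed_maps(img, gt.td, hs_cfg, [800e-9, 100e-9])


class TestRadialProfile:
    def test_recovers_analytic_radial_function(self):
        # map values = g(r) with g linear in radius; bin means must follow g
        pitch = 0.5e-6
        ny = nx = 33
        y, x = np.mgrid[0:ny, 0:nx].astype(float)
        rr = np.hypot(x - 16, y - 16) * pitch
        g = lambda r: 5e3 * (1 - r / 10e-6)
        prof = radial_profile(ScalarMap(g(rr), "Pa", pitch), (16, 16),
                              r_max=7e-6, n_bins=14)
        mid = prof.counts > 0
        assert np.allclose(prof.mean[mid], g(prof.bin_centers[mid]),
                           rtol=0.03)

    def test_constant_map_normalizes_to_ones(self):
        m = ScalarMap(np.full((9, 9), 3.0), "m", 1e-6)
        prof = radial_profile(m, (4, 4), r_max=4e-6, n_bins=4, normalize=True)
        assert np.allclose(prof.mean[prof.counts > 0], 1.0)
        assert prof.normalized

    def test_masked_region_excluded_empty_bin_nan(self):
        vals = np.ones((9, 9))
        mask = np.zeros((9, 9), dtype=bool)
        mask[3:6, 3:6] = True  # mask the center 3x3 around the profile center
        prof = radial_profile(ScalarMap(vals, "m", 1e-6, mask=mask), (4, 4),
                              r_max=4e-6, n_bins=8)
        assert prof.counts[0] == 0 and np.isnan(prof.mean[0])
        assert prof.counts[-1] > 0 and prof.mean[-1] == 1.0

    def test_center_outside_rejected(self):
        with pytest.raises(ValueError, match="center"):
            radial_profile(ScalarMap(np.ones((4, 4)), "m", 1e-6), (9, 0), 1e-6)


class TestLinescanStats:
    def test_time_constant_series_is_flat(self):
        s = make_linescan_series(n_times=20, decay_to=1.0, seed=0)
        stress_t, height_t = linescan_stats(s)
        assert np.allclose(stress_t, stress_t[0])
        assert np.allclose(height_t, height_t[0])

    def test_decay_to_half_plateau(self):
        """Stress decaying with tau = 10 min over a 1 h series plateaus at
        50% of the initial central average."""
        s = make_linescan_series(n_times=120, t_step=30.0, decay_to=0.5,
                                 tau=600.0, seed=0)
        stress_t, _ = linescan_stats(s, window_width=5e-6)
        assert stress_t[-1] / stress_t[0] == pytest.approx(0.5, abs=0.02)

    def test_height_stat_options(self):
        s = make_linescan_series(n_times=5, seed=0)
        _, hmax = linescan_stats(s, height_stat="max")
        _, hmean = linescan_stats(s, height_stat="mean")
        assert np.all(hmax >= hmean)

    def test_window_wider_than_profile_rejected(self):
        s = make_linescan_series(n_times=5, n_pix=16, pitch=0.25e-6, seed=0)
        with pytest.raises(ValueError, match="window"):
            linescan_stats(s, window_width=10e-6)
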