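"""Per-curve OLS against a normal-equations oracle, map fitting, the
train/test split, and prediction error."""

import numpy as np
import pytest

from prestressmap import (AcquisitionConfig, ForceCurve, ModelConfig,
                          PixelContext, TipDescriptors, basis_functions,
                          fit_curve_linear, fit_map, make_phantom,
                          map_objective, pack_curves, prediction_error,
                          simulate_spectrum_image, split_train_test)
from prestressmap.contact_models import PARAM_NAMES
from prestressmap.curve_processing import topography_gradients
from prestressmap.fitting import propagated_noise_std


def normal_equations_oracle(X, y):
    """Independent textbook solve: beta = (X^T X)^{-1} X^T y."""
    return np.linalg.inv(X.T @ X) @ (X.T @ y)


def make_curve(td, ctx, sigma=2e3, E=8e3, noise=0.0, seed=0, model="hs",
               r_cell=None):
    rng = np.random.default_rng(seed)
    d = np.arange(0, 801e-9, 10e-9)
    cols, ok = basis_functions(model, td, ctx, d, r_cell=r_cell)
    assert ok.all()
    params = {"hs": [sigma, E], "hertz": [E], "sneddon": [E], "cslc": [sigma]}[model]
    f = cols @ np.array(params) + rng.normal(0, noise, d.size)
    f[0] = 0.0 if noise == 0 else f[0]
    return ForceCurve(d=d, f=f, pixel=(0, 0)), np.array(params)


class TestFitCurve:
    def test_noiseless_round_trip_machine_precision(self):
        td = TipDescriptors(50e-9, 10e-9, 30e-9, 0.02)
        ctx = PixelContext(0.3, -0.5)
        c, truth = make_curve(td, ctx, sigma=2e3, E=8e3)
        fit = fit_curve_linear(c, ModelConfig("hs"), td, ctx)
        assert fit.sigma == pytest.approx(2e3, rel=1e-10)
        assert fit.E == pytest.approx(8e3, rel=1e-10)
        assert fit.residual_rms < 1e-20
        assert fit.ok and not fit.flags

    def test_all_zero_force(self):
        d = np.arange(0, 101e-9, 10e-9)
        c = ForceCurve(d=d, f=np.zeros_like(d), pixel=(0, 0))
        fit = fit_curve_linear(c, ModelConfig("hs"), TipDescriptors(50e-9),
                               PixelContext())
        assert fit.sigma == 0.0 and fit.E == 0.0 and fit.residual_rms == 0.0

    @pytest.mark.parametrize("model,r_cell", [("hs", None), ("hertz", None),
                                              ("sneddon", None), ("cslc", 8e-6)])
    def test_matches_normal_equations_oracle(self, model, r_cell, rng):
        base = 0.35 if model == "sneddon" else 50e-9
        td = TipDescriptors(base, 0, 0, 0.0)
        ctx = PixelContext(0.2, 0.1)
        sigma = 2e-4 if model == "cslc" else 2e3
        c, _ = make_curve(td, ctx, sigma=sigma, E=8e3, noise=5e-11,
                          seed=3, model=model, r_cell=r_cell)
        cfg = ModelConfig(model, r_cell=r_cell)
        fit = fit_curve_linear(c, cfg, td, ctx)
        X, _ = basis_functions(model, td, ctx, c.d, r_cell=r_cell)
        ref = normal_equations_oracle(X, c.f)
        got = np.array([fit.params[n] for n in PARAM_NAMES[model]])
        assert np.allclose(got, ref, rtol=1e-8)

    def test_singular_design_flagged_not_raised(self):
        d = np.array([0.0] + [100e-9] * 5)
        c = ForceCurve(d=d, f=np.linspace(0, 1e-10, 6), pixel=(0, 0), flag=None)
        # all nonzero depths equal -> the two HS columns are proportional
        fit = fit_curve_linear(c, ModelConfig("hs"), TipDescriptors(50e-9),
                               PixelContext())
        assert "singular" in fit.flags

    def test_geometry_violation_flagged(self):
        c, _ = make_curve(TipDescriptors(50e-9), PixelContext())
        bad_td = TipDescriptors(10e-9, 0, 0, -1.0)  # R < 0 at depth
        fit = fit_curve_linear(c, ModelConfig("hs"), bad_td, PixelContext())
        assert "geometry_violation" in fit.flags and not fit.ok

    def test_negative_modulus_soft_flagged(self):
        td = TipDescriptors(50e-9)
        ctx = PixelContext()
        c, _ = make_curve(td, ctx, sigma=5e3, E=-2e3)
        fit = fit_curve_linear(c, ModelConfig("hs"), td, ctx)
        assert "negative_E" in fit.flags
        assert fit.E == pytest.approx(-2e3, rel=1e-9)  # value kept, not clamped


class TestFitMap:
    def test_vectorized_path_agrees_with_per_curve_path(self, noisy16, hs_cfg):
        img, gt = noisy16
        ctx = topography_gradients(img)
        fit = fit_map(img, hs_cfg, gt.td)
        for (iy, ix) in [(0, 0), (7, 8), (15, 15), (3, 12)]:
            one = fit_curve_linear(img.curves[(iy, ix)], hs_cfg, gt.td,
                                   PixelContext(ctx.gx[iy, ix], ctx.gy[iy, ix]))
            assert fit.params["sigma"][iy, ix] == pytest.approx(one.sigma, rel=1e-9)
            assert fit.params["E"][iy, ix] == pytest.approx(one.E, rel=1e-9)
            assert fit.residual_rms[iy, ix] == pytest.approx(one.residual_rms,
                                                             rel=1e-6)

    def test_true_descriptors_give_near_zero_objective(self, clean16, hs_cfg):
        img, gt = clean16
        fit = fit_map(img, hs_cfg, gt.td)
        assert fit.objective < 1e-30  # noiseless: residuals at machine precision
        assert fit.objective == pytest.approx(fit.recompute_objective())

    def test_perturbing_descriptors_increases_objective(self, clean16, hs_cfg):
        img, gt = clean16
        packed = pack_curves(img)
        ctx = topography_gradients(img)
        base = map_objective(packed, ctx, hs_cfg, gt.td, "sum")
        for factor in (0.7, 1.3):
            td = TipDescriptors(gt.td.r * factor, gt.td.a, gt.td.b, gt.td.c)
            assert map_objective(packed, ctx, hs_cfg, td, "sum") > base

    def test_objective_invariant_to_pixel_ordering(self, rng):
        # flat topography so gradients do not move with the permutation
        ph = make_phantom(nx=8, ny=8, dome_height=1e-12, seed=2)
        img, gt = simulate_spectrum_image(ph, AcquisitionConfig(noise_rms=3e-11))
        cfg = ModelConfig("hs")
        base = fit_map(img, cfg, gt.td).objective
        perm = rng.permutation(64)
        keys = sorted(img.curves)
        img.curves = {keys[i]: img.curves[keys[perm[i]]] for i in range(64)}
        assert fit_map(img, cfg, gt.td).objective == pytest.approx(base, rel=1e-9)

    def test_missing_pixels_masked_not_dropped(self, hs_cfg):
        ph = make_phantom(nx=8, ny=8, seed=1)
        img, gt = simulate_spectrum_image(ph, AcquisitionConfig(noise_rms=0.0))
        del img.curves[(2, 3)]
        fit = fit_map(img, hs_cfg, gt.td)
        assert fit.flags["missing"][2, 3]
        assert np.isnan(fit.params["sigma"][2, 3])
        assert np.isfinite(fit.objective)


class TestSplit:
    def test_fraction_and_determinism(self, noisy16):
        img, _ = noisy16
        packed = pack_curves(img)
        m1 = split_train_test(packed, 0.125, seed=5)
        m2 = split_train_test(packed, 0.125, seed=5)
        assert np.array_equal(m1, m2)
        frac = m1.sum() / packed.valid.sum()
        assert 0.115 <= frac <= 0.135
        # test samples only where data exists, and they span the depth range
        assert not np.any(m1 & ~packed.valid)
        d_test = packed.d[m1]
        assert d_test.min() < 100e-9 and d_test.max() > 500e-9

    def test_different_seed_different_split(self, noisy16):
        img, _ = noisy16
        packed = pack_curves(img)
        assert not np.array_equal(split_train_test(packed, seed=0),
                                  split_train_test(packed, seed=1))


class TestPredictionError:
    def test_true_model_hits_noise_floor(self, phantom16, hs_cfg):
        noise = 3e-11
        img, gt = simulate_spectrum_image(
            phantom16, AcquisitionConfig(noise_rms=noise, seed=2))
        packed = pack_curves(img)
        ctx = topography_gradients(img)
        test = split_train_test(packed, seed=0)
        pe = prediction_error(packed, ctx, hs_cfg, gt.td, test)
        assert pe.rms == pytest.approx(noise, rel=0.15)
        # noiseless version is essentially exact
        img0, gt0 = simulate_spectrum_image(phantom16,
                                            AcquisitionConfig(noise_rms=0.0))
        packed0 = pack_curves(img0)
        pe0 = prediction_error(packed0, ctx, hs_cfg, gt0.td,
                               split_train_test(packed0, seed=0))
        assert pe0.rms < 1e-18

    def test_wrong_model_pays_a_penalty(self, noisy16):
        img, gt = noisy16
        packed = pack_curves(img)
        ctx = topography_gradients(img)
        test = split_train_test(packed, seed=0)
        pe_hs = prediction_error(packed, ctx, ModelConfig("hs"), gt.td, test)
        pe_hz = prediction_error(packed, ctx, ModelConfig("hertz"), gt.td, test)
        assert pe_hz.rms > 2 * pe_hs.rms


def test_propagated_noise_std_matches_monte_carlo(phantom16, hs_cfg):
    """Analytic OLS noise propagation vs empirical scatter over repeated
    noise draws on the same pixel."""
    noise = 3e-11
    img, gt = simulate_spectrum_image(phantom16, AcquisitionConfig(noise_rms=0.0))
    packed = pack_curves(img)
    ctx = topography_gradients(img)
    bound = propagated_noise_std(packed, ctx, hs_cfg, gt.td, noise)["sigma"]
    iy, ix = 8, 8
    c = img.curves[(iy, ix)]
    cols, _ = basis_functions("hs", gt.td,
                              PixelContext(ctx.gx[iy, ix], ctx.gy[iy, ix]), c.d)
    rng = np.random.default_rng(0)
    draws = []
    for _ in range(400):
        y = c.f + rng.normal(0, noise, c.f.size)
        draws.append(np.linalg.lstsq(cols, y, rcond=None)[0][0])
    assert np.std(draws) == pytest.approx(bound[iy, ix], rel=0.15)
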