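"""Force-expression correctness: frozen single-point oracles, scaling laws,
model nesting, the angle-factor identity, and the shallow negative-force
crossover for compressive prestress."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from prestressmap import (GeometryError, ModelConfig, PixelContext,
                          TipDescriptors, basis_functions, cslc_force,
                          hertz_force, hs_force, model_force,
                          negative_force_crossover, sneddon_force,
                          tip_radius_at)
from prestressmap.contact_models import default_angle_factor

GAMMA = 0.5

# frozen values from a straight-transcription evaluation script written
# independently of the package (R=1 um, d=100 nm, gamma=0.5)
ORACLE_POINT = dict(R=1e-6, d=1e-7)
ORACLE_VALUES = {
    "hs": 8.364033834799e-10,       # sigma=1 kPa, E=10 kPa
    "hertz": 5.621826951410e-10,    # E=10 kPa
    "sneddon": 3.089475302495e-11,  # theta=20 deg, E=10 kPa
    "cslc": 2.764601535159e-10,     # T=2e-4 N/m, r_cell=10 um
}


class TestTipRadius:
    def test_constant_when_uncoupled(self):
        td = TipDescriptors(r=100e-9)
        for d in (0.0, 50e-9, 800e-9):
            assert tip_radius_at(td, PixelContext(1.0, -2.0), d) == 100e-9

    def test_linear_form(self):
        td = TipDescriptors(r=100e-9, a=50e-9)
        assert tip_radius_at(td, PixelContext(gx=1.0), 0.0) == pytest.approx(150e-9)

    def test_nonpositive_not_clamped(self):
        td = TipDescriptors(r=10e-9, c=-1.0)
        assert tip_radius_at(td, PixelContext(), 20e-9) < 0
        _, ok = basis_functions("hs", td, PixelContext(), np.array([0.0, 20e-9]))
        assert ok[0] and not ok[1]


class TestForceExpressions:
    def test_frozen_oracle_points(self):
        R, d = ORACLE_POINT["R"], ORACLE_POINT["d"]
        assert hs_force(1e3, 1e4, R, d, GAMMA) == pytest.approx(
            ORACLE_VALUES["hs"], rel=1e-10)
        assert hertz_force(1e4, R, d, GAMMA) == pytest.approx(
            ORACLE_VALUES["hertz"], rel=1e-10)
        assert sneddon_force(1e4, np.radians(20.0), d, GAMMA) == pytest.approx(
            ORACLE_VALUES["sneddon"], rel=1e-10)
        assert cslc_force(2e-4, 1e-5, R, d) == pytest.approx(
            ORACLE_VALUES["cslc"], rel=1e-10)

    def test_zero_depth_zero_force(self):
        assert hs_force(1e3, 1e4, 1e-7, 0.0) == 0.0
        assert hertz_force(1e4, 1e-7, 0.0) == 0.0
        assert sneddon_force(1e4, 0.3, 0.0) == 0.0
        assert cslc_force(1e-4, 1e-5, 1e-7, 0.0) == 0.0

    def test_prestress_only_term(self):
        # E = 0 leaves the stress term: positive and increasing in d
        d = np.linspace(10e-9, 500e-9, 20)
        f = hs_force(1e3, 0.0, 1e-7, d)
        assert np.all(f > 0) and np.all(np.diff(f) > 0)
        assert f[-1] == pytest.approx(
            4 * np.pi * 1e-7 * d[-1] * 1e3 * np.sqrt(d[-1] / (d[-1] + 2e-7)))

    def test_hs_nests_hertz(self, rng):
        for _ in range(20):
            R = rng.uniform(2e-8, 5e-7)
            d = rng.uniform(0, 8e-7)
            E = rng.uniform(1e3, 1e5)
            assert hs_force(0.0, E, R, d, GAMMA) == hertz_force(E, R, d, GAMMA)

    @given(st.floats(1e-9, 1e-6), st.floats(1e-9, 1e-6))
    @settings(derandomize=True, max_examples=50)
    def test_hertz_power_law(self, R, d):
        f1, f2 = hertz_force(1e4, R, d), hertz_force(1e4, R, 2 * d)
        assert f2 == pytest.approx(2**1.5 * f1, rel=1e-12)

    def test_sneddon_quadratic_and_domain(self):
        assert sneddon_force(1e4, 0.3, 2e-7) == pytest.approx(
            4 * sneddon_force(1e4, 0.3, 1e-7), rel=1e-12)
        with pytest.raises(GeometryError):
            sneddon_force(1e4, np.pi / 2, 1e-7)

    def test_cslc_linear_and_large_R_limit(self):
        assert cslc_force(1e-4, 1e-5, 1e-7, 4e-7) == pytest.approx(
            2 * cslc_force(1e-4, 1e-5, 1e-7, 2e-7), rel=1e-12)
        # R >> r_cell: F -> 4 pi T d R / r_cell
        R = 1.0
        assert cslc_force(1e-4, 1e-5, R, 1e-7) == pytest.approx(
            4 * np.pi * 1e-4 * 1e-7 * R / 1e-5, rel=1e-4)

    def test_negative_depth_rejected(self):
        for fn in (lambda d: hs_force(1e3, 1e4, 1e-7, d),
                   lambda d: hertz_force(1e4, 1e-7, d),
                   lambda d: sneddon_force(1e4, 0.3, d),
                   lambda d: cslc_force(1e-4, 1e-5, 1e-7, d)):
            with pytest.raises(ValueError):
                fn(-1e-9)


@given(st.floats(1e-6, 1e6))
@settings(derandomize=True, max_examples=200)
def test_angle_factor_identity(x):
    """cos(tan^-1 x) == 1/sqrt(1+x^2); the implementation uses the algebraic
    form with x = sqrt(2R/d), i.e. sqrt(d/(d+2R))."""
    R = 1e-7
    d = 2 * R / x**2
    got = default_angle_factor(np.array([d]), np.array([R]))[0]
    assert got == pytest.approx(np.cos(np.arctan(x)), abs=1e-14)


@pytest.mark.parametrize("model,params,kwargs", [
    ("hs", (2e3, 8e3), {}),
    ("hertz", (8e3,), {}),
    ("sneddon", (8e3,), {}),
    ("cslc", (2e-4,), {"r_cell": 8e-6}),
])
def test_basis_reproduces_force(model, params, kwargs, rng):
    """dot(design columns, true parameters) equals the direct force
    expression with the same depth-dependent geometry, at random points."""
    base = 0.35 if model == "sneddon" else 60e-9
    c = 1e5 if model == "sneddon" else 0.03
    td = TipDescriptors(base, 0.0, 0.0, c)
    ctx = PixelContext(gx=0.1, gy=-0.2)
    cfg = ModelConfig(model, r_cell=kwargs.get("r_cell"))
    d = rng.uniform(0, 800e-9, 20)
    cols, ok = basis_functions(model, td, ctx, d, r_cell=kwargs.get("r_cell"))
    assert ok.all()
    direct = model_force(params, cfg, td, ctx, d)
    assert np.allclose(cols @ np.array(params), direct, rtol=1e-12)
    # columns vanish at zero depth
    cols0, _ = basis_functions(model, td, ctx, np.array([0.0]),
                               r_cell=kwargs.get("r_cell"))
    assert np.all(cols0 == 0.0)


class TestNegativeForceCrossover:
    def test_matches_independent_root_finder(self):
        # negative shallow force needs |sigma| above ~0.2 E (both terms scale
        # as d^1.5 at shallow depth); sigma/E = 0.5 puts d* well inside range
        td = TipDescriptors(80e-9, 0, 0, 0.02)
        ctx = PixelContext(0.1, 0.3)
        dstar = negative_force_crossover(-5e3, 1e4, td, ctx, d_max=3e-6)

        def F(d):
            R = float(tip_radius_at(td, ctx, d))
            return float(hs_force(-5e3, 1e4, R, d))

        ref = brentq(F, 3e-15, 3e-6, xtol=1e-18, rtol=1e-13)
        assert dstar == pytest.approx(ref, rel=1e-3)
        # force is negative below d*, positive above
        assert F(0.5 * dstar) < 0 < F(2 * dstar)

    def test_tensile_has_no_crossing(self):
        with pytest.raises(ValueError, match="no zero crossing"):
            negative_force_crossover(+2e3, 2e4, TipDescriptors(80e-9),
                                     PixelContext(), d_max=1e-6)
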