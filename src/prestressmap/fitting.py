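"""Per-curve linear regression and map-wide error aggregation.

Once the tip geometry ``R(d)`` is fixed, every contact model here is linear
in its material parameters (prestress sigma and modulus E for HS; E for
Hertz/Sneddon; cortical tension T for CSLC), so each pixel's curve is fitted
by ordinary least squares on the model's design columns.  Two aggregate
quantities drive the informatics loop:

* **fitting error** — the in-sample residual rms per indentation (pixel);
  its *variance across the map* is the default objective the MCMC tip-shape
  search minimizes (a correctly described tip leaves no location-dependent
  misfit).  A "sum" objective (accumulated residual rms) is also available.
* **prediction error** — the out-of-sample rms on a held-out 1/8 of the
  samples, fitted on the remaining 7/8; this is what ranks the four models.

The map path is fully vectorized: design sums and the 1x1 / 2x2 normal
equations are evaluated across all pixels at once, with column equilibration
for numerical head-room.  ``fit_curve_linear`` is the reference single-curve
path (QR-based ``lstsq``) and agrees with the vectorized solver to machine
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .contact_models import (PARAM_NAMES, ModelConfig, PixelContext,
                             TipDescriptors, basis_functions)
from .curve_processing import topography_gradients, truncate_to_depth
from .io_formats import ForceCurve, SpectrumImage

__all__ = [
    "PixelFit",
    "MapFitResult",
    "PredictionError",
    "PackedCurves",
    "pack_curves",
    "fit_curve_linear",
    "fit_map",
    "map_objective",
    "split_train_test",
    "prediction_error",
]

#: fraction of invalid-geometry samples above which a descriptor proposal is
#: rejected outright (infinite objective) instead of masking pixels
GEOMETRY_VIOLATION_BUDGET = 0.01

_HARD_FLAGS = ("missing", "too_shallow", "geometry_violation", "singular")


@dataclass
class PixelFit:
    """OLS result for one pixel's curve.

    ``params`` maps parameter names (see ``contact_models.PARAM_NAMES``) to
    fitted values: sigma in Pa (tensile > 0), E in Pa, T in N/m.  Flags:
    ``geometry_violation`` (nonphysical R/theta at a used sample),
    ``too_shallow`` (< 4 usable samples), ``negative_E`` (unconstrained OLS
    gave a negative modulus/tension — flagged, never clamped), ``singular``
    (rank-deficient design).  Any flag masks the pixel in map aggregation.
    """

    model: str
    params: Dict[str, float] = field(default_factory=dict)
    residual_rms: float = np.nan
    n_samples: int = 0
    flags: frozenset = frozenset()

    @property
    def sigma(self) -> Optional[float]:
        return self.params.get("sigma")

    @property
    def E(self) -> Optional[float]:
        return self.params.get("E")

    @property
    def T(self) -> Optional[float]:
        return self.params.get("T")

    @property
    def ok(self) -> bool:
        return not (set(self.flags) & set(_HARD_FLAGS))


@dataclass
class MapFitResult:
    """Per-pixel fits over a whole spectrum image, plus the map objective.

    ``params[name]`` are (ny, nx) arrays (NaN where masked); ``mask`` is True
    where a pixel is excluded from the objective.  ``objective`` is the
    variance (or sum) of per-pixel residual rms over unmasked pixels and is
    recomputable from the stored grids via :meth:`recompute_objective`.
    """

    model: str
    td: TipDescriptors
    params: Dict[str, np.ndarray]
    residual_rms: np.ndarray
    n_used: np.ndarray
    flags: Dict[str, np.ndarray]
    mask: np.ndarray
    objective: float
    objective_kind: str = "variance"
    depth_window: Optional[float] = None

    def recompute_objective(self) -> float:
        r = self.residual_rms[np.isfinite(self.residual_rms)]
        if r.size == 0:
            return np.inf
        return float(np.var(r)) if self.objective_kind == "variance" else float(np.sum(r))

    @property
    def frac_flagged(self) -> float:
        return float(np.mean(self.mask))


@dataclass
class PredictionError:
    """Out-of-sample force rms; ``per_pixel`` keeps the per-pixel breakdown."""

    rms: float
    per_pixel: np.ndarray
    n_test: int


@dataclass
class PackedCurves:
    """Rectangular (ny, nx, nmax) view of a curve grid for vectorized math.

    ``valid`` marks real samples (padding is False); ``pixel_ok`` marks
    pixels carrying a usable (unflagged) curve.
    """

    d: np.ndarray
    f: np.ndarray
    valid: np.ndarray
    pixel_ok: np.ndarray

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.d.shape


def pack_curves(img: SpectrumImage, depth_window: Optional[float] = None) -> PackedCurves:
    """Pack the per-pixel curves into padded arrays, optionally depth-windowed."""
    ny, nx = img.ny, img.nx
    curves = {}
    nmax = 4
    for key, c in img.curves.items():
        if c.flag in ("missing", "too_shallow"):
            continue
        if depth_window is not None:
            c = truncate_to_depth(c, depth_window)
            if c.flag in ("missing", "too_shallow"):
                continue
        curves[key] = c
        nmax = max(nmax, c.n_samples)
    d = np.zeros((ny, nx, nmax))
    f = np.zeros((ny, nx, nmax))
    valid = np.zeros((ny, nx, nmax), dtype=bool)
    pixel_ok = np.zeros((ny, nx), dtype=bool)
    for (iy, ix), c in curves.items():
        n = c.n_samples
        good = np.isfinite(c.d) & np.isfinite(c.f)
        d[iy, ix, :n] = np.where(good, c.d, 0.0)
        f[iy, ix, :n] = np.where(good, c.f, 0.0)
        valid[iy, ix, :n] = good
        pixel_ok[iy, ix] = np.count_nonzero(good) >= 4
    return PackedCurves(d=d, f=f, valid=valid, pixel_ok=pixel_ok)


# ------------------------------------------------------------------ OLS cores

def _design_grid(packed: PackedCurves, ctx: PixelContext, cfg: ModelConfig,
                 td: TipDescriptors):
    """Design columns over the packed grid: (ny, nx, nmax, k) + validity."""
    gx = np.asarray(ctx.gx, dtype=float)[..., None]
    gy = np.asarray(ctx.gy, dtype=float)[..., None]
    cols, geom_ok = basis_functions(
        cfg.model, td, PixelContext(gx=gx, gy=gy), packed.d,
        poisson_ratio=cfg.poisson_ratio, r_cell=cfg.r_cell,
        angle_factor=cfg.angle_factor)
    return cols, geom_ok


def _solve_grid(cols: np.ndarray, f: np.ndarray, w: np.ndarray):
    """Weighted OLS per pixel via equilibrated normal equations.

    ``cols``: (ny, nx, n, k); ``f``: (ny, nx, n); ``w``: boolean sample use
    mask.  Returns (beta (ny, nx, k), singular (ny, nx) bool).
    Columns are scaled to unit norm before the solve so the 2x2 system's
    conditioning reflects only column correlation, not magnitude.
    """
    k = cols.shape[-1]
    wf = np.where(w, f, 0.0)
    wcols = np.where(w[..., None], cols, 0.0)
    A = np.einsum("...ni,...nj->...ij", wcols, wcols)
    b = np.einsum("...ni,...n->...i", wcols, wf)
    diag = np.sqrt(np.einsum("...ii->...i", A))
    zero_col = diag == 0.0
    s = np.where(zero_col, 1.0, diag)
    As = A / (s[..., :, None] * s[..., None, :])
    bs = b / s

    if k == 1:
        a11 = As[..., 0, 0]
        singular = a11 < 1e-12
        beta = np.where(singular, 0.0, bs[..., 0] / np.where(singular, 1.0, a11))[..., None]
    elif k == 2:
        det = As[..., 0, 0] * As[..., 1, 1] - As[..., 0, 1] * As[..., 1, 0]
        singular = (det < 1e-12) | np.any(zero_col, axis=-1)
        safe = np.where(singular, 1.0, det)
        b0 = (As[..., 1, 1] * bs[..., 0] - As[..., 0, 1] * bs[..., 1]) / safe
        b1 = (As[..., 0, 0] * bs[..., 1] - As[..., 0, 1] * bs[..., 0]) / safe
        beta = np.stack([b0, b1], axis=-1)
        beta = np.where(singular[..., None], 0.0, beta)
    else:  # pragma: no cover - no 3+ parameter model defined
        raise ValueError(f"unsupported parameter count {k}")
    # all-zero force with all-zero columns is a valid zero fit, not singular
    allzero = (np.abs(b).max(axis=-1) == 0.0) & np.all(zero_col, axis=-1)
    singular = singular & ~allzero
    return beta / s, singular


def _residual_rms_grid(cols, f, w, beta):
    pred = np.einsum("...ni,...i->...n", cols, beta)
    r2 = np.where(w, (f - pred) ** 2, 0.0)
    n = np.count_nonzero(w, axis=-1)
    with np.errstate(invalid="ignore"):
        rms = np.sqrt(r2.sum(axis=-1) / np.maximum(n, 1))
    return np.where(n > 0, rms, np.nan), n


# ----------------------------------------------------------------- public API

def fit_curve_linear(curve: ForceCurve, cfg: ModelConfig, td: TipDescriptors,
                     ctx: PixelContext) -> PixelFit:
    """OLS fit of one curve's force on the model's design columns.

    HS returns (sigma, E); Hertz/Sneddon return E; CSLC returns T.  No
    non-negativity constraint is applied — a negative modulus/tension sets
    the ``negative_E`` flag.  A singular design (e.g. all depths equal) is
    flagged, not raised.
    """
    flags = set()
    if curve.flag in ("missing", "too_shallow"):
        return PixelFit(model=cfg.model, flags=frozenset({curve.flag}))
    good = np.isfinite(curve.d) & np.isfinite(curve.f)
    d, f = curve.d[good], curve.f[good]
    if d.size < 4:
        return PixelFit(model=cfg.model, flags=frozenset({"too_shallow"}))

    cols, geom_ok = basis_functions(cfg.model, td, ctx, d,
                                    poisson_ratio=cfg.poisson_ratio,
                                    r_cell=cfg.r_cell, angle_factor=cfg.angle_factor)
    if not np.all(geom_ok):
        flags.add("geometry_violation")
        return PixelFit(model=cfg.model, flags=frozenset(flags), n_samples=int(d.size))

    names = PARAM_NAMES[cfg.model]
    if np.all(f == 0.0) and np.all(cols == 0.0):
        return PixelFit(model=cfg.model, params={n: 0.0 for n in names},
                        residual_rms=0.0, n_samples=int(d.size))
    scale = np.linalg.norm(cols, axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    beta_s, res, rank, _ = np.linalg.lstsq(cols / scale, f, rcond=None)
    beta = beta_s / scale
    if rank < len(names):
        flags.add("singular")
    resid = f - cols @ beta
    rms = float(np.sqrt(np.mean(resid**2)))
    params = dict(zip(names, (float(v) for v in beta)))
    if params.get("E", params.get("T", 0.0)) < 0:
        flags.add("negative_E")
    return PixelFit(model=cfg.model, params=params, residual_rms=rms,
                    n_samples=int(d.size), flags=frozenset(flags))


def _fit_grid(packed: PackedCurves, ctx: PixelContext, cfg: ModelConfig,
              td: TipDescriptors, sample_mask: Optional[np.ndarray] = None):
    """Shared vectorized fit. Returns beta, rms, n, flag arrays."""
    cols, geom_ok = _design_grid(packed, ctx, cfg, td)
    w = packed.valid if sample_mask is None else (packed.valid & sample_mask)
    geom_bad_pixel = np.any(packed.valid & ~geom_ok, axis=-1)
    w = w & geom_ok
    enough = np.count_nonzero(w, axis=-1) >= 4
    beta, singular = _solve_grid(cols, packed.f, w)
    rms, n = _residual_rms_grid(cols, packed.f, w, beta)
    n_bad = int(np.count_nonzero(packed.valid & ~geom_ok))
    return cols, w, beta, rms, n, {
        "geometry_violation": geom_bad_pixel,
        "too_shallow": packed.pixel_ok & ~enough,
        "singular": singular & packed.pixel_ok,
        "missing": ~packed.pixel_ok,
    }, n_bad


def fit_map(img: SpectrumImage, cfg: ModelConfig, td: TipDescriptors,
            objective: str = "variance", depth_window: Optional[float] = None,
            ctx: Optional[PixelContext] = None,
            packed: Optional[PackedCurves] = None) -> MapFitResult:
    """Fit every unmasked pixel independently; aggregate the map objective.

    ``objective`` is the variance (default) or sum of per-pixel residual rms
    over unmasked pixels.  Pixels with any flag are excluded from the
    objective and masked (NaN) in the parameter grids.  More than 50%
    flagged pixels is recorded in the result, not raised.
    """
    if objective not in ("variance", "sum"):
        raise ValueError(f"objective must be 'variance' or 'sum', got {objective!r}")
    if ctx is None:
        ctx = topography_gradients(img)
    if packed is None:
        packed = pack_curves(img, depth_window=depth_window)
    cols, w, beta, rms, n, flags, _ = _fit_grid(packed, ctx, cfg, td)

    names = PARAM_NAMES[cfg.model]
    neg = beta[..., -1] < 0.0  # modulus/tension is the last column of every model
    flags = dict(flags)
    flags["negative_E"] = neg & packed.pixel_ok
    hard = np.zeros(packed.pixel_ok.shape, dtype=bool)
    for name in _HARD_FLAGS:
        hard |= flags[name]
    # negative_E is a soft flag: the values stay in the grids (masking them
    # would bias shallow windows, where E is barely identifiable and the
    # sign of its noise correlates with the sigma estimate); callers can
    # mask via flags["negative_E"] if they want
    mask = hard

    params = {}
    for j, name in enumerate(names):
        arr = beta[..., j].copy()
        arr[mask] = np.nan
        params[name] = arr
    rms_out = rms.copy()
    rms_out[hard] = np.nan

    # objective over hard-valid pixels (matches map_objective): a negative
    # modulus is still a valid misfit measurement
    r = rms_out[~hard]
    if r.size == 0:
        obj = np.inf
    else:
        obj = float(np.var(r)) if objective == "variance" else float(np.sum(r))
    return MapFitResult(model=cfg.model, td=td, params=params,
                        residual_rms=rms_out, n_used=n, flags=flags, mask=mask,
                        objective=obj, objective_kind=objective,
                        depth_window=depth_window)


def map_objective(packed: PackedCurves, ctx: PixelContext, cfg: ModelConfig,
                  td: TipDescriptors, objective: str = "variance",
                  sample_mask: Optional[np.ndarray] = None) -> float:
    """Cheap map-wide objective for the MCMC search (no per-pixel outputs).

    A descriptor proposal whose geometry is nonphysical on more than
    ``GEOMETRY_VIOLATION_BUDGET`` of all samples returns +inf (an
    infinite-penalty signal), otherwise violating pixels are dropped from
    the aggregate.
    """
    _, w, beta, rms, n, flags, n_bad = _fit_grid(packed, ctx, cfg, td, sample_mask)
    total = int(np.count_nonzero(packed.valid))
    if total == 0 or n_bad > GEOMETRY_VIOLATION_BUDGET * total:
        return np.inf
    # only hard-invalid pixels leave the objective; a fit with a negative
    # modulus still measures misfit, and excluding such pixels would let a
    # bad proposal lower the aggregate by shedding its worst pixels
    bad = flags["missing"] | flags["too_shallow"] | flags["geometry_violation"] \
        | flags["singular"]
    r = rms[~bad]
    r = r[np.isfinite(r)]
    if r.size == 0:
        return np.inf
    return float(np.var(r)) if objective == "variance" else float(np.sum(r))


def propagated_noise_std(packed: PackedCurves, ctx: PixelContext,
                         cfg: ModelConfig, td: TipDescriptors,
                         noise_rms: float) -> Dict[str, np.ndarray]:
    """Per-pixel OLS parameter standard deviations under iid force noise.

    Standard linear-model propagation: ``Cov(beta) = s^2 (X^T X)^{-1}`` with
    ``s = noise_rms``.  Used to state what stress contrast a map can resolve
    — e.g. the fixed-cell null check: on a zero-stress specimen the fitted
    |sigma| should sit within a few of these bounds.  NaN where the design
    is unusable.
    """
    cols, geom_ok = _design_grid(packed, ctx, cfg, td)
    w = packed.valid & geom_ok
    wcols = np.where(w[..., None], cols, 0.0)
    A = np.einsum("...ni,...nj->...ij", wcols, wcols)
    k = A.shape[-1]
    names = PARAM_NAMES[cfg.model]
    out: Dict[str, np.ndarray] = {}
    if k == 1:
        a = A[..., 0, 0]
        with np.errstate(divide="ignore", invalid="ignore"):
            var = np.where(a > 0, noise_rms**2 / a, np.nan)
        out[names[0]] = np.sqrt(var)
    else:
        det = A[..., 0, 0] * A[..., 1, 1] - A[..., 0, 1] ** 2
        good = det > 0
        safe = np.where(good, det, 1.0)
        with np.errstate(invalid="ignore"):
            out[names[0]] = np.sqrt(np.where(good, noise_rms**2 * A[..., 1, 1] / safe, np.nan))
            out[names[1]] = np.sqrt(np.where(good, noise_rms**2 * A[..., 0, 0] / safe, np.nan))
    return out


def split_train_test(packed: PackedCurves, fraction_test: float = 0.125,
                     seed: int = 0) -> np.ndarray:
    """Deterministic per-seed, depth-stratified per-curve sample split.

    Within each curve the samples (already depth-ordered) are cut into
    ``round(n * fraction_test)`` contiguous depth blocks and one sample is
    drawn from each, so every curve contributes test points spanning its
    depth range and per-pixel variates stay estimable from the training
    points.  Curves with fewer than 8 samples go wholly to training.
    Returns a boolean test mask of ``packed`` shape.
    """
    if not (0.0 < fraction_test < 0.5):
        raise ValueError("fraction_test must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    ny, nx, _ = packed.shape
    test = np.zeros(packed.shape, dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            idx = np.nonzero(packed.valid[iy, ix])[0]
            n = idx.size
            if n < 8:
                continue
            n_test = max(1, round(n * fraction_test))
            for block in np.array_split(idx, n_test):
                test[iy, ix, block[rng.integers(0, block.size)]] = True
    return test


def prediction_error(packed: PackedCurves, ctx: PixelContext, cfg: ModelConfig,
                     td: TipDescriptors, test_mask: np.ndarray) -> PredictionError:
    """Out-of-sample force rms: fit each pixel on its training samples only,
    predict the held-out samples, aggregate the rms over all test points.

    Pixels with no test points (or unusable fits) are skipped from the
    aggregate; the per-pixel rms breakdown is retained (NaN where skipped).
    """
    cols, w, beta, _, _, flags, _ = _fit_grid(packed, ctx, cfg, td, ~test_mask)
    bad = flags["missing"] | flags["too_shallow"] | flags["geometry_violation"] \
        | flags["singular"]
    tw = packed.valid & test_mask & ~bad[..., None]
    pred = np.einsum("...ni,...i->...n", cols, beta)
    err2 = np.where(tw, (packed.f - pred) ** 2, 0.0)
    n_pix = np.count_nonzero(tw, axis=-1)
    with np.errstate(invalid="ignore"):
        per_pixel = np.sqrt(err2.sum(axis=-1) / np.maximum(n_pix, 1))
    per_pixel = np.where(n_pix > 0, per_pixel, np.nan)
    n_test = int(n_pix.sum())
    if n_test == 0:
        return PredictionError(rms=np.nan, per_pixel=per_pixel, n_test=0)
    rms = float(np.sqrt(err2.sum() / n_test))
    return PredictionError(rms=rms, per_pixel=per_pixel, n_test=n_test)
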