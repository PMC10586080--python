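"""Closed-form contact-mechanics force models and the shared tip-shape parametrization.

Four models are evaluated against AFM force-deformation data:

* **HS** — Hertzian sphere plus a horizontal-prestress term.  The prestress
  sigma enters linearly, so a tensile (positive) sigma adds resistance while a
  compressive (negative) sigma can make the *total* force negative at shallow
  depth (the indented element bends away from the tip).
* **Hertz** — classical spherical indenter, ``F ~ E sqrt(R) d^1.5``.
* **Sneddon** — conical indenter, ``F ~ E tan(theta) d^2``.
* **CSLC** — cortical shell with liquid core, force linear in depth and
  parametrized by cortical tension ``T`` and cell radius ``r_cell``.

All models share one tip-geometry parametrization: the effective tip radius
(or cone half-angle for Sneddon) is a linear function of the local topographic
gradients and the depth,

    R(d) = r + a * dz/dx + b * dz/dy + c * d

with coefficients ``(r, a, b, c)`` — the quantities the MCMC calibration
optimizes.  The gradient terms absorb tip asymmetry and scan/indent
synchronization error; the depth term absorbs deviation from an ideal
hemisphere (and, empirically, substrate proximity).

Every model is linear in its material parameters once the geometry is fixed,
which is what :func:`basis_functions` exposes: per-sample design columns such
that ``F = design @ params``.  Units are strict SI (m, N, Pa, N/m, rad).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "TipDescriptors",
    "ModelConfig",
    "PixelContext",
    "GeometryError",
    "MODELS",
    "PARAM_NAMES",
    "tip_radius_at",
    "default_angle_factor",
    "hs_force",
    "hertz_force",
    "sneddon_force",
    "cslc_force",
    "model_force",
    "basis_functions",
    "negative_force_crossover",
]

#: canonical model identifiers, in the order the four models are compared
MODELS = ("hs", "hertz", "sneddon", "cslc")

#: names of the linear material parameters each model fits
PARAM_NAMES = {
    "hs": ("sigma", "E"),
    "hertz": ("E",),
    "sneddon": ("E",),
    "cslc": ("T",),
}


class GeometryError(ValueError):
    """Effective tip geometry evaluated to a nonphysical value (R <= 0 or
    theta outside (0, pi/2)) at a sample used in a fit."""


@dataclass(frozen=True)
class TipDescriptors:
    """Tip-geometry variates ``(r, a, b, c)``.

    For the spherical-tip models ``r`` is the base radius (m), ``a, b`` couple
    to the topographic gradients (m per unit slope) and ``c`` to depth
    (dimensionless).  For the conical (Sneddon) model the same slots hold the
    base half-angle theta0 (rad), rad-per-slope couplings and a rad/m depth
    coupling; the geometry is then an angle, not a radius.
    """

    r: float
    a: float = 0.0
    b: float = 0.0
    c: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.a, self.b, self.c], dtype=float)

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TipDescriptors":
        r, a, b, c = (float(v) for v in x)
        return cls(r, a, b, c)


@dataclass(frozen=True)
class PixelContext:
    """Topographic gradients at a pixel (or broadcastable arrays of them).

    ``gx = dz/dx`` and ``gy = dz/dy`` are dimensionless slopes; ``gy`` is the
    gradient along the slow scan axis, which empirically couples strongest to
    the effective tip radius (scan/indent synchronization error).
    """

    gx: float | np.ndarray = 0.0
    gy: float | np.ndarray = 0.0


@dataclass(frozen=True)
class ModelConfig:
    """Which model to evaluate and its fixed (non-fitted) physical inputs."""

    model: str = "hs"
    poisson_ratio: float = 0.5  # incompressible cell, standard in AFM work
    r_cell: Optional[float] = None  # m, CSLC only
    angle_factor: Optional[Callable] = field(default=None, compare=False)

    def __post_init__(self):
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        g = self.poisson_ratio
        if not (0.0 <= g < 0.5 + 1e-9):
            raise ValueError(f"poisson_ratio {g} outside [0, 0.5]")
        if self.model == "cslc":
            if self.r_cell is None or self.r_cell <= 0:
                raise ValueError("cslc model requires r_cell > 0")


def tip_radius_at(td: TipDescriptors, ctx: PixelContext, d):
    """Effective tip radius (or half-angle) ``r + a*gx + b*gy + c*d``.

    Vectorized over ``d`` and over array-valued gradients.  Nonpositive
    results are returned as-is — callers treat them as geometry violations
    (the fitter converts them to an infinite-penalty flag, never a clamp).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < -0.0) and np.any(d < 0):
        raise ValueError("depth d must be >= 0")
    return td.r + td.a * np.asarray(ctx.gx) + td.b * np.asarray(ctx.gy) + td.c * d


def default_angle_factor(d, R):
    """cos(tan^-1 sqrt(2R/d)) written as the algebraic identity sqrt(d/(d+2R)).

    The identity form is exact (cos(atan x) = 1/sqrt(1+x^2)) and well behaved
    at d = 0.  Swappable so an alternate reading of the angle argument can be
    tested without touching the fitter.
    """
    d = np.asarray(d, dtype=float)
    R = np.asarray(R, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.sqrt(d / (d + 2.0 * R))
    return np.where(d == 0, 0.0, out)


def _check_depth(d) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth d must be >= 0")
    return d


def hs_force(sigma, E, R, d, poisson_ratio: float = 0.5, angle_factor=None):
    """Hertz-sphere-plus-prestress force.

    F = 4 pi R d sigma * cos(tan^-1 sqrt(2R/d)) + (4/3)(1/(1-g^2)) E sqrt(R) d^1.5

    The first term is the vertical projection of the pre-existing horizontal
    stress acting over the contact; the second is the classical Hertz term.
    sigma > 0 is tensile, sigma < 0 compressive.
    """
    d = _check_depth(d)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise GeometryError("hs_force requires R > 0")
    af = angle_factor or default_angle_factor
    return 4.0 * np.pi * R * d * sigma * af(d, R) + hertz_force(E, R, d, poisson_ratio)


def hertz_force(E, R, d, poisson_ratio: float = 0.5):
    """Classical Hertz sphere: F = (4/3)(1/(1-g^2)) E sqrt(R) d^1.5."""
    d = _check_depth(d)
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        raise GeometryError("hertz_force requires R > 0")
    return (4.0 / 3.0) / (1.0 - poisson_ratio**2) * E * np.sqrt(R) * d**1.5


def sneddon_force(E, theta, d, poisson_ratio: float = 0.5):
    """Conical indenter: F = (2 tan(theta) / pi)(1/(1-g^2)) E d^2."""
    d = _check_depth(d)
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= np.pi / 2):
        raise GeometryError("sneddon_force requires 0 < theta < pi/2")
    return (2.0 * np.tan(theta) / np.pi) / (1.0 - poisson_ratio**2) * E * d**2


def cslc_force(T, r_cell, R, d):
    """Cortical shell / liquid core: F = 4 T (1/r_cell + 1/R) pi R d.

    Linear in depth and in the cortical tension T (N/m); as R -> inf the
    dominant term is 4 pi T d R / r_cell.
    """
    d = _check_depth(d)
    R = np.asarray(R, dtype=float)
    if r_cell <= 0:
        raise ValueError("cslc_force requires r_cell > 0")
    if np.any(R <= 0):
        raise GeometryError("cslc_force requires R > 0")
    return 4.0 * T * (1.0 / r_cell + 1.0 / R) * np.pi * R * d


def model_force(params: Sequence[float], cfg: ModelConfig, td: TipDescriptors,
                ctx: PixelContext, d):
    """Force of ``cfg.model`` at depths ``d`` with the depth-dependent geometry."""
    cols, ok = basis_functions(cfg.model, td, ctx, d,
                               poisson_ratio=cfg.poisson_ratio, r_cell=cfg.r_cell,
                               angle_factor=cfg.angle_factor)
    if not np.all(ok):
        raise GeometryError(f"{cfg.model}: nonphysical tip geometry at some samples")
    return cols @ np.asarray(params, dtype=float)


def basis_functions(model: str, td: TipDescriptors, ctx: PixelContext, d,
                    poisson_ratio: float = 0.5, r_cell: Optional[float] = None,
                    angle_factor=None):
    """Design columns multiplying the linear material parameters of ``model``.

    Returns ``(columns, valid)`` where ``columns`` has shape ``d.shape + (k,)``
    (k = number of fitted parameters, see :data:`PARAM_NAMES`) and ``valid``
    is a boolean geometry mask per sample.  Invalid samples carry zeroed
    columns; callers must honour the mask rather than fit through it.

    The depth-dependent geometry ``R(d)`` (or ``theta(d)``) from
    :func:`tip_radius_at` is substituted pointwise into the constant-geometry
    expressions — the same treatment for every model.
    """
    d = _check_depth(d)
    geom = tip_radius_at(td, ctx, d)
    geom = np.broadcast_to(np.asarray(geom, dtype=float), d.shape).copy()

    if model == "sneddon":
        valid = (geom > 0.0) & (geom < np.pi / 2)
    else:
        valid = geom > 0.0
    safe = np.where(valid, geom, 1.0)

    pref = 1.0 / (1.0 - poisson_ratio**2)
    if model == "hs":
        af = angle_factor or default_angle_factor
        phi_sigma = 4.0 * np.pi * safe * d * af(d, safe)
        phi_E = (4.0 / 3.0) * pref * np.sqrt(safe) * d**1.5
        cols = np.stack([phi_sigma, phi_E], axis=-1)
    elif model == "hertz":
        cols = ((4.0 / 3.0) * pref * np.sqrt(safe) * d**1.5)[..., None]
    elif model == "sneddon":
        cols = ((2.0 * np.tan(safe) / np.pi) * pref * d**2)[..., None]
    elif model == "cslc":
        if r_cell is None or r_cell <= 0:
            raise ValueError("cslc basis requires r_cell > 0")
        cols = (4.0 * np.pi * d * (safe / r_cell + 1.0))[..., None]
    else:
        raise ValueError(f"unknown model {model!r}")

    cols = np.where(valid[..., None], cols, 0.0)
    return cols, valid


def negative_force_crossover(sigma: float, E: float, td: TipDescriptors,
                             ctx: PixelContext, d_max: float,
                             poisson_ratio: float = 0.5,
                             tol: float = 1e-6) -> float:
    """Depth ``d* > 0`` where the HS total force crosses zero, by bisection.

    For compressive prestress (sigma < 0) with E > 0 the prestress term
    dominates at shallow depth and the Hertz term at larger depth, so the
    total force is negative below d* and positive above.  Returns d* in m.

    Raises ``ValueError`` when no sign change exists on (0, d_max] (e.g.
    tensile sigma, where the force is positive throughout).
    """
    if d_max <= 0:
        raise ValueError("d_max must be > 0")

    def F(d):
        R = tip_radius_at(td, ctx, d)
        return float(hs_force(sigma, E, float(R), d, poisson_ratio))

    lo = d_max * 1e-9
    hi = d_max
    flo, fhi = F(lo), F(hi)
    if flo == 0.0:
        return lo
    if flo * fhi > 0:
        raise ValueError("no zero crossing of the total force on (0, d_max]")
    # plain bisection to relative tol on depth
    while (hi - lo) > tol * hi:
        mid = 0.5 * (lo + hi)
        fm = F(mid)
        if fm == 0.0:
            return mid
        if flo * fm < 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)
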