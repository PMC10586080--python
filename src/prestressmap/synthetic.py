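"""Virtual-cell phantoms: force-volume data with known ground truth.

Every test and recovery experiment in this package runs against data whose
true stress field, modulus field and tip geometry are known exactly.  The
phantom emulates the structures a live-cell scan presents to the analysis:

* a dome topography (truncated paraboloid — smooth, analytic gradients);
* fiber-like tensile stress segments (actin stress fibers, sigma > 0) over a
  compressive background (microtubule-dominated, sigma < 0);
* an optional two-layer stress structure under a nucleus disk: a cortex
  layer of thickness ``t`` over a deep (nucleoskeletal) layer;
* scan/indent synchronization error, injected as an extra tip-radius
  coupling to the topographic gradient along the scan axis;
* additive Gaussian force noise and trigger-threshold truncation
  (3 nN for mapping, 1.5 nN for line scans).

Forward curves use the HS (Hertz sphere + prestress) model with the true
depth-dependent tip radius.  The two-layer curve is an offset-matched
concatenation — continuous at the interface by construction; it is a test
scaffold for depth-window discrimination, not a physical multilayer model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Tuple

import numpy as np

from .contact_models import TipDescriptors, hs_force
from .io_formats import ForceCurve, SpectrumImage
from .mapping import LineScanSeries

__all__ = [
    "PhantomSpec",
    "Phantom",
    "AcquisitionConfig",
    "GroundTruth",
    "MAPPING_THRESHOLD_N",
    "LINESCAN_THRESHOLD_N",
    "make_phantom",
    "simulate_curve",
    "simulate_spectrum_image",
    "make_linescan_series",
]

#: instrument trigger forces: 3 nN for 2D mapping, 1.5 nN for line profiles
MAPPING_THRESHOLD_N = 3e-9
LINESCAN_THRESHOLD_N = 1.5e-9


@dataclass
class PhantomSpec:
    """Stated world of the virtual cell.  All SI.

    Defaults describe a desk-scale cell: a 16 um field (32 x 32 at 0.5 um
    pitch), 3 um dome, ~kPa-scale stresses (tensile fibers over a weaker
    compressive background), 10 kPa modulus, and a sharp tip whose effective
    radius couples to local slope and depth.
    """

    nx: int = 32
    ny: int = 32
    pitch: float = 0.5e-6
    seed: int = 0
    # topography
    dome_height: float = 3e-6
    dome_radius: float = 7e-6
    # stress field (layer 1 / cortex); tens-of-kPa scale, matching the
    # stress magnitudes live-cell depth maps report (~30-40 kPa tension)
    sigma_bg: float = -5e3          # compressive background, Pa
    sigma_fiber: float = 20e3       # tensile fiber stress, Pa
    n_fibers: int = 3
    fiber_width: float = 0.8e-6
    # optional deep layer under the nucleus disk
    two_layer: bool = False
    nucleus_radius: float = 3e-6
    sigma_deep: float = 30e3        # nucleoskeletal layer, Pa
    sigma_cortex: Optional[float] = None  # overrides layer-1 sigma inside nucleus
    cortex_thickness: float = 150e-9
    # modulus
    E0: float = 10e3                # Pa
    fiber_E_boost: float = 0.0      # optional stiffness elevation on fibers
    # true tip geometry (spherical-tip parametrization)
    tip_r: float = 50e-9
    tip_a: float = 10e-9
    tip_b: float = 30e-9
    tip_c: float = 0.02
    sync_b: float = 40e-9           # extra dz/dy coupling when sync error is on


@dataclass
class Phantom:
    """Realized fields plus queryable ground truth."""

    spec: PhantomSpec
    topography: np.ndarray      # (ny, nx) m
    sigma1: np.ndarray          # layer-1 (cortex) prestress, Pa
    sigma2: np.ndarray          # deep-layer prestress (== sigma1 when single-layer)
    E: np.ndarray               # Pa
    fiber_mask: np.ndarray
    nucleus_mask: np.ndarray
    gx: np.ndarray              # dz/dx, same finite differences the fitter uses
    gy: np.ndarray
    td_true: TipDescriptors = field(default=None)

    @property
    def pitch(self) -> float:
        return self.spec.pitch

    def sigma_at(self, ix: int, iy: int, layer: int = 1) -> float:
        """Ground-truth prestress at a pixel; layer 1 = cortex, 2 = deep."""
        return float((self.sigma1 if layer == 1 else self.sigma2)[iy, ix])

    def effective_td(self, sync_error: bool = False) -> TipDescriptors:
        """True descriptors, folding the sync-error coupling into b."""
        s = self.spec
        b = s.tip_b + (s.sync_b if sync_error else 0.0)
        return TipDescriptors(r=s.tip_r, a=s.tip_a, b=b, c=s.tip_c)


def make_phantom(spec: Optional[PhantomSpec] = None, **overrides) -> Phantom:
    """Build the deterministic phantom fields for ``spec`` (plus overrides).

    Fiber segments are chords across the dome drawn from the phantom seed;
    a fiber falling (partly) outside the grid is clipped with a warning.
    Same spec + seed => identical phantom, bit for bit.
    """
    spec = PhantomSpec(**{**asdict(spec or PhantomSpec()), **overrides})
    if spec.pitch <= 0 or spec.dome_height <= 0 or spec.dome_radius <= 0:
        raise ValueError("geometric parameters must be positive")
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.ny, spec.nx
    y, x = np.mgrid[0:ny, 0:nx].astype(float) * spec.pitch
    cx, cy = (nx - 1) * spec.pitch / 2, (ny - 1) * spec.pitch / 2
    rr = np.hypot(x - cx, y - cy)

    s2 = (rr / spec.dome_radius) ** 2
    topo = spec.dome_height * np.clip(1.0 - s2, 0.0, None)
    inside = rr < spec.dome_radius

    fiber = np.zeros((ny, nx), dtype=bool)
    half = 0.85 * min(spec.dome_radius, cx, cy)
    for _ in range(spec.n_fibers):
        ang = rng.uniform(0, np.pi)
        off = rng.uniform(-0.5, 0.5) * half
        ux, uy = np.cos(ang), np.sin(ang)
        px, py = cx - uy * off, cy + ux * off
        p0 = np.array([px - ux * half, py - uy * half])
        p1 = np.array([px + ux * half, py + uy * half])
        if np.any(p0 < 0) or np.any(p1 < 0) or p0[0] > (nx - 1) * spec.pitch \
                or p1[0] > (nx - 1) * spec.pitch or p0[1] > (ny - 1) * spec.pitch \
                or p1[1] > (ny - 1) * spec.pitch:
            warnings.warn("fiber extends outside the grid; clipping", stacklevel=2)
        # distance from every pixel to the segment p0-p1
        v = p1 - p0
        L2 = float(v @ v)
        t = np.clip(((x - p0[0]) * v[0] + (y - p0[1]) * v[1]) / L2, 0.0, 1.0)
        dist = np.hypot(x - (p0[0] + t * v[0]), y - (p0[1] + t * v[1]))
        fiber |= dist <= spec.fiber_width / 2
    fiber &= inside

    sigma1 = np.where(inside, spec.sigma_bg, 0.0)
    sigma1 = np.where(fiber, spec.sigma_fiber, sigma1)
    nucleus = rr < spec.nucleus_radius
    if spec.sigma_cortex is not None:
        sigma1 = np.where(nucleus, spec.sigma_cortex, sigma1)
    sigma2 = np.where(nucleus, spec.sigma_deep, sigma1) if spec.two_layer \
        else sigma1.copy()

    E = np.full((ny, nx), spec.E0)
    if spec.fiber_E_boost:
        E = np.where(fiber, spec.E0 + spec.fiber_E_boost, E)

    gy, gx = np.gradient(topo, spec.pitch)
    return Phantom(spec=spec, topography=topo, sigma1=sigma1, sigma2=sigma2,
                   E=E, fiber_mask=fiber, nucleus_mask=nucleus, gx=gx, gy=gy,
                   td_true=TipDescriptors(spec.tip_r, spec.tip_a, spec.tip_b,
                                          spec.tip_c))


@dataclass
class AcquisitionConfig:
    """How the virtual instrument samples the phantom."""

    d_max: float = 800e-9
    d_step: float = 10e-9
    force_threshold: Optional[float] = MAPPING_THRESHOLD_N  # None = no trigger
    noise_rms: float = 0.0          # N, additive iid Gaussian on force
    sync_error: bool = False
    spring_constant: float = 0.05   # N/m, metadata only
    poisson_ratio: float = 0.5
    seed: int = 0

    def depth_grid(self) -> np.ndarray:
        return np.arange(0.0, self.d_max + self.d_step / 2, self.d_step)


def simulate_curve(ph: Phantom, pixel: Tuple[int, int],
                   d_grid: Optional[np.ndarray] = None, *,
                   sync_error: bool = False, noise_rms: float = 0.0,
                   force_threshold: Optional[float] = MAPPING_THRESHOLD_N,
                   poisson_ratio: float = 0.5,
                   rng: Optional[np.random.Generator] = None) -> ForceCurve:
    """Forward HS curve at one pixel with the true depth-dependent tip radius.

    Two-layer pixels (inside the nucleus disk of a ``two_layer`` phantom) use
    layer-1 parameters down to the cortex thickness ``t`` and continue with
    the deep layer, offset-matched so the curve is continuous at ``d = t``.
    Gaussian noise of ``noise_rms`` is added, then the curve is cut at the
    first sample at or above the trigger threshold; if the trigger is never
    reached the curve ends at ``d_max`` flagged ``'threshold_not_reached'``.
    """
    ix, iy = pixel
    s = ph.spec
    if not (0 <= ix < s.nx and 0 <= iy < s.ny):
        raise ValueError(f"pixel {pixel} outside grid")
    if d_grid is None:
        d_grid = AcquisitionConfig().depth_grid()
    d = np.asarray(d_grid, dtype=float)
    td = ph.effective_td(sync_error)
    R = td.r + td.a * ph.gx[iy, ix] + td.b * ph.gy[iy, ix] + td.c * d
    if np.any(R <= 0):
        raise ValueError(f"pixel {pixel}: true tip geometry nonpositive")

    E = ph.E[iy, ix]
    f = hs_force(ph.sigma1[iy, ix], E, R, d, poisson_ratio)
    if s.two_layer and ph.nucleus_mask[iy, ix]:
        t = s.cortex_thickness
        Rt = td.r + td.a * ph.gx[iy, ix] + td.b * ph.gy[iy, ix] + td.c * t
        f1_t = hs_force(ph.sigma1[iy, ix], E, Rt, t, poisson_ratio)
        f2_t = hs_force(ph.sigma2[iy, ix], E, Rt, t, poisson_ratio)
        f2 = hs_force(ph.sigma2[iy, ix], E, R, d, poisson_ratio)
        deep = d > t
        f = np.where(deep, f2 - f2_t + f1_t, f)

    if noise_rms > 0:
        if rng is None:
            rng = np.random.default_rng(s.seed)
        f = f + rng.normal(0.0, noise_rms, size=f.shape)
        f[0] = 0.0  # contact defines the force zero

    flag = None
    if force_threshold is not None:
        hit = np.nonzero(f >= force_threshold)[0]
        if hit.size:
            f = f[: hit[0] + 1]
            d = d[: hit[0] + 1]
        else:
            flag = "threshold_not_reached"
    if d.size < 4:
        return ForceCurve(d=d, f=f, contact_height=float(ph.topography[iy, ix]),
                          pixel=(ix, iy), flag="too_shallow")
    return ForceCurve(d=d, f=f, contact_height=float(ph.topography[iy, ix]),
                      pixel=(ix, iy), flag=flag)


@dataclass
class GroundTruth:
    """Per-pixel truth carried alongside a simulated container."""

    sigma: np.ndarray           # layer-1 prestress, Pa
    sigma_deep: np.ndarray
    E: np.ndarray
    td: TipDescriptors          # effective descriptors (sync folded in)
    fiber_mask: np.ndarray
    two_layer: bool
    cortex_thickness: float

    def to_json(self) -> str:
        return json.dumps({
            "td": dict(zip("rabc", self.td.as_array().tolist())),
            "two_layer": self.two_layer,
            "cortex_thickness_m": self.cortex_thickness,
            "sigma_Pa": self.sigma.tolist(),
            "sigma_deep_Pa": self.sigma_deep.tolist(),
            "E_Pa": self.E.tolist(),
            "fiber_mask": self.fiber_mask.astype(int).tolist(),
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        o = json.loads(text)
        td = o["td"]
        return cls(sigma=np.array(o["sigma_Pa"]),
                   sigma_deep=np.array(o["sigma_deep_Pa"]),
                   E=np.array(o["E_Pa"]),
                   td=TipDescriptors(td["r"], td["a"], td["b"], td["c"]),
                   fiber_mask=np.array(o["fiber_mask"], dtype=bool),
                   two_layer=bool(o["two_layer"]),
                   cortex_thickness=float(o["cortex_thickness_m"]))


def simulate_spectrum_image(ph: Phantom,
                            acq: Optional[AcquisitionConfig] = None
                            ) -> Tuple[SpectrumImage, GroundTruth]:
    """Acquire the full virtual force volume: one curve per pixel, row-major.

    Exactly reproducible from (phantom spec, acquisition seed).
    """
    acq = acq or AcquisitionConfig()
    rng = np.random.default_rng(acq.seed)
    d_grid = acq.depth_grid()
    curves: Dict[Tuple[int, int], ForceCurve] = {}
    for iy in range(ph.spec.ny):
        for ix in range(ph.spec.nx):
            curves[(iy, ix)] = simulate_curve(
                ph, (ix, iy), d_grid, sync_error=acq.sync_error,
                noise_rms=acq.noise_rms, force_threshold=acq.force_threshold,
                poisson_ratio=acq.poisson_ratio, rng=rng)
    img = SpectrumImage(
        nx=ph.spec.nx, ny=ph.spec.ny, pixel_pitch=ph.spec.pitch,
        spring_constant=acq.spring_constant,
        force_threshold=(acq.force_threshold if acq.force_threshold is not None
                         else np.inf),
        topography=ph.topography.copy(), curves=curves, scan_axis="y")
    gt = GroundTruth(sigma=ph.sigma1.copy(), sigma_deep=ph.sigma2.copy(),
                     E=ph.E.copy(), td=ph.effective_td(acq.sync_error),
                     fiber_mask=ph.fiber_mask.copy(),
                     two_layer=ph.spec.two_layer,
                     cortex_thickness=ph.spec.cortex_thickness)
    return img, gt


def make_linescan_series(n_times: int = 120, n_pix: int = 64,
                         pitch: float = 0.25e-6, t_step: float = 30.0,
                         stress_peak: float = 2e3, decay_to: float = 1.0,
                         tau: float = 600.0, height_peak: float = 3e-6,
                         height_factor_final: float = 1.0,
                         noise_rel: float = 0.0, seed: int = 0) -> LineScanSeries:
    """Synthesize a repeated-line-scan time series of stress and height.

    A Gaussian stress bump and a 1D dome height profile are replayed at
    ``t_step`` intervals; the central stress amplitude relaxes exponentially
    (time constant ``tau``) toward ``decay_to`` x its initial value, the
    height toward ``height_factor_final`` x initial.  This emulates the
    profile-level signature of a cell responding to repeated indentation; it
    is a profile generator, not a curve-level simulation.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(n_times, dtype=float) * t_step
    xs = (np.arange(n_pix) - (n_pix - 1) / 2) * pitch
    span = (n_pix - 1) * pitch / 2
    bump = np.exp(-0.5 * (xs / (span / 3)) ** 2)
    dome = np.clip(1.0 - (xs / span) ** 2, 0.0, None)

    relax = np.exp(-times / tau)
    s_amp = stress_peak * (decay_to + (1.0 - decay_to) * relax)
    h_amp = height_peak * (height_factor_final + (1.0 - height_factor_final) * relax)
    stress = s_amp[:, None] * bump[None, :]
    height = h_amp[:, None] * dome[None, :]
    if noise_rel > 0:
        stress = stress + rng.normal(0, noise_rel * stress_peak, stress.shape)
        height = height + rng.normal(0, noise_rel * height_peak, height.shape)
    return LineScanSeries(times=times, stress=stress, height=height, pitch=pitch)
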