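"""Raw-trace conversion, contact detection, depth windows, topography gradients.

The analysis proper starts from post-contact force-deformation (f-d) curves.
When only raw approach traces (piezo height + cantilever deflection) are
available, :func:`raw_to_fd` converts them: force is spring constant times
baseline-corrected deflection, deformation is piezo travel minus cantilever
bending past the contact point.  Contact detection is not a settled
procedure; the default is a noise-floor threshold on the baseline-corrected
force, refined by backward extrapolation of a d^1.5 (Hertz-like) fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_models import PixelContext
from .io_formats import ForceCurve, SpectrumImage

__all__ = ["RawTrace", "raw_to_fd", "truncate_to_depth", "topography_gradients"]


@dataclass
class RawTrace:
    """Approach segment of a raw indentation: piezo height vs deflection."""

    z_piezo: np.ndarray   # m, increasing toward the sample
    deflection: np.ndarray  # m
    k: float              # cantilever spring constant, N/m

    def __post_init__(self):
        self.z_piezo = np.asarray(self.z_piezo, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z_piezo.shape != self.deflection.shape or self.z_piezo.ndim != 1:
            raise ValueError("z_piezo and deflection must be equal-length 1D arrays")
        if self.k <= 0:
            raise ValueError("spring constant must be > 0")


def raw_to_fd(trace: RawTrace, method: str = "baseline_mad",
              pixel=(0, 0)) -> ForceCurve:
    """Convert an approach trace to a post-contact f-d curve.

    ``method``:

    * ``"baseline_mad"`` (default) — fit a linear baseline to the first 30%
      of the approach; contact is the first sample whose force exceeds the
      baseline by 5x the MAD-estimated noise, refined by extrapolating a
      F ~ (z - z0)^1.5 fit back to zero force.
    * ``"baseline_simple"`` — same baseline, no d^1.5 refinement.

    Force: ``f = k * (deflection - baseline)``.  Deformation:
    ``d = (z - z0) - (deflection - deflection(z0))``, clipped to >= 0.
    A trace whose force never rises above the noise floor is returned with
    ``flag='missing'``.
    """
    if method not in ("baseline_mad", "baseline_simple"):
        raise ValueError(f"unknown contact-detection method {method!r}")
    z, defl, k = trace.z_piezo, trace.deflection, trace.k
    n = z.size
    if n < 8:
        return ForceCurve(d=np.zeros(1), f=np.zeros(1), pixel=pixel, flag="missing")

    nb = max(4, int(0.3 * n))
    coeffs = np.polyfit(z[:nb], defl[:nb], 1)
    baseline = np.polyval(coeffs, z)
    f = k * (defl - baseline)

    resid = defl[:nb] - np.polyval(coeffs, z[:nb])
    mad = np.median(np.abs(resid - np.median(resid)))
    noise = k * 1.4826 * mad
    floor = max(5.0 * noise, 1e-13)  # 0.1 pN absolute floor for clean traces

    above = np.nonzero(f > floor)[0]
    above = above[above >= nb // 2]
    if above.size == 0 or above[0] >= n - 3:
        return ForceCurve(d=np.zeros(1), f=np.zeros(1), pixel=pixel, flag="missing")
    i0 = int(above[0])
    z0 = z[i0]

    if method == "baseline_mad":
        # refine z0: F = A (z - z0)^1.5  =>  F^(2/3) linear in z
        sel = slice(i0, min(n, i0 + max(8, (n - i0) // 2)))
        fs, zs = f[sel], z[sel]
        pos = fs > 0
        if np.count_nonzero(pos) >= 4:
            p = np.polyfit(zs[pos], fs[pos] ** (2.0 / 3.0), 1)
            if p[0] > 0:
                z0_ref = -p[1] / p[0]
                # only accept a refinement inside the local bracket
                if z[max(0, i0 - 5)] <= z0_ref <= z[min(n - 1, i0 + 5)]:
                    z0 = z0_ref

    post = z >= z0
    if np.count_nonzero(post) < 4:
        return ForceCurve(d=np.zeros(1), f=np.zeros(1), pixel=pixel, flag="missing")
    defl0 = float(np.interp(z0, z, defl))
    d = (z[post] - z0) - (defl[post] - defl0)
    d = np.maximum(d, 0.0)
    d[0] = 0.0
    fp = f[post].copy()
    # keep monotone depth ordering; physical approach traces already are
    order = np.argsort(d, kind="stable")
    return ForceCurve(d=d[order], f=fp[order], contact_height=float(z0), pixel=pixel)


def truncate_to_depth(curve: ForceCurve, d_max: float) -> ForceCurve:
    """Restrict a curve to samples with d <= d_max (a depth window).

    Shallow windows probe the cortex; the full depth reads the
    nucleoskeleton-dominated response.  A window leaving fewer than 4 samples
    returns the curve flagged ``'too_shallow'``.
    """
    if d_max <= 0:
        raise ValueError("d_max must be > 0")
    if curve.flag in ("missing", "too_shallow"):
        return curve
    keep = curve.d <= d_max
    if np.count_nonzero(keep) < 4:
        return ForceCurve(d=curve.d, f=curve.f, contact_height=curve.contact_height,
                          pixel=curve.pixel, flag="too_shallow")
    if np.all(keep):
        return curve
    return ForceCurve(d=curve.d[keep], f=curve.f[keep],
                      contact_height=curve.contact_height, pixel=curve.pixel,
                      flag=curve.flag)


def topography_gradients(img: SpectrumImage) -> PixelContext:
    """Per-pixel topographic gradients (dimensionless slopes).

    Central differences over the pixel pitch in the interior, one-sided at
    the edges.  Returns a :class:`PixelContext` whose ``gx``/``gy`` are
    (ny, nx) arrays: ``gx`` is dz/dx (along axis 1), ``gy`` dz/dy (along
    axis 0, the default scan direction — the gradient that couples strongest
    to the effective tip radius through scan/indent synchronization error).
    """
    gy, gx = np.gradient(img.topography, img.pixel_pitch)
    return PixelContext(gx=gx, gy=gy)
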