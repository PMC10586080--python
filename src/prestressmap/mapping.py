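"""Map assembly, depth-windowed refits, radial profiles, line-scan statistics.

Downstream of the tip calibration, the per-pixel fits become physical-quantity
images: a signed prestress map (tensile positive, compressive negative), a
modulus map and the simultaneous topography.  Re-fitting the same curves
truncated to a shallow depth window reads the cortex; the full depth reads
the nucleoskeleton-dominated response — the descriptors are calibrated once
on the full curves and reused for every window.  Radial profiles and
central-window line-scan statistics condense round cells and time series to
1D curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .contact_models import ModelConfig, TipDescriptors
from .fitting import MapFitResult, fit_map
from .io_formats import SpectrumImage

__all__ = [
    "ScalarMap",
    "RadialProfile",
    "LineScanSeries",
    "build_maps",
    "depth_windowed_maps",
    "radial_profile",
    "linescan_stats",
]


@dataclass
class ScalarMap:
    """A 2D physical-quantity image with units, mask and provenance."""

    values: np.ndarray
    units: str
    pixel_pitch: float
    mask: Optional[np.ndarray] = None
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map values must be 2D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    def masked_values(self) -> np.ndarray:
        if self.mask is None:
            return self.values
        return np.where(self.mask, np.nan, self.values)


@dataclass
class RadialProfile:
    """Mean map value in equal-width radial bins around a center."""

    center: Tuple[float, float]   # pixel coords (ix, iy)
    bin_edges: np.ndarray         # m
    mean: np.ndarray
    counts: np.ndarray
    normalized: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class LineScanSeries:
    """Repeated 1D scans: per-time stress and height profiles."""

    times: np.ndarray        # s, strictly increasing
    stress: np.ndarray       # (n_times, n_pix), Pa
    height: np.ndarray       # (n_times, n_pix), m
    pitch: float             # m

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        self.height = np.asarray(self.height, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.stress.shape != self.height.shape or \
                self.stress.shape[0] != self.times.size:
            raise ValueError("stress/height must be (n_times, n_pix) and match times")
        if self.pitch <= 0:
            raise ValueError("pitch must be > 0")


def build_maps(fit: MapFitResult, img: SpectrumImage) -> Dict[str, ScalarMap]:
    """Assemble the stress / modulus (or tension) / topography maps of a fit.

    Keys: ``"stress"`` (HS only, signed Pa), ``"modulus"`` (Pa; ``"tension"``
    in N/m for CSLC), ``"topography"`` (m, straight from contact heights —
    never altered by the fit).  Fit masks propagate to the fitted maps only.
    """
    prov = {"model": fit.model, "td": tuple(fit.td.as_array()),
            "objective": fit.objective, "depth_window": fit.depth_window}
    out: Dict[str, ScalarMap] = {}
    if "sigma" in fit.params:
        out["stress"] = ScalarMap(fit.params["sigma"], "Pa", img.pixel_pitch,
                                  mask=fit.mask.copy(), provenance=dict(prov))
    if "E" in fit.params:
        out["modulus"] = ScalarMap(fit.params["E"], "Pa", img.pixel_pitch,
                                   mask=fit.mask.copy(), provenance=dict(prov))
    if "T" in fit.params:
        out["tension"] = ScalarMap(fit.params["T"], "N/m", img.pixel_pitch,
                                   mask=fit.mask.copy(), provenance=dict(prov))
    out["topography"] = ScalarMap(img.topography.copy(), "m", img.pixel_pitch,
                                  mask=img.missing_mask(),
                                  provenance={"source": "contact heights"})
    return out


def depth_windowed_maps(img: SpectrumImage, td: TipDescriptors,
                        cfg: ModelConfig, windows: Sequence[float],
                        objective: str = "variance"
                        ) -> List[Dict[str, ScalarMap]]:
    """Refit per pixel within each depth window ``d <= d_max`` (fixed ``td``).

    ``windows`` must be ascending depths in m (e.g. ``[100e-9, 800e-9]`` for
    cortex vs nucleoskeleton).  Pixels left with fewer than 4 samples in a
    window are masked in that window's maps.  Each returned map set carries
    its window in the provenance.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("windows list is empty")
    if any(w <= 0 for w in windows) or any(b <= a for a, b in zip(windows, windows[1:])):
        raise ValueError("windows must be positive and strictly ascending")
    out = []
    for w in windows:
        fit = fit_map(img, cfg, td, objective=objective, depth_window=w)
        maps = build_maps(fit, img)
        for m in maps.values():
            m.provenance["depth_window_m"] = w
        out.append(maps)
    return out


def radial_profile(scalar_map: ScalarMap, center: Tuple[float, float],
                   r_max: float, n_bins: int = 32,
                   normalize: bool = False) -> RadialProfile:
    """Azimuthal average in equal-width radial bins out to ``r_max`` (m).

    ``center`` is in pixel coordinates (ix, iy) and must lie inside the map.
    Masked pixels never contribute; an empty bin yields NaN with count 0.
    ``normalize`` divides by the maximum |mean| so the profile peaks at 1.
    """
    ny, nx = scalar_map.values.shape
    cx, cy = center
    if not (0 <= cx <= nx - 1 and 0 <= cy <= ny - 1):
        raise ValueError(f"center {center} outside the map")
    if r_max <= 0 or n_bins < 1:
        raise ValueError("r_max and n_bins must be positive")
    y, x = np.mgrid[0:ny, 0:nx].astype(float)
    rr = np.hypot(x - cx, y - cy) * scalar_map.pixel_pitch
    vals = scalar_map.masked_values()
    use = np.isfinite(vals) & (rr <= r_max)

    edges = np.linspace(0.0, r_max, n_bins + 1)
    idx = np.clip(np.digitize(rr[use], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals[use], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    normalized = False
    if normalize:
        peak = np.nanmax(np.abs(mean))
        if peak > 0:
            mean = mean / peak
            normalized = True
    return RadialProfile(center=(float(cx), float(cy)), bin_edges=edges,
                         mean=mean, counts=counts, normalized=normalized)


def linescan_stats(series: LineScanSeries, window_center: Optional[float] = None,
                   window_width: float = 5e-6, height_stat: str = "max"
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Central-window time statistics of a repeated line scan.

    Returns ``(mean_stress, height)`` versus time: the mean stress within the
    window (default 5 um wide, centered on the scan) and the per-time height
    statistic over the same window (``"max"`` by default, ``"mean"``
    selectable).  The window must fit inside the profile.
    """
    n_pix = series.stress.shape[1]
    length = (n_pix - 1) * series.pitch
    if window_center is None:
        window_center = length / 2
    half = window_width / 2
    if window_width <= 0 or window_center - half < -1e-12 or \
            window_center + half > length + 1e-12:
        raise ValueError(
            f"window [{window_center - half:.2e}, {window_center + half:.2e}] m "
            f"outside the {length:.2e} m profile")
    xs = np.arange(n_pix) * series.pitch
    sel = (xs >= window_center - half) & (xs <= window_center + half)
    if not np.any(sel):
        raise ValueError("window contains no profile points")
    mean_stress = series.stress[:, sel].mean(axis=1)
    if height_stat == "max":
        height = series.height[:, sel].max(axis=1)
    elif height_stat == "mean":
        height = series.height[:, sel].mean(axis=1)
    else:
        raise ValueError("height_stat must be 'max' or 'mean'")
    return mean_stress, height
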