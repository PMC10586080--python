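"""Force-volume container I/O and map export.

A *spectrum image* (force volume) is a grid of force-deformation curves with
simultaneous topography.  No vendor format is read here; the package defines
its own minimal container in two dialects:

* **hdf5** — ``/meta`` attrs (nx, ny, pixel_pitch_m, spring_constant_N_per_m,
  force_threshold_N, scan_axis), ``/topography`` (ny x nx float64, m),
  ``/curves/<iy>_<ix>/d`` and ``.../f`` (float64; m and N).
* **tsv_dir** — a debug-friendly directory: ``meta.json`` +
  ``topography.csv`` + ``curves/<iy>_<ix>.tsv`` (two columns ``d_m``, ``f_N``,
  header required).

All stored values are strict SI; the reader never guesses units — missing
unit-bearing metadata is a hard error.  Missing pixels are explicit (absent
curve group), never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import h5py
import numpy as np

__all__ = [
    "ForceCurve",
    "SpectrumImage",
    "FormatError",
    "read_force_volume",
    "write_force_volume",
    "export_map",
]

_META_KEYS = ("nx", "ny", "pixel_pitch_m", "spring_constant_N_per_m",
              "force_threshold_N", "scan_axis")


class FormatError(ValueError):
    """Container does not conform to the documented layout."""


@dataclass
class ForceCurve:
    """One pixel's post-contact force-deformation samples.

    ``d`` is the deformation (m, monotone nondecreasing, d[0] == 0 at
    contact), ``f`` the force (N).  ``contact_height`` is the piezo height at
    contact and becomes the topography entry.  ``flag`` marks curves the
    fitter must skip ("missing", "too_shallow", "threshold_not_reached").
    """

    d: np.ndarray
    f: np.ndarray
    contact_height: float = 0.0
    pixel: Tuple[int, int] = (0, 0)  # (ix, iy)
    flag: Optional[str] = None

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.d.shape != self.f.shape or self.d.ndim != 1:
            raise FormatError(f"curve {self.pixel}: d and f must be equal-length 1D arrays")
        if self.flag not in ("missing", "too_shallow"):
            if self.d.size < 4:
                raise FormatError(f"curve {self.pixel}: needs >= 4 samples, got {self.d.size}")
            if self.d[0] != 0.0:
                raise FormatError(f"curve {self.pixel}: d[0] must be 0 at contact")
            dd = np.diff(self.d)
            if np.any(dd < 0):
                raise FormatError(f"curve {self.pixel}: d must be monotone nondecreasing")

    @property
    def n_samples(self) -> int:
        return int(self.d.size)


@dataclass
class SpectrumImage:
    """Pixel grid of force curves with topography and acquisition metadata.

    ``topography[iy, ix]`` is the contact height (m); ``curves[(iy, ix)]``
    holds the per-pixel :class:`ForceCurve`.  Pixels absent from ``curves``
    are missing and show up in :meth:`missing_mask`.  ``scan_axis`` names the
    fast scan direction ('x' or 'y').
    """

    nx: int
    ny: int
    pixel_pitch: float
    spring_constant: float
    force_threshold: float
    topography: np.ndarray
    curves: Dict[Tuple[int, int], ForceCurve] = field(default_factory=dict)
    scan_axis: str = "y"

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise FormatError("nx and ny must be >= 2")
        if self.pixel_pitch <= 0:
            raise FormatError("pixel_pitch must be > 0")
        if self.scan_axis not in ("x", "y"):
            raise FormatError(f"scan_axis must be 'x' or 'y', got {self.scan_axis!r}")
        self.topography = np.asarray(self.topography, dtype=float)
        if self.topography.shape != (self.ny, self.nx):
            raise FormatError(
                f"topography shape {self.topography.shape} != (ny, nx) = {(self.ny, self.nx)}")
        # trigger overshoot allowance: one depth step past the threshold
        # crossing plus additive noise can land the last sample above the
        # nominal trigger force
        tol = 0.25
        for (iy, ix), c in self.curves.items():
            if not (0 <= ix < self.nx and 0 <= iy < self.ny):
                raise FormatError(f"curve index {(iy, ix)} outside grid")
            if c.flag is None and c.f.size:
                fmax = np.nanmax(c.f) if np.any(np.isfinite(c.f)) else 0.0
                if fmax > self.force_threshold * (1.0 + tol):
                    raise FormatError(
                        f"curve {(iy, ix)}: max force {fmax:.3e} N exceeds trigger "
                        f"threshold {self.force_threshold:.3e} N")

    def missing_mask(self) -> np.ndarray:
        """Boolean (ny, nx) mask, True where no usable curve exists."""
        m = np.ones((self.ny, self.nx), dtype=bool)
        for (iy, ix), c in self.curves.items():
            if c.flag != "missing":
                m[iy, ix] = False
        return m

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectrumImage):
            return NotImplemented
        if (self.nx, self.ny, self.scan_axis) != (other.nx, other.ny, other.scan_axis):
            return False
        for attr in ("pixel_pitch", "spring_constant", "force_threshold"):
            if getattr(self, attr) != getattr(other, attr):
                return False
        if not np.array_equal(self.topography, other.topography, equal_nan=True):
            return False
        if set(self.curves) != set(other.curves):
            return False
        for k, c in self.curves.items():
            o = other.curves[k]
            if not (np.array_equal(c.d, o.d, equal_nan=True)
                    and np.array_equal(c.f, o.f, equal_nan=True)
                    and c.contact_height == o.contact_height
                    and c.flag == o.flag):
                return False
        return True


# ---------------------------------------------------------------- HDF5 dialect

def _write_hdf5(img: SpectrumImage, path: Path) -> None:
    with h5py.File(path, "w") as h5:
        meta = h5.create_group("meta")
        meta.attrs["nx"] = img.nx
        meta.attrs["ny"] = img.ny
        meta.attrs["pixel_pitch_m"] = img.pixel_pitch
        meta.attrs["spring_constant_N_per_m"] = img.spring_constant
        meta.attrs["force_threshold_N"] = img.force_threshold
        meta.attrs["scan_axis"] = img.scan_axis
        h5.create_dataset("topography", data=img.topography)
        curves = h5.create_group("curves")
        for (iy, ix), c in sorted(img.curves.items()):
            g = curves.create_group(f"{iy}_{ix}")
            g.create_dataset("d", data=c.d)
            g.create_dataset("f", data=c.f)
            g.attrs["contact_height_m"] = c.contact_height
            if c.flag is not None:
                g.attrs["flag"] = c.flag


def _read_hdf5(path: Path) -> SpectrumImage:
    with h5py.File(path, "r") as h5:
        if "meta" not in h5:
            raise FormatError("missing /meta group")
        meta = h5["meta"].attrs
        for key in _META_KEYS:
            if key not in meta:
                raise FormatError(f"missing /meta attribute {key!r}")
        if "topography" not in h5:
            raise FormatError("missing /topography dataset")
        topo = np.asarray(h5["topography"], dtype=float)
        curves: Dict[Tuple[int, int], ForceCurve] = {}
        if "curves" in h5:
            for name, g in h5["curves"].items():
                try:
                    iy, ix = (int(v) for v in name.split("_"))
                except ValueError as e:
                    raise FormatError(f"malformed curve group name {name!r}") from e
                if "d" not in g or "f" not in g:
                    raise FormatError(f"curve {name}: missing d or f dataset")
                curves[(iy, ix)] = ForceCurve(
                    d=np.asarray(g["d"], dtype=float),
                    f=np.asarray(g["f"], dtype=float),
                    contact_height=float(g.attrs.get("contact_height_m", 0.0)),
                    pixel=(ix, iy),
                    flag=(str(g.attrs["flag"]) if "flag" in g.attrs else None),
                )
        return SpectrumImage(
            nx=int(meta["nx"]), ny=int(meta["ny"]),
            pixel_pitch=float(meta["pixel_pitch_m"]),
            spring_constant=float(meta["spring_constant_N_per_m"]),
            force_threshold=float(meta["force_threshold_N"]),
            topography=topo, curves=curves, scan_axis=str(meta["scan_axis"]),
        )


# ------------------------------------------------------------- TSV-dir dialect

def _write_tsv_dir(img: SpectrumImage, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "nx": img.nx, "ny": img.ny,
        "pixel_pitch_m": img.pixel_pitch,
        "spring_constant_N_per_m": img.spring_constant,
        "force_threshold_N": img.force_threshold,
        "scan_axis": img.scan_axis,
        "flags": {f"{iy}_{ix}": c.flag for (iy, ix), c in img.curves.items()
                  if c.flag is not None},
        "contact_heights": {f"{iy}_{ix}": c.contact_height
                            for (iy, ix), c in sorted(img.curves.items())},
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.savetxt(path / "topography.csv", img.topography, delimiter=",", fmt="%.17g")
    cdir = path / "curves"
    cdir.mkdir(exist_ok=True)
    for (iy, ix), c in sorted(img.curves.items()):
        arr = np.column_stack([c.d, c.f])
        np.savetxt(cdir / f"{iy}_{ix}.tsv", arr, delimiter="\t",
                   header="d_m\tf_N", comments="", fmt="%.17g")


def _read_tsv_dir(path: Path) -> SpectrumImage:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FormatError("missing meta.json")
    meta = json.loads(meta_path.read_text())
    for key in _META_KEYS:
        if key not in meta:
            raise FormatError(f"meta.json: missing field {key!r}")
    topo_path = path / "topography.csv"
    if not topo_path.exists():
        raise FormatError("missing topography.csv")
    topo = np.loadtxt(topo_path, delimiter=",", ndmin=2)
    flags = meta.get("flags", {})
    heights = meta.get("contact_heights", {})
    curves: Dict[Tuple[int, int], ForceCurve] = {}
    cdir = path / "curves"
    if cdir.is_dir():
        for tsv in sorted(cdir.glob("*.tsv")):
            name = tsv.stem
            try:
                iy, ix = (int(v) for v in name.split("_"))
            except ValueError as e:
                raise FormatError(f"malformed curve file name {tsv.name!r}") from e
            with open(tsv) as fh:
                header = fh.readline().strip()
            if header.split("\t") != ["d_m", "f_N"]:
                raise FormatError(f"curve {tsv.name}: expected header 'd_m\\tf_N', got {header!r}")
            arr = np.loadtxt(tsv, delimiter="\t", skiprows=1, ndmin=2)
            curves[(iy, ix)] = ForceCurve(
                d=arr[:, 0], f=arr[:, 1],
                contact_height=float(heights.get(name, 0.0)),
                pixel=(ix, iy), flag=flags.get(name),
            )
    return SpectrumImage(
        nx=int(meta["nx"]), ny=int(meta["ny"]),
        pixel_pitch=float(meta["pixel_pitch_m"]),
        spring_constant=float(meta["spring_constant_N_per_m"]),
        force_threshold=float(meta["force_threshold_N"]),
        topography=topo, curves=curves, scan_axis=str(meta["scan_axis"]),
    )


# ------------------------------------------------------------------ public API

def read_force_volume(path, format: str = "hdf5") -> SpectrumImage:
    """Read a force-volume container; see module docstring for the layouts.

    Raises :class:`FormatError` naming the first offending field on any
    layout violation, and ``FileNotFoundError`` if the path does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "hdf5":
        return _read_hdf5(path)
    if format == "tsv_dir":
        return _read_tsv_dir(path)
    raise ValueError(f"unknown format {format!r}; expected 'hdf5' or 'tsv_dir'")


def write_force_volume(img: SpectrumImage, path, format: str = "hdf5",
                       overwrite: bool = False):
    """Write ``img``; refuses to clobber an existing path unless ``overwrite``."""
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace")
    if format == "hdf5":
        _write_hdf5(img, path)
    elif format == "tsv_dir":
        _write_tsv_dir(img, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'hdf5' or 'tsv_dir'")
    return path


def export_map(scalar_map, path, format: str = "csv"):
    """Export a 2D physical-quantity map.

    ``scalar_map`` is any object with ``values`` (2D array), ``units`` (str)
    and optional ``mask`` (True = invalid) — i.e. a ``mapping.ScalarMap``.
    Formats: ``csv`` (row-major, ``# units=<u>`` header, masked cells NaN),
    ``tiff32`` (32-bit float TIFF, masked NaN), ``png_preview`` (diverging
    palette: tensile red, compressive green).
    """
    values = np.asarray(scalar_map.values, dtype=float)
    units = getattr(scalar_map, "units", None)
    if not units:
        raise ValueError("map has no units; refusing to export unitless data")
    mask = getattr(scalar_map, "mask", None)
    if mask is not None:
        values = np.where(np.asarray(mask, dtype=bool), np.nan, values)
    path = Path(path)
    if format == "csv":
        np.savetxt(path, values, delimiter=",", fmt="%.17g",
                   header=f"units={units}", comments="# ")
    elif format == "tiff32":
        import tifffile
        tifffile.imwrite(path, values.astype(np.float32))
    elif format == "png_preview":
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        vmax = np.nanmax(np.abs(values)) or 1.0
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(values, cmap="RdYlGn_r", vmin=-vmax, vmax=vmax,
                       origin="lower", interpolation="nearest")
        fig.colorbar(im, ax=ax, label=units)
        ax.set_xlabel("ix")
        ax.set_ylabel("iy")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
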