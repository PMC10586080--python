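"""End-to-end workflows: simulate, calibrate-and-map, profile.

These functions wire the modules into the three recurring analyses —
generating a virtual force volume, running the MCMC tip calibration with
model ranking and map export, and condensing maps/series into profiles.
They are the scripting surface of the package (see ``examples/``); every
output is a text artifact (CSV/JSON) and a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Sequence

import pandas as pd

from .contact_models import MODELS, ModelConfig, TipDescriptors
from .fitting import fit_map
from .io_formats import export_map, read_force_volume, write_force_volume
from .mapping import build_maps, depth_windowed_maps, linescan_stats, radial_profile
from .mcmc import McmcConfig, compare_models, mcmc_optimize
from .synthetic import (AcquisitionConfig, PhantomSpec, make_phantom,
                        simulate_spectrum_image)

__all__ = ["RunConfig", "run_simulate", "run_fit", "run_profile"]

_CSV_FLOAT = "%.12g"


@dataclass
class RunConfig:
    """One validated bag of settings for a workflow run.

    The full config is echoed as ``config.json`` into the output directory
    so any result can be traced to the settings that produced it.
    """

    out_dir: str = "."
    input_path: Optional[str] = None
    input_format: str = "hdf5"
    seed: int = 0
    # models & physics
    models: Sequence[str] = ("hs",)
    poisson_ratio: float = 0.5
    r_cell: Optional[float] = 8e-6
    nominal_tip_radius: float = 50e-9
    nominal_half_angle: float = 0.35   # rad, conical init
    # fitting / MCMC
    objective: str = "variance"
    mcmc_iters: int = 1000
    test_fraction: float = 0.125
    depth_windows: Sequence[float] = ()
    # simulation
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    # profiling
    profile_center: Optional[Sequence[float]] = None  # pixel (ix, iy)
    profile_r_max: Optional[float] = None
    profile_n_bins: int = 32
    profile_normalize: bool = True
    linescan_window_width: float = 5e-6

    def validate(self) -> "RunConfig":
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")
        if not (0 < self.test_fraction < 0.5):
            raise ValueError("test_fraction must be in (0, 0.5)")
        if self.mcmc_iters < 1:
            raise ValueError("mcmc_iters must be >= 1")
        if self.objective not in ("variance", "sum"):
            raise ValueError("objective must be 'variance' or 'sum'")
        if list(self.depth_windows) != sorted(set(self.depth_windows)):
            raise ValueError("depth_windows must be strictly ascending")
        return self

    def to_json(self) -> str:
        d = asdict(self)
        d["models"] = list(self.models)
        d["depth_windows"] = list(self.depth_windows)
        if self.profile_center is not None:
            d["profile_center"] = list(self.profile_center)
        return json.dumps(d, indent=1, sort_keys=True, default=float)


def _prepare_out(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(cfg.to_json())
    return out


def _init_td(cfg: RunConfig, model: str) -> TipDescriptors:
    if model == "sneddon":
        return TipDescriptors(cfg.nominal_half_angle)
    return TipDescriptors(cfg.nominal_tip_radius)


def _model_cfg(cfg: RunConfig, model: str) -> ModelConfig:
    return ModelConfig(model=model, poisson_ratio=cfg.poisson_ratio,
                       r_cell=cfg.r_cell if model == "cslc" else None)


def run_simulate(cfg: RunConfig) -> Dict[str, Path]:
    """Generate a phantom force volume; write container + ground-truth sidecar."""
    cfg.validate()
    out = _prepare_out(cfg)
    ph = make_phantom(cfg.phantom, seed=cfg.seed)
    acq = AcquisitionConfig(**{**asdict(cfg.acquisition), "seed": cfg.seed})
    img, gt = simulate_spectrum_image(ph, acq)
    container = out / "force_volume.h5"
    write_force_volume(img, container, format="hdf5", overwrite=True)
    sidecar = out / "ground_truth.json"
    sidecar.write_text(gt.to_json())
    return {"container": container, "ground_truth": sidecar}


def run_fit(cfg: RunConfig) -> Dict[str, Path]:
    """Calibrate descriptors per model, rank models, export best-model maps.

    Writes ``model_ranking.csv``, per-model ``trace_<model>.csv``, the best
    model's stress/modulus/topography CSV maps, and depth-windowed map CSVs
    when ``depth_windows`` is set.
    """
    cfg.validate()
    if cfg.input_path is None:
        raise ValueError("run_fit needs input_path (a force-volume container)")
    out = _prepare_out(cfg)
    img = read_force_volume(cfg.input_path, format=cfg.input_format)

    mcfg = McmcConfig(n_iter=cfg.mcmc_iters, seed=cfg.seed, objective=cfg.objective)
    configs = [_model_cfg(cfg, m) for m in cfg.models]
    inits = {m: _init_td(cfg, m) for m in cfg.models}
    ranking = compare_models(img, configs, inits, mcfg,
                             fraction_test=cfg.test_fraction, seed=cfg.seed)
    paths = {"ranking": out / "model_ranking.csv"}
    ranking.to_csv(paths["ranking"], index=False, float_format=_CSV_FLOAT)

    best_model = ranking.loc[0, "model"]
    best_cfg = _model_cfg(cfg, best_model)
    trace = mcmc_optimize(img, best_cfg, inits[best_model], mcfg)
    paths["trace"] = out / f"trace_{best_model}.csv"
    trace.to_dataframe().to_csv(paths["trace"], index=False, float_format=_CSV_FLOAT)

    fit = fit_map(img, best_cfg, trace.best_td, objective=cfg.objective)
    maps = build_maps(fit, img)
    for name, m in maps.items():
        p = out / f"map_{name}.csv"
        export_map(m, p, format="csv")
        paths[f"map_{name}"] = p

    for w, maps_w in zip(cfg.depth_windows,
                         depth_windowed_maps(img, trace.best_td, best_cfg,
                                             cfg.depth_windows, cfg.objective)
                         if cfg.depth_windows else []):
        for name, m in maps_w.items():
            if name == "topography":
                continue
            p = out / f"map_{name}_d{int(round(w * 1e9))}nm.csv"
            export_map(m, p, format="csv")
            paths[f"map_{name}_{int(round(w * 1e9))}nm"] = p

    report = {
        "best_model": str(best_model),
        "best_objective": float(trace.best_objective),
        "best_iteration": int(trace.best_iteration),
        "best_td": dict(zip("rabc", trace.best_td.as_array().tolist())),
        "prediction_error_N": float(ranking.loc[0, "prediction_error_N"]),
        "frac_flagged": float(fit.frac_flagged),
    }
    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report, indent=1, sort_keys=True))
    return paths


def run_profile(cfg: RunConfig, scalar_map=None, series=None) -> Dict[str, Path]:
    """Condense a map to a radial profile and/or a line-scan series to
    central-window time statistics; write CSVs."""
    cfg.validate()
    out = _prepare_out(cfg)
    paths: Dict[str, Path] = {}
    if scalar_map is not None:
        ny, nx = scalar_map.values.shape
        center = tuple(cfg.profile_center) if cfg.profile_center is not None \
            else ((nx - 1) / 2, (ny - 1) / 2)
        r_max = cfg.profile_r_max if cfg.profile_r_max is not None \
            else min(nx, ny) / 2 * scalar_map.pixel_pitch
        prof = radial_profile(scalar_map, center, r_max,
                              n_bins=cfg.profile_n_bins,
                              normalize=cfg.profile_normalize)
        df = pd.DataFrame({"r_m": prof.bin_centers, "mean": prof.mean,
                           "count": prof.counts})
        paths["radial_profile"] = out / "radial_profile.csv"
        df.to_csv(paths["radial_profile"], index=False, float_format=_CSV_FLOAT)
    if series is not None:
        stress_t, height_t = linescan_stats(
            series, window_width=cfg.linescan_window_width)
        df = pd.DataFrame({"time_s": series.times,
                           "mean_stress_Pa": stress_t, "height_m": height_t})
        paths["linescan_stats"] = out / "linescan_stats.csv"
        df.to_csv(paths["linescan_stats"], index=False, float_format=_CSV_FLOAT)
    if not paths:
        raise ValueError("run_profile needs a scalar_map and/or a series")
    return paths
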