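"""Markov-chain Monte Carlo calibration of the tip-shape descriptors.

The tip descriptors ``(r, a, b, c)`` (base radius / half-angle, gradient
couplings, depth coupling) cannot be measured directly on a live-cell scan;
they are found by minimizing the map-wide objective — by default the
*variance* of per-pixel fitting errors, which is small only when no residual
misfit tracks location (i.e. topography).  The chain is a Metropolis
minimizer, not a posterior sampler: Gaussian proposals per parameter,
acceptance ``min(1, exp(-(L' - L)/Tmp))`` with the temperature set from the
initial objective scale and annealed linearly to 10% of it, and the
best-so-far descriptors are what the caller uses.  1000 iterations is the
default search length.

Model selection runs this calibration independently per model on the
training 7/8 of the samples and ranks models by held-out prediction error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .contact_models import ModelConfig, PixelContext, TipDescriptors
from .curve_processing import topography_gradients
from .fitting import (PackedCurves, map_objective, pack_curves,
                      prediction_error, split_train_test)
from .io_formats import SpectrumImage

__all__ = ["McmcConfig", "McmcTrace", "mcmc_optimize", "compare_models"]

_PARAMS = ("r", "a", "b", "c")

#: default starting temperature as a fraction of the initial objective.  The
#: objective basin around the true descriptors is shallow (relative depth
#: ~1e-3 at realistic noise), so the chain is run cold — descent-dominated
#: with just enough acceptance of uphill moves to hop local roughness.
TEMPERATURE_FRACTION = 1e-3


@dataclass
class McmcConfig:
    """Search settings.

    Proposal scales default to 5% of |init| with absolute floors (1 nm for
    r, 1e-3 for a, b, c in their own units); bounds keep the geometry
    physical: r in (0, 10 um], a, b in [-5 um, 5 um] per unit slope, c in
    [-10, 10].  For the conical model the same slots are radians
    (theta0 in (0.01, 1.55), a, b in [-1, 1] rad, c in [-2e6, 2e6] rad/m).
    """

    n_iter: int = 1000
    seed: int = 0
    objective: str = "variance"
    proposal_scales: Optional[Sequence[float]] = None
    bounds: Optional[Sequence[tuple]] = None
    temperature: Optional[float] = None  # default: TEMPERATURE_FRACTION x L_init
    anneal_floor: float = 0.1

    def __post_init__(self):
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if self.objective not in ("variance", "sum"):
            raise ValueError("objective must be 'variance' or 'sum'")
        if self.proposal_scales is not None and np.any(np.asarray(self.proposal_scales) <= 0):
            raise ValueError("proposal scales must be > 0")

    def resolved_scales(self, init: TipDescriptors, model: str) -> np.ndarray:
        if self.proposal_scales is not None:
            return np.asarray(self.proposal_scales, dtype=float)
        x = np.abs(init.as_array())
        if model == "sneddon":
            floors = np.array([5e-3, 2e-3, 2e-3, 1e3])
        else:
            floors = np.array([1e-9, 1e-3 * 1e-6, 1e-3 * 1e-6, 1e-3])
        return np.maximum(0.05 * x, floors)

    def resolved_bounds(self, model: str) -> List[tuple]:
        if self.bounds is not None:
            return list(self.bounds)
        if model == "sneddon":
            return [(1e-2, 1.55), (-1.0, 1.0), (-1.0, 1.0), (-2e6, 2e6)]
        return [(1e-12, 10e-6), (-5e-6, 5e-6), (-5e-6, 5e-6), (-10.0, 10.0)]


@dataclass
class McmcTrace:
    """Full iteration history of one search."""

    params: np.ndarray        # (n_iter, 4) proposed-or-kept state per iteration
    objective: np.ndarray     # (n_iter,)
    accepted: np.ndarray      # (n_iter,) bool
    best_td: TipDescriptors = None
    best_objective: float = np.inf
    best_iteration: int = -1
    model: str = "hs"

    def __len__(self) -> int:
        return self.objective.size

    def best_so_far(self) -> np.ndarray:
        """Running minimum of the objective (non-increasing by construction)."""
        return np.minimum.accumulate(self.objective)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.params, columns=list(_PARAMS))
        df.insert(0, "iteration", np.arange(len(self)))
        df["objective"] = self.objective
        df["accepted"] = self.accepted.astype(int)
        return df


def mcmc_optimize(img: SpectrumImage, cfg: ModelConfig, init_td: TipDescriptors,
                  mcmc: McmcConfig, ctx: Optional[PixelContext] = None,
                  packed: Optional[PackedCurves] = None,
                  sample_mask: Optional[np.ndarray] = None) -> McmcTrace:
    """Annealed Metropolis minimization of the map objective over (r, a, b, c).

    Exactly reproducible from (seed, config, data).  ``sample_mask``
    restricts the objective to a sample subset (the training split during
    model selection).  Raises if no iteration ever evaluates finite —
    usually a sign the initial descriptors or bounds are nonphysical.
    """
    if ctx is None:
        ctx = topography_gradients(img)
    if packed is None:
        packed = pack_curves(img)
    rng = np.random.default_rng(mcmc.seed)
    scales = mcmc.resolved_scales(init_td, cfg.model)
    bounds = mcmc.resolved_bounds(cfg.model)

    def L(x: np.ndarray) -> float:
        for v, (lo, hi) in zip(x, bounds):
            if not (lo <= v <= hi):
                return np.inf
        return map_objective(packed, ctx, cfg, TipDescriptors.from_array(x),
                             objective=mcmc.objective, sample_mask=sample_mask)

    x = init_td.as_array()
    Lx = L(x)
    T0 = mcmc.temperature if mcmc.temperature is not None else \
        (TEMPERATURE_FRACTION * Lx if np.isfinite(Lx) and Lx > 0 else 1.0)

    n = mcmc.n_iter
    params = np.empty((n, 4))
    objs = np.empty(n)
    acc = np.zeros(n, dtype=bool)
    best_x, best_L, best_i = x.copy(), Lx, -1

    for i in range(n):
        frac = i / max(n - 1, 1)
        temp = T0 * (1.0 - (1.0 - mcmc.anneal_floor) * frac)
        prop = x + rng.normal(0.0, scales)
        Lp = L(prop)
        if np.isfinite(Lp) and (Lp <= Lx or (np.isfinite(Lx) and temp > 0 and
                                             rng.random() < np.exp(-(Lp - Lx) / temp))):
            x, Lx = prop, Lp
            acc[i] = True
        elif not np.isfinite(Lx) and np.isfinite(Lp):
            x, Lx = prop, Lp
            acc[i] = True
        params[i] = x
        objs[i] = Lx
        if Lx < best_L:
            best_x, best_L, best_i = x.copy(), Lx, i

    if not np.isfinite(best_L):
        raise RuntimeError(
            "MCMC never reached a finite objective; revise init descriptors or bounds")
    return McmcTrace(params=params, objective=objs, accepted=acc,
                     best_td=TipDescriptors.from_array(best_x),
                     best_objective=float(best_L), best_iteration=int(best_i),
                     model=cfg.model)


def compare_models(img: SpectrumImage, configs: Sequence[ModelConfig],
                   init_tds: Dict[str, TipDescriptors], mcmc: McmcConfig,
                   fraction_test: float = 0.125,
                   seed: Optional[int] = None) -> pd.DataFrame:
    """Calibrate each model on the training 7/8, rank by test prediction error.

    Returns a DataFrame sorted ascending by ``prediction_error_N`` with the
    best descriptors and trace summaries per model; a model that fails
    outright ranks last with its error message in ``failure``.
    """
    if len(configs) < 1:
        raise ValueError("need at least one model config")
    seed = mcmc.seed if seed is None else seed
    ctx = topography_gradients(img)
    packed = pack_curves(img)
    test_mask = split_train_test(packed, fraction_test=fraction_test, seed=seed)

    rows = []
    for cfg in configs:
        row = {"model": cfg.model, "failure": ""}
        try:
            trace = mcmc_optimize(img, cfg, init_tds[cfg.model], mcmc,
                                  ctx=ctx, packed=packed, sample_mask=~test_mask)
            pe = prediction_error(packed, ctx, cfg, trace.best_td, test_mask)
            row.update(prediction_error_N=pe.rms, n_test=pe.n_test,
                       best_objective=trace.best_objective,
                       best_iteration=trace.best_iteration,
                       acceptance_rate=float(trace.accepted.mean()),
                       **{f"td_{p}": v for p, v in
                          zip(_PARAMS, trace.best_td.as_array())})
        except Exception as e:  # ranked last, reason reported
            row.update(prediction_error_N=np.inf, failure=str(e))
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("prediction_error_N", kind="stable")
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df.reset_index(drop=True)
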