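"""Model-assisted TELISA inference: RMSE fitting, calibration, quantification, LOD.

The protocol is two-stage, mirroring how the platform is operated:

1. *Calibrate* — with a known label-enzyme amount Ea, sweep the forward
   model over a (kcat, InF) grid and take the RMSE-minimizing node; this
   absorbs day-to-day enzyme-activity and platform drift.
2. *Quantify* — with the calibrated (kcat, InF) fixed, sweep Ea over a
   1D grid against each unknown trace and take the RMSE argmin.

The limit of detection is extrapolated from replicate determinations:
the average per-level standard deviation of the estimated amounts is
intersected with the fitted mean-response line; the x-value where the
(mean line - average SD) crosses zero is the smallest amount whose
signal rises above the replicate spread.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError
from .reaction_transport import KineticParams
from .thermal_readout import ForwardModel, SignalTrace

__all__ = [
    "FitSurface",
    "CalibrationResult",
    "QuantResult",
    "LODResult",
    "rmse",
    "calibrate",
    "quantify",
    "estimate_lod",
    "default_kcat_grid",
    "default_inf_grid",
    "default_ea_grid",
]

DEFAULT_MASK_START = 0.1  # s; excludes the ~100 ms capillary-filling artifact


def default_kcat_grid(n: int = 15) -> np.ndarray:
    """Log-spaced turnover-rate grid, 1/s."""
    return np.geomspace(1e4, 1e6, n)


def default_inf_grid(n: int = 13) -> np.ndarray:
    """Log-spaced inactivation-factor grid."""
    return np.geomspace(0.5, 32.0, n)


def default_ea_grid(n: int = 25) -> np.ndarray:
    """Log-spaced enzyme-amount grid, mol (0.05-5 fmol)."""
    return np.geomspace(0.05e-15, 5e-15, n)


@dataclass
class FitSurface:
    """RMSE (V) evaluated on an ordered parameter grid."""

    axes: dict[str, np.ndarray]
    values: np.ndarray

    def __post_init__(self):
        shape = tuple(len(v) for v in self.axes.values())
        if self.values.shape != shape:
            raise DataError("fit surface shape does not match its axes")
        if np.any(self.values < 0):
            raise DataError("RMSE must be non-negative")

    def argmin(self) -> tuple[int, ...]:
        """Grid index of the minimum; ties resolve to the smallest
        parameter values (first occurrence in ascending-grid order)."""
        return np.unravel_index(int(np.argmin(self.values)), self.values.shape)

    def on_boundary(self, idx: tuple[int, ...]) -> bool:
        return any(i == 0 or i == self.values.shape[d] - 1
                   for d, i in enumerate(idx))


@dataclass
class CalibrationResult:
    """Best-fit (kcat, InF) at known enzyme amount, plus the full surface."""

    kcat_hat: float
    InF_hat: float
    rmse_min: float
    surface: FitSurface
    Ea_known: float
    boundary_hit: bool


@dataclass
class QuantResult:
    """Best-fit enzyme amount at fixed calibrated kinetics."""

    Ea_hat: float
    rmse_min: float
    surface: FitSurface
    kcat: float
    InF: float
    boundary_hit: bool


@dataclass
class LODResult:
    """Replicate-spread LOD extrapolation.

    ``slope``/``intercept`` define the ordinary-least-squares fit of the
    per-level mean determination against the true amount; ``lod`` is the
    x-intercept of (mean line - average SD), clipped at zero.
    """

    levels: np.ndarray  # true amounts, mol
    level_means: np.ndarray
    level_sds: np.ndarray
    avg_sd: float
    slope: float
    intercept: float
    lod: float


def rmse(y: SignalTrace, y_prime: SignalTrace,
         mask_start: float = DEFAULT_MASK_START) -> float:
    """Root-mean-square residual (V) over samples with t >= mask_start.

    The mask excludes the capillary-filling artifact window; traces must
    already share sampling (same Δt and length).
    """
    if len(y.times) != len(y_prime.times):
        raise DataError("traces must share length; resample before rmse")
    if abs(y.dt - y_prime.dt) > 1e-9 * y.dt:
        raise DataError("traces must share the sampling interval")
    if mask_start < 0:
        raise ValueError("mask_start must be >= 0")
    keep = y.times >= mask_start - 1e-12
    n = int(keep.sum())
    if n == 0:
        raise DataError("mask removed every sample")
    r = y.voltage[keep] - y_prime.voltage[keep]
    return float(np.sqrt(np.mean(r * r)))


def _model_trace(fm: ForwardModel, kin: KineticParams, S0: float) -> SignalTrace:
    return fm.run(kin, S0).signal


def calibrate(
    signal: SignalTrace,
    Ea_known: float,
    kcat_grid: Sequence[float],
    InF_grid: Sequence[float],
    fm: ForwardModel,
    S0: float,
    base: KineticParams | None = None,
    mask_start: float = DEFAULT_MASK_START,
    refine: bool = False,
) -> CalibrationResult:
    """Grid-search (kcat, InF) against one known-amount trace.

    ``base`` supplies Km, dH and t_start (platform constants); Ea is held
    at the known amount. ``refine=True`` adds one local pass shrinking
    each range 4x around the argmin (same node counts).
    """
    kcat_grid = np.asarray(kcat_grid, dtype=float)
    InF_grid = np.asarray(InF_grid, dtype=float)
    if kcat_grid.size == 0 or InF_grid.size == 0:
        raise ValueError("parameter grids must be non-empty")
    if not Ea_known > 0:
        raise ValueError("Ea_known must be > 0")
    base = base if base is not None else KineticParams(Ea=Ea_known, kcat=1.0)

    def sweep(kcats, infs):
        vals = np.empty((len(kcats), len(infs)))
        for i, kc in enumerate(kcats):
            for j, inf_ in enumerate(infs):
                kin = replace(base, Ea=Ea_known, kcat=float(kc), InF=float(inf_))
                vals[i, j] = rmse(signal, _model_trace(fm, kin, S0), mask_start)
        return FitSurface(axes={"kcat": kcats, "InF": infs}, values=vals)

    surface = sweep(kcat_grid, InF_grid)
    i, j = surface.argmin()
    if refine:
        kc_f = _shrunk_grid(kcat_grid, i, len(kcat_grid))
        in_f = _shrunk_grid(InF_grid, j, len(InF_grid))
        surface = sweep(kc_f, in_f)
        i, j = surface.argmin()
    boundary = surface.on_boundary((i, j))
    if boundary:
        warnings.warn("calibration argmin on the grid boundary; widen the "
                      "search ranges", stacklevel=2)
    return CalibrationResult(
        kcat_hat=float(surface.axes["kcat"][i]),
        InF_hat=float(surface.axes["InF"][j]),
        rmse_min=float(surface.values[i, j]),
        surface=surface, Ea_known=Ea_known, boundary_hit=boundary,
    )


def _shrunk_grid(grid: np.ndarray, idx: int, n: int) -> np.ndarray:
    """Log-spaced grid spanning 1/4 of the original range around node idx."""
    lo, hi = math.log(grid[0]), math.log(grid[-1])
    span = (hi - lo) / 4.0
    c = math.log(grid[idx])
    a = max(lo, c - span / 2)
    b = min(hi, c + span / 2)
    if b <= a:
        return np.array([grid[idx]])
    return np.exp(np.linspace(a, b, n))


def quantify(
    signal: SignalTrace,
    kcat: float,
    InF: float,
    Ea_grid: Sequence[float],
    fm: ForwardModel,
    S0: float,
    base: KineticParams | None = None,
    mask_start: float = DEFAULT_MASK_START,
) -> QuantResult:
    """1D RMSE minimization over the enzyme amount at fixed kinetics."""
    Ea_grid = np.asarray(Ea_grid, dtype=float)
    if Ea_grid.size == 0:
        raise ValueError("Ea grid must be non-empty")
    if np.any(Ea_grid < 0):
        raise ValueError("Ea grid must be non-negative")
    base = base if base is not None else KineticParams(Ea=0.0, kcat=kcat)
    vals = np.empty(len(Ea_grid))
    for i, ea in enumerate(Ea_grid):
        kin = replace(base, Ea=float(ea), kcat=float(kcat), InF=float(InF))
        vals[i] = rmse(signal, _model_trace(fm, kin, S0), mask_start)
    surface = FitSurface(axes={"Ea": Ea_grid}, values=vals)
    (i,) = surface.argmin()
    boundary = surface.on_boundary((i,))
    if boundary:
        warnings.warn("Ea argmin on the grid boundary; widen the range",
                      stacklevel=2)
    return QuantResult(Ea_hat=float(Ea_grid[i]), rmse_min=float(vals[i]),
                       surface=surface, kcat=kcat, InF=InF,
                       boundary_hit=boundary)


def estimate_lod(determinations: Mapping[float, Sequence[float]]) -> LODResult:
    """Extrapolate the limit of detection from replicate determinations.

    ``determinations`` maps each true amount (mol) to the replicate
    estimates at that level (>= 2 levels, >= 2 replicates each). The LOD
    is the amount where the fitted mean-response line, lowered by the
    average per-level SD, crosses zero — i.e. where the determined signal
    is no longer distinguishable from the replicate spread.

    Invariant to the ordering of levels and replicates; scales linearly
    with the per-level SDs when the mean response is the identity.
    """
    items = sorted(determinations.items())
    if len(items) < 2:
        raise ValueError("need at least two amount levels")
    levels = np.array([lv for lv, _ in items], dtype=float)
    if np.unique(levels).size < 2:
        raise ValueError("degenerate fit: all levels equal")
    means, sds = [], []
    for lv, ests in items:
        ests = np.asarray(list(ests), dtype=float)
        if ests.size < 2:
            raise ValueError("need >= 2 replicates per level")
        means.append(ests.mean())
        sds.append(ests.std(ddof=1))
    means = np.array(means)
    sds = np.array(sds)
    slope, intercept = np.polyfit(levels, means, 1)
    if not slope > 0:
        raise ValueError("degenerate fit: non-increasing mean response")
    avg_sd = float(sds.mean())
    lod = max(0.0, (avg_sd - intercept) / slope)
    return LODResult(levels=levels, level_means=means, level_sds=sds,
                     avg_sd=avg_sd, slope=float(slope),
                     intercept=float(intercept), lod=float(lod))
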