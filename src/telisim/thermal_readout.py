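"""Transient heat conduction through the platform and thermopile readout.

The reaction heat is deposited uniformly in the reaction-zone cells and
conducts through the liquid, membranes, walls and silicon frame:

    rho*cp * dT/dt = div(k grad T) + q(x, t)

with the exterior faces held at ambient (the frame acts as the heat
sink) or optionally coupled through a linearized film coefficient.
Radiative/convective losses at these scales are dwarfed by conduction
into the frame, so the film is off by default. The liquid is stationary
(capillary filling has finished before the reaction starts).

The thermopile reports the volume-averaged sensing-junction temperature
minus the reference-junction temperature, times the total Seebeck
coefficient (27 Bi/Ti pairs x 78 uV/K by default).

Because the thermal stage is linear and time-invariant, the full forward
map (kinetics -> voltage) can be evaluated through precomputed response
kernels of the same discrete operators; :class:`ForwardModel` does this
and is algebraically identical to running the two steppers directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

from ._fv import assemble_diffusion
from .core_model import (
    GridResolution,
    RegionMap,
    SimulationGrid,
    build_geometry,
    build_grid,
)
from .errors import DataError, SolverError
from .reaction_transport import (
    KineticParams,
    PowerTrace,
    ReactionTrace,
    TransportSystem,
    _mm_step,
    active_enzyme,
    heat_source_series,
    simulate_reaction_diffusion,
)
from .units import v_to_uv

__all__ = [
    "ThermopileSpec",
    "ThermalTrace",
    "SignalTrace",
    "simulate_thermal",
    "steady_state_dT",
    "to_voltage",
    "ForwardModel",
    "ForwardResult",
    "forward_model",
]

AMBIENT_DEFAULT = 293.15  # K


@dataclass(frozen=True)
class ThermopileSpec:
    """Differential Bi/Ti thermopile readout.

    The per-pair Seebeck coefficient defaults to 78 uV/K (bulk Bi/Ti
    literature value; the platform's calibrated value is configurable).
    """

    n_junctions: int = 27
    seebeck_per_pair: float = 78e-6  # V/K

    def __post_init__(self):
        if self.n_junctions < 1:
            raise ValueError("n_junctions must be >= 1")
        if self.seebeck_per_pair <= 0:
            raise ValueError("seebeck_per_pair must be > 0")

    @property
    def total_seebeck(self) -> float:
        """Total sensitivity, V/K."""
        return self.n_junctions * self.seebeck_per_pair


@dataclass
class ThermalTrace:
    """Region-averaged temperatures (K) of the two junction sets."""

    times: np.ndarray
    T_sense: np.ndarray
    T_ref: np.ndarray
    ambient: float = AMBIENT_DEFAULT

    def __post_init__(self):
        if not (len(self.times) == len(self.T_sense) == len(self.T_ref)):
            raise DataError("thermal trace arrays must share one length")

    @property
    def dT(self) -> np.ndarray:
        """Sensing minus reference temperature, K."""
        return self.T_sense - self.T_ref


@dataclass
class SignalTrace:
    """Uniformly sampled thermopile output; voltage in volts (uV at I/O)."""

    times: np.ndarray
    voltage: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if len(self.times) != len(self.voltage):
            raise DataError("times and voltage must share one length")
        if len(self.times) < 2:
            raise DataError("a signal trace needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(np.abs(steps - steps[0]) > 0.01 * steps[0]):
            raise DataError("times must be uniformly spaced (within 1%)")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def peak(self) -> float:
        """Maximum voltage, V."""
        return float(self.voltage.max())

    def peak_uv(self) -> float:
        return v_to_uv(self.peak())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "voltage_uV": self.voltage / 1e-6}
        )


class _ThermalSystem:
    """Factorized implicit stepper for the conduction problem."""

    def __init__(self, grid: SimulationGrid, dt: float, boundary: str,
                 film_h: float | None):
        if boundary not in ("dirichlet", "adiabatic"):
            raise SolverError(f"unknown boundary model '{boundary}'")
        self.dt = dt
        vols = grid.volumes()
        self.cap = (grid.rho * grid.cp * vols).ravel()  # J/K per cell
        bkind = "dirichlet" if boundary == "dirichlet" else "neumann"
        L = assemble_diffusion(grid.dx, grid.dy, grid.dz, grid.k,
                               boundary=bkind, film_h=film_h)
        M = sp.diags(self.cap) - dt * L
        self._lu = splu(M.tocsc())
        self.L = L
        rz = grid.mask("reaction_zone").ravel()
        if rz.sum() == 0:
            raise SolverError("grid has no reaction-zone cells")
        w = vols.ravel()[rz]
        self.q_vec = np.zeros(self.cap.size)
        self.q_vec[rz] = w / w.sum()  # W per W of total power
        vflat = vols.ravel()
        self._sense = grid.mask("sensing_junctions").ravel()
        self._ref = grid.mask("reference_junctions").ravel()
        self._w_sense = vflat[self._sense] / vflat[self._sense].sum()
        self._w_ref = vflat[self._ref] / vflat[self._ref].sum()

    def step(self, theta: np.ndarray, P: float) -> np.ndarray:
        rhs = self.cap * theta + self.dt * self.q_vec * P
        out = self._lu.solve(rhs)
        if not np.all(np.isfinite(out)):
            raise SolverError("thermal solve produced non-finite temperatures")
        return out

    def readout(self, theta: np.ndarray) -> tuple[float, float]:
        return (float(self._w_sense @ theta[self._sense]),
                float(self._w_ref @ theta[self._ref]))


def simulate_thermal(
    grid: SimulationGrid,
    power: PowerTrace,
    ambient_T: float = AMBIENT_DEFAULT,
    boundary: str = "dirichlet",
    film_h: float | None = None,
) -> ThermalTrace:
    """Propagate the reaction heat and record the junction temperatures.

    ``boundary="dirichlet"`` holds the exterior faces at ``ambient_T``;
    ``boundary="adiabatic"`` insulates them (used for energy-accounting
    checks). The power trace is piecewise constant over each step.
    """
    dt = power.dt
    sys_ = _ThermalSystem(grid, dt, boundary, film_h)
    n = len(power.times)
    theta = np.zeros(sys_.cap.size)
    T_s = np.zeros(n)
    T_r = np.zeros(n)
    for i in range(1, n):
        theta = sys_.step(theta, float(power.power[i]))
        T_s[i], T_r[i] = sys_.readout(theta)
    return ThermalTrace(times=power.times.copy(),
                        T_sense=ambient_T + T_s, T_ref=ambient_T + T_r,
                        ambient=ambient_T)


def steady_state_dT(grid: SimulationGrid, Q: float,
                    film_h: float | None = None) -> float:
    """Stationary sensing-minus-reference ΔT (K) for constant power Q (W).

    Solves -L theta = q with Dirichlet exterior faces; serves as an
    independent oracle for the transient solver's long-time limit.
    """
    L = assemble_diffusion(grid.dx, grid.dy, grid.dz, grid.k,
                           boundary="dirichlet", film_h=film_h)
    vols = grid.volumes().ravel()
    rz = grid.mask("reaction_zone").ravel()
    q = np.zeros(vols.size)
    q[rz] = Q * vols[rz] / vols[rz].sum()
    theta = spsolve((-L).tocsc(), q)
    sense = grid.mask("sensing_junctions").ravel()
    ref = grid.mask("reference_junctions").ravel()
    ws = vols[sense] / vols[sense].sum()
    wr = vols[ref] / vols[ref].sum()
    return float(ws @ theta[sense] - wr @ theta[ref])


def to_voltage(tt: ThermalTrace, tp: ThermopileSpec = ThermopileSpec()
               ) -> SignalTrace:
    """Thermopile output: voltage(t) = total_seebeck * ΔT(t)."""
    return SignalTrace(times=tt.times.copy(),
                       voltage=tp.total_seebeck * tt.dT)


@dataclass
class ForwardResult:
    """Everything the forward map produces for one parameter point."""

    reaction: ReactionTrace
    power: PowerTrace
    dT: np.ndarray  # sensing - reference, K
    signal: SignalTrace


class ForwardModel:
    """The forward map g(Ea, kcat, InF; S0) -> thermopile voltage trace.

    Composition of substrate reaction-diffusion, enthalpy conversion,
    transient conduction and Seebeck readout, sampled at Δt. Both PDE
    stages are linear time-invariant in the quantities the composition
    needs, so the model precomputes, once per grid:

    * a transport response kernel κ_j — the reaction-zone mean of the
      implicit diffusion operator applied j times to a unit reaction-zone
      concentration drop — which turns the zone-mean concentration into
      an exact scalar convolution recursion; and
    * a thermal impulse-response kernel h_j (K per W held for one step)
      for the sensing-minus-reference temperature.

    Evaluating a parameter point then costs one scalar Volterra recursion
    plus one convolution, and reproduces the direct 3D stepping to
    roundoff (``method="direct"`` runs the full solvers for comparison).
    Results are cached per parameter point, which the inference grid
    sweeps rely on.
    """

    def __init__(
        self,
        region_map: RegionMap | None = None,
        resolution: GridResolution | None = None,
        *,
        grid: SimulationGrid | None = None,
        thermopile: ThermopileSpec = ThermopileSpec(),
        dt: float = 0.01,
        t_end: float = 30.0,
        ambient_T: float = AMBIENT_DEFAULT,
        boundary: str = "dirichlet",
        film_h: float | None = None,
    ):
        if grid is None:
            region_map = region_map if region_map is not None else build_geometry()
            grid = build_grid(region_map, resolution)
        self.grid = grid
        self.thermopile = thermopile
        self.dt = float(dt)
        self.t_end = float(t_end)
        self.n_steps = int(round(t_end / dt))
        self.times = np.arange(self.n_steps + 1) * self.dt
        self.ambient_T = ambient_T
        self.boundary = boundary
        self.film_h = film_h
        self._transport: TransportSystem | None = None
        self._kappa: np.ndarray | None = None
        self._h: np.ndarray | None = None
        self._cache: dict = {}

    # -- kernels -----------------------------------------------------------
    def _transport_system(self) -> TransportSystem:
        if self._transport is None:
            self._transport = TransportSystem(self.grid, self.dt)
        return self._transport

    def transport_kernel(self) -> np.ndarray:
        """κ_j: zone-mean remnant of a unit zone concentration drop after
        j diffusion steps (κ_0 = 1, decaying as the drop spreads out)."""
        if self._kappa is None:
            sys_ = self._transport_system()
            u = np.zeros(sys_.n)
            u[sys_.sink_idx] = 1.0
            kappa = np.empty(self.n_steps + 1)
            kappa[0] = 1.0
            for j in range(1, self.n_steps + 1):
                u = sys_.diffuse(u)
                kappa[j] = sys_.sink_mean(u)
            self._kappa = kappa
        return self._kappa

    def thermal_kernel(self) -> np.ndarray:
        """h_j: ΔT response (K) at step j to 1 W deposited during step 1."""
        if self._h is None:
            sys_ = _ThermalSystem(self.grid, self.dt, self.boundary, self.film_h)
            theta = np.zeros(sys_.cap.size)
            h = np.zeros(self.n_steps + 1)
            for j in range(1, self.n_steps + 1):
                theta = sys_.step(theta, 1.0 if j == 1 else 0.0)
                s, r = sys_.readout(theta)
                h[j] = s - r
            self._h = h
        return self._h

    # -- evaluation --------------------------------------------------------
    def run(self, kin: KineticParams, S0: float, *, method: str = "kernel",
            cache: bool = True) -> ForwardResult:
        """Evaluate the forward map at one kinetic parameter point.

        S0 is the initial substrate concentration in mol/m^3 (== mM).
        """
        key = (round(kin.Ea, 25), kin.kcat, kin.Km, kin.InF, kin.dH,
               kin.t_start, S0, method)
        if cache and key in self._cache:
            return self._cache[key]
        if method == "kernel":
            result = self._run_kernel(kin, S0)
        elif method == "direct":
            result = self._run_direct(kin, S0)
        else:
            raise ValueError(f"unknown method '{method}'")
        if cache:
            self._cache[key] = result
        return result

    def _run_kernel(self, kin: KineticParams, S0: float) -> ForwardResult:
        if S0 < 0:
            raise ValueError("S0 must be >= 0")
        sys_ = self._transport_system()
        kappa = self.transport_kernel()
        V_rz = sys_.V_sink
        n = self.n_steps
        dt = self.dt
        deltas = np.zeros(n + 1)  # zone concentration drop applied per step
        consumed = np.zeros(n + 1)
        active = np.full(n + 1, kin.Ea)
        cap = kin.turnover_capacity
        C = 0.0
        for m in range(1, n + 1):
            t_prev = (m - 1) * dt
            dC = 0.0
            if t_prev >= kin.t_start - 1e-12 and kin.Ea > 0:
                # zone mean after this step's diffusion of all past drops
                S_bar = S0 - float(deltas[1:m] @ kappa[m - 1:0:-1])
                S_bar = max(0.0, S_bar)
                E = active_enzyme(kin.Ea, C, kin.InF)
                dC = _mm_step(S_bar, kin.kcat * E, kin.Km, V_rz, dt)
                if math.isfinite(cap):
                    dC = min(dC, max(0.0, cap - C))
                deltas[m] = dC / V_rz
            C += dC
            consumed[m] = C
            active[m] = active_enzyme(kin.Ea, C, kin.InF)
        rate = np.zeros(n + 1)
        rate[1:] = np.diff(consumed) / dt
        total0 = S0 * float(sys_.vol.sum())
        reaction = ReactionTrace(times=self.times.copy(), consumed=consumed,
                                 active=active, rate=rate,
                                 initial_substrate=total0)
        power = heat_source_series(reaction, kin.dH)
        h = self.thermal_kernel()
        dT = np.zeros(n + 1)
        if n >= 1:
            full = np.convolve(power.power[1:], h[1:])
            dT[1:] = full[:n]
        signal = SignalTrace(times=self.times.copy(),
                             voltage=self.thermopile.total_seebeck * dT)
        return ForwardResult(reaction=reaction, power=power, dT=dT,
                             signal=signal)

    def _run_direct(self, kin: KineticParams, S0: float) -> ForwardResult:
        reaction, _ = simulate_reaction_diffusion(
            self.grid, kin, S0, t_end=self.t_end, dt=self.dt)
        power = heat_source_series(reaction, kin.dH)
        tt = simulate_thermal(self.grid, power, ambient_T=self.ambient_T,
                              boundary=self.boundary, film_h=self.film_h)
        signal = to_voltage(tt, self.thermopile)
        return ForwardResult(reaction=reaction, power=power, dT=tt.dT,
                             signal=signal)

    def clear_cache(self) -> None:
        self._cache.clear()


def forward_model(kin: KineticParams, S0: float, config=None, *,
                  fm: ForwardModel | None = None, method: str = "kernel"
                  ) -> SignalTrace:
    """Convenience wrapper: evaluate g(Ea, kcat, InF) -> SignalTrace.

    ``config`` may be a :class:`~telisim.cli_io.RunConfig` (its
    ``build_forward_model`` is used); alternatively pass a prebuilt
    ``fm`` to amortize the kernel computations across calls.
    """
    if fm is None:
        if config is not None and hasattr(config, "build_forward_model"):
            fm = config.build_forward_model()
        else:
            fm = ForwardModel()
    return fm.run(kin, S0, method=method).signal
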