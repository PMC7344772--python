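# Methods

This note documents the model behind `telisim`, the numerical choices,
the defaults that matter, and what the synthetic-data pipeline does and
does not establish.

## Platform model

The simulated domain is a structured, axis-aligned finite-volume grid
(x along the channel length, y across the width, z upward from the
base) containing:

* the **channel liquid** (2355 × 3000 × 50 µm block of water) with the
  cylindrical **reaction zone** (⌀500 µm × 5 µm) at its floor;
* two 1 µm Su-8 **membranes** closing the channel below and above; the
  bottom membrane carries the thermopile: two semicircular composite
  regions (**sensing** and **reference junctions**, ⌀500 µm) and a
  rectangular **track** block between them;
* Su-8 **walls** around the channel footprint, and silicon **lid/base
  slabs** (default 300 µm) that support the membranes *outside* an
  etched window. Inside the window — which spans the channel footprint
  — the slabs are replaced by an air-filled **cavity**, reproducing the
  suspended-membrane construction that thermally isolates the
  calorimeter. Without this cavity the silicon would clamp the membrane
  to ambient and the microvolt-scale signals could not arise.

Curved regions are rasterized by cell-center membership; the channel
footprint is tiled exactly, so the labeled liquid volume is exact and
the rasterized cylinder volume is within ~2.6 % of the analytic value
at the default resolution (converging under refinement). The default
lateral cell size, 62.5 µm, is the coarsest that resolves the reaction
zone with 8 cells across its diameter; the liquid uses 6 vertical
layers (2 across the zone), each slab 3, and the frame margin
(default 1000 µm) uses geometrically stretched cells.

Material defaults (k W/(m·K), ρ kg/m³, c_p J/(kg·K)): water
(0.6, 998, 4182) with H₂O₂ diffusivity D = 1.4 × 10⁻⁹ m²/s; Su-8
(0.2, 1123, 1200); junction composite (0.46, 1268, 1180); track
composite (2.4, 2346, 1034); silicon (130, 2329, 700); air
(0.026, 1.2, 1006). All are configurable per region.

Several dimensions are platform details published only in the device
literature and are exposed as documented defaults: membrane thickness
1 µm, slab thickness 300 µm, sensing–reference center separation
1000 µm (across the channel width, where the paper situates the thermal
gradient), track width 200 µm. The thermopile sensitivity defaults to
27 × 78 µV/K = 2.106 mV/K (bulk Bi/Ti Seebeck values); a measured
device coefficient can be substituted in the config.

## Substrate transport and kinetics

The substrate field obeys ∂S/∂t = D∇²S − r(x,t) on the liquid with
no-flux boundaries and a homogeneous initial concentration S₀. The sink
is the Michaelis–Menten rate evaluated on the volume-averaged zone
concentration S̄ — the zone is treated as one well-mixed reaction
volume — and the reaction starts at t = 0.05 s (the capillary-filling
offset). Active enzyme declines linearly with cumulative consumption,
E = max(0, E_a − C/(InF·10⁷)), i.e. each enzyme survives InF × 10⁷
turnover events; consumption is capped at that capacity so the
consumption trace plateaus exactly when the enzyme is exhausted.

Time integration is operator splitting: an implicit (backward-Euler)
diffusion step — unconditionally stable, exactly mass-conserving, and
positivity-preserving because the system matrix is an M-matrix —
followed by the reaction step integrated **in closed form** over the
step via the Lambert-W solution of the well-mixed Michaelis–Menten ODE.
The closed form removes the stiffness of the sink entirely (the zone
depletes with a ~35 ms time constant at the 1 mM operating point,
faster than the 10 ms sampling), with enzyme activity held at its
start-of-step value (it changes by ≪1 % per step). The removed moles
are distributed over the zone cells by volume; cells that would be
driven below zero are floored and the deficit is redistributed within
the zone, which matters only during deep depletion. Per-step
consumption is reported as the difference of successive whole-channel
substrate integrals, mirroring the instrument's data processing, and
multiplied by ΔH = 98 kJ/mol to form the heat source.

Default sampling is Δt = 10 ms over 30 s (3001 samples); halving Δt
moves the outputs by <2 %, and refining the grid 1.5× laterally and 2×
vertically moves the peak amplitudes by <1 %.

## Thermal readout

ρc_p ∂T/∂t = ∇·(k∇T) + q with the reaction power deposited uniformly
in the zone cells. Exterior faces are held at ambient (293.15 K) —
conduction into the frame dominates at these scales — with an optional
linearized film coefficient; an adiabatic mode supports energy-balance
checks (stored enthalpy matches deposited heat to solver precision).
The liquid is stationary: filling has completed before the reaction
starts, and the model contains no advection and no feedback of
temperature on kinetics. The readout is the volume-averaged junction
temperature difference times the total Seebeck coefficient.

The model's step-response time constant is 0.30–0.32 s, matching the
platform's measured 325 ms without adjustment, and its peak ΔT occurs
near 0.4 s, as observed on the device.

### Kernel evaluation of the forward map

Both PDE stages are linear and time-invariant in the quantities the
composition needs, so `ForwardModel` precomputes two response kernels
per grid: the zone-mean remnant of a unit zone concentration drop after
j diffusion steps, and the junction ΔT response to a unit power step.
A parameter evaluation then reduces to a scalar Volterra recursion for
the zone concentration plus one convolution — milliseconds per node —
while remaining an algebraic rearrangement of the direct 3-D stepping
(the two paths agree to within ~1.5 % of peak, differing only through
the sink flooring above). The direct solvers remain the reference path
and are cross-checked in the tests; grid sweeps additionally cache each
node's trace.

## Inference

RMSE is computed over samples with t ≥ 0.1 s, excluding the ~100 ms
filling artifact (configurable). Calibration sweeps a log-spaced
(k_cat, InF) grid (defaults 15 nodes over 10⁴–10⁶ 1/s and 13 over
0.5–32) at the known enzyme amount; quantification sweeps E_a (25 nodes
over 0.05–5 fmol) at the calibrated kinetics. Ties resolve to the
smallest parameters; an argmin on a grid boundary is flagged and
warned. An optional refinement pass shrinks the ranges 4× around the
argmin.

**Identifiability.** k_cat shapes the whole transient and is recovered
within one grid cell from 0.5 µV-noise traces. *InF* is weakly
identified at realistic operating points: in 30 s an enzyme performs at
most k_cat·t·S₀/(K_m+S₀) ≈ 10⁶ turnovers, far below the InF × 10⁷
survival threshold for InF ≥ 0.5, so the inactivation term perturbs the
trace by ≪ the noise. *InF* must be read as an effective, fitted
parameter; the recovery tests exercise it in an inactivation-dominant
regime (small E_a·InF, enzyme exhausted mid-run) where it is genuinely
identified.

**Limit of detection.** Per level, replicate determinations give a mean
and an SD; an ordinary-least-squares line is fitted to the level means
against the true amounts, and the LOD is the x-intercept of (fitted
line − average SD), clipped at zero — the amount at which the
determined signal no longer rises above the replicate spread. With an
identity mean response this reduces to LOD = average SD exactly, and it
scales linearly with the per-level spread. This is one consistent
geometric reading of "where the average SD intersects the x-axis"; it
is invariant to the ordering of levels and replicates.

## Synthetic traces

`synthetic_data` layers onto the forward signal: a half-sine filling
artifact (default 50 µV over the first 100 ms — only its support
matters, since inference masks the window), white Gaussian noise
(default σ = 0.5 µV, chosen so the synthetic SNR at the
17 µV / 2.5 fmol operating point resembles measured trace roughness),
and optional linear drift. Randomness is counter-based per
(seed, level, replicate), so replicate sets are bit-reproducible.

What passing on synthetic data shows: the estimator recovers the
parameters of the *model that generated the data* under realistic
noise. What it does not show: robustness to the error sources that
dominate the real assay — pipetting-volume error (~6.5 % per
deposition), enzyme placement offsets, enzyme diffusion out of the
reaction zone over 30 s (not modelled), bubble formation above 10 mM
substrate (unmodellable; the assay is specified for ≤10 mM and amounts
up to ~3 fmol at 10 mM), and day-to-day Seebeck/kinetics drift, which
the calibration step absorbs only to first order.

## Model-vs-device agreement at the reference operating points

Run `scripts/acceptance.py` to recompute both. At the 10 mM / 2.5 fmol
point the model peaks at 16.5 µV against the device's 17 µV. At the
1 mM / 10 fmol point it peaks at 5.8 µV against the device's 9 µV; the
shortfall is robust to grid and step refinement and to every unprinted
geometry parameter within physical ranges (those move the 10 mM peak
far more than the 1 mM peak). The two reference traces were acquired on
different devices and days with separately calibrated k_cat, and a
single linear thermal model matching the measured 325 ms time constant
fixes their peak ratio near 2.8, whereas the quoted device peaks stand
in ratio 1.9 — so one default Seebeck coefficient cannot reproduce both
amplitudes simultaneously. Matching a particular device is what the
per-device amplitude calibration (rescaling the total Seebeck
coefficient from one known-amount trace) is for.

## Known limitations

* No enzyme diffusion or immobilization kinetics; the zone is a fixed
  cylinder with uniform enzyme.
* Single well-mixed zone rate rather than per-cell kinetics (the zone
  is 8 × 2 cells at default resolution; the distinction is small
  because K_m ≫ S₀).
* No advection during filling, no bubble physics, no temperature
  dependence of k_cat, no amplifier chain (signals are referred to the
  thermopile output).
* The etched-window extent, membrane thickness and junction separation
  are defaults, not measured values; absolute amplitudes carry that
  uncertainty, while conservation properties, time constants and the
  inference machinery do not depend on them.
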