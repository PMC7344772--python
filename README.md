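# telisim

Forward modelling and model-assisted inference for **thermometric
ELISA (TELISA)** on a capillary-perfused nanocalorimeter.

In a TELISA the readout is the *heat* of the label enzyme's reaction
rather than colour or fluorescence. The platform modelled here is a
microfluidic channel (2355 × 3000 × 50 µm of liquid) crossing a thin
Su-8 membrane that carries a 27-junction Bi/Ti differential thermopile.
Substrate (H₂O₂) wicks into the channel by capillarity and reconstitutes
a femtomole-scale spot of dried catalase in a small *reaction zone*
(⌀500 µm × 5 µm) above the sensing junctions. The exothermic
decomposition (ΔH = −98 kJ/mol) warms the sensing junctions relative to
the reference junctions further across the channel, and the thermopile
converts that differential into microvolts.

`telisim` is a digital twin of this measurement plus the inference that
turns traces into enzyme amounts:

1. **Substrate transport** — finite-volume diffusion of H₂O₂ in the
   channel liquid with a Michaelis–Menten sink in the reaction zone,

   v = k_cat · E_a · S̄ / (K_m + S̄),

   and catalase suicide inactivation: each enzyme survives
   *InF* × 10⁷ turnovers, so E_active = max(0, E_a − C / (InF·10⁷))
   where C is the cumulative consumption.
2. **Thermal readout** — the consumption increments become a heat
   source in the reaction zone; transient conduction through liquid,
   membranes, walls and the silicon frame yields the sensing-minus-
   reference temperature; voltage = total Seebeck coefficient × ΔT.
   Together these define the forward map g(E_a, k_cat, InF) → y′(n·Δt).
3. **Inference** — RMSE = √(Σ(y−y′)²/n) between measured and modelled
   traces over the 30 s time course (masking the ~100 ms capillary-
   filling artifact); grid-search calibration of (k_cat, InF) at a known
   enzyme amount, 1-D inversion for unknown amounts, and extrapolation
   of the limit of detection from the replicate spread of the
   determinations.
4. **Synthetic traces** — forward signal + filling artifact + sensor
   noise + optional drift, so the whole pipeline is testable without
   instrument data.

## Worked example

A reduced-resolution configuration keeps the forward model fast (the
lateral grid is fixed by the reaction-zone size; vertical layers,
margins and the 20 ms sampling are reduced):

```yaml
# demo.yaml
resolution: {dxy: 62.5, n_z_liquid: 4, n_z_slab: 2, n_margin: 2}
solver: {dt: 0.02, t_end: 30.0}
grids: {kcat_n: 9, inf_n: 5, ea_n: 17}
```

Generate a synthetic "calibration day" trace at a known 2.5 fmol of
catalase in 10 mM H₂O₂, calibrate the kinetics on it, then determine an
unknown (true value 1.5 fmol):

```console
$ telisim synth --config demo.yaml --ea 2.5 --s0 10 --sigma 0.5 --seed 7 --out known.csv
INFO telisim: synth: wrote known.csv (seed 7, sigma 0.5 uV, config d1d7102dddabe5aa)

$ telisim calibrate --config demo.yaml --signal known.csv --ea 2.5 --s0 10 --out calib.json
UserWarning: calibration argmin on the grid boundary; widen the search ranges
INFO telisim: calibrate: kcat=3.162e+05 1/s, InF=0.5, rmse=0.877 uV -> calib.json

$ telisim synth --config demo.yaml --ea 1.5 --s0 10 --sigma 0.5 --seed 8 --out unknown.csv
$ telisim quantify --config demo.yaml --signal unknown.csv --calib calib.json --s0 10 --out quant.json
INFO telisim: quantify: Ea=1.186 fmol, rmse=0.529 uV -> quant.json
```

Reading the numbers: the trace was generated at k_cat = 260 000 1/s
(off-grid); the calibration lands on 3.16 × 10⁵ 1/s — the nearest node
of the 9-point search grid. The inactivation factor hits the grid
boundary and triggers a warning: at these operating conditions a
2.5 fmol spot performs far fewer than InF × 10⁷ turnovers in 30 s, so
*InF* barely shapes the trace and is only weakly identified — it is an
effective, calibrated parameter, not a mechanistic constant. The
subsequent inversion returns 1.19 fmol for the 1.5 fmol "unknown", a
spread consistent with fitting a 0.5 µV-noise trace with
nearest-node kinetics. `telisim lod --results dir/ --out lod.json`
turns replicate determinations at several levels into a detection
limit. All results embed the config hash and seeds, and identical
inputs reproduce byte-identical outputs.

The same pipeline is available as a library (`telisim.ForwardModel`,
`telisim.calibrate`, `telisim.quantify`, `telisim.estimate_lod`);
`ForwardModel` caches its grid response kernels and per-node traces, so
parameter sweeps cost milliseconds per node after the first solve.

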