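# flowadhesion

Analysis of **initial bacterial adhesion in parallel-plate flow cells
(PPFC)**: did the adhesion rate drop because of hydrodynamic blocking, or
because cells detach under drag?

The package is aimed at biofilm/antifouling researchers who monitor
adhesion in real time under controlled shear. It provides:

- **Transport & drag estimates** — Smoluchowski–Levich (SL) deposition
  flux, Péclet number, wall drag on adhered cells and the local Reynolds
  number for a rectangular channel:

  ```
  Pe  = 3 v_av R_b³ / (2 (h₀/2)² D∞)
  SL  = 0.538 (D∞ C_b / R_b) (Pe h₀ / x)^(1/3)
  D   = 32 τ_w R_b²,   τ_w = µγ,   Re_c = ρ γ R_b² / µ
  ```

- **A stochastic adhesion simulator** — Poisson arrivals, hard-core
  exclusion, optional downstream "shadow" blocking, first-order
  detachment, and a brightfield-like frame renderer with ground truth.
- **Cell detection** — inversion + prominence (h-maxima) peak finding and
  Otsu surface-coverage measurement on 8-bit frames.
- **Two-phase kinetics** — breakpoint-selected two-segment regression of
  density vs. time, percent rate reduction, ANOVA + Tukey HSD across
  conditions.
- **Blocking analysis** — 2D pair-correlation probability-density maps
  around reference cells, a flow-axis depletion index, and a
  rotation-permutation test for directional bias.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

The bundled preset encodes a reference flow-cell operating point (0.8 ×
1.6 cm channel, mid-channel observation at x = 12.71 cm, buffer at
ρ = 993.37 kg/m³ and µ = 6.94×10⁻⁴ kg/(m·s), cells with R_b = 0.45 µm,
D∞ = 4×10⁻¹³ m²/s, C_b = 7.6×10¹³ cells/m³) at six flow rates with
CFD-derived wall shear rates:

```sh
$ flowadhesion transport --preset flowcell
 Q_mL_per_s  v_av_m_s  shear_rate_per_s  tau_w_Pa       Pe  SL_cells_cm2_s       drag_N     Re_c
        1.0  0.007812               7.5  0.005205 0.000167       79.592310 3.372840e-14 0.000002
        2.0  0.015625              15.0  0.010410 0.000334      100.280027 6.745680e-14 0.000004
        4.0  0.031250              33.7  0.023388 0.000667      126.344917 1.515529e-13 0.000010
        6.0  0.046875              51.6  0.035810 0.001001      144.628826 2.320514e-13 0.000015
        8.0  0.062500              80.3  0.055728 0.001335      159.184620 3.611187e-13 0.000023
       10.0  0.078125             100.8  0.069955 0.001669      171.476434 4.533097e-13 0.000029
```

Reading the table: raising the flow rate from 1 to 10 mL/s increases the
transport-limited deposition flux from ~80 to ~171 cells/(cm²·s) — only
×2.2, the Q^(1/3) scaling of the SL flux — while the drag on an adhered
cell grows ×13, from 3.4×10⁻¹⁴ to 4.5×10⁻¹³ N. Pe ≤ 0.0017 and
Re_c ≤ 3×10⁻⁵ confirm diffusion-dominated near-wall transport and creeping
flow (Stokes drag valid). Faster flow therefore feeds the surface a little
faster but pulls on adhered cells much harder.

Simulating an adhesion assay with detachment and fitting the two-phase
kinetics:

```python
import flowadhesion as fa

cfg = fa.SimulationConfig(rng_seed=1, detachment_rate=0.002)  # 1/s
sim = fa.simulate_adhesion(cfg)
series = fa.AdhesionTimeSeries(sim.frame_times, sim.densities_cells_cm2())
fit = fa.fit_two_phase(series)
print(f"breakpoint: {fit.breakpoint_s/60:.0f} min  s1: {fit.slope1:.0f}  "
      f"s2: {fit.slope2:.0f}  reduction: {fit.reduction_pct:.0f}%")
```

```
breakpoint: 9 min  s1: 3042  s2: 296  reduction: 90%
```

The density initially climbs at ~3000 cells/(cm²·min) and flattens once
detachment balances arrival — a 90% rate reduction with **no blocking at
all** (the shadow model was off), illustrating that a slope decrease alone
does not demonstrate hydrodynamic blocking. The pair-correlation map of the
same run (`fa.pair_correlation_map`) stays rotationally uniform and the
permutation test finds no flow-axis depletion; switching the shadow model
on produces a depletion index < 1 at p < 0.01.

A full run (transport → simulation → kinetics → blocking for every
condition) with all outputs as CSV/JSON:

```sh
flowadhesion run --preset flowcell --seed 1 --out results/run1
```

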