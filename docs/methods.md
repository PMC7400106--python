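# Methods

## The problem

When a bacterial suspension flows through a parallel-plate flow cell (PPFC)
over a test surface, cells accumulate on the surface at an initial rate set
by convective-diffusive transport, and that rate commonly drops after a few
minutes. Two competing explanations are (i) *hydrodynamic blocking* — each
adhered cell casts a downstream "shadow" in which further deposition is
suppressed — and (ii) *detachment* — the drag exerted by the flow removes
weakly bound cells. The two mechanisms leave different fingerprints: blocking
produces a directional depletion in the spatial pattern of adhered cells,
while detachment does not. This package implements the full analysis chain
needed to tell them apart: transport and drag estimates, cell detection in
image frames, two-phase adhesion-rate regression, and a 2D pair-correlation
test for flow-axis anisotropy, together with a stochastic simulator that
generates ground-truthed synthetic data under either mechanism.

## Transport and drag model (`transport`)

For a rectangular channel of width *w*, height *h₀*, with volumetric flow
rate *Q*, the cross-section mean velocity is *v_av = Q/(w·h₀)*. Transport of
a cell of equivalent radius *R_b* and diffusivity *D∞* to the wall at axial
position *x* is summarised by the Péclet number

    Pe = 3 v_av R_b³ / (2 (h₀/2)² D∞)

and the Smoluchowski–Levich (SL) perfect-sink deposition flux

    SL = 0.538 (D∞ C_b / R_b) (Pe h₀ / x)^(1/3)

with *C_b* the bulk cell concentration. SL assumes every cell reaching the
wall sticks irreversibly and neglects interception, gravity and lift; it is
an upper bound on the attainable adhesion rate. Because *Pe ∝ v_av ∝ Q*, the
flux scales as *Q^(1/3)* exactly — a property the tests assert.

The load on an adhered cell is the Stokes-regime wall drag *D = 32 τ_w R_b²*
with wall shear stress *τ_w = µγ*; the expansion is valid while the
shear-based local Reynolds number *Re_c = ργR_b²/µ* stays well below 1,
which holds by orders of magnitude at all supported shear rates.

Rod-shaped cells can be mapped to an equivalent spherical radius via
*R_b = (L/2)/(ln(L/b) − 0.11)* (defined for aspect ratios above e^0.11),
but because typical published operating points quote *R_b* directly, the
equivalent radius is a first-class config parameter (default 4.5×10⁻⁷ m)
and the rod formula is never invoked implicitly.

Wall shear rates in a real finite-aspect-ratio channel come from CFD or
measurement and are **supplied** per flow condition; the bundled preset
carries the six CFD-derived values (7.5–100.8 s⁻¹ for 1–10 mL/s). The
analytic wide-slot formula γ = 6Q/(w·h₀²) is available as an explicit
fallback but disagrees with CFD by tens of percent (5.86 vs 7.5 s⁻¹ at
1 mL/s for the default channel) and is therefore never substituted silently.

Internal units are strictly SI; the flux is converted to cells/(cm²·s) only
at the reporting boundary.

## Adhesion simulator (`simulate`)

Arrivals form a homogeneous Poisson process in time at rate
(arrival_rate × field area); each arrival lands uniformly at random and is
**lost** (not re-queued — convection sweeps rejected cells away) if it falls
within 2·hard_core_radius of an adhered cell or, when the shadow model is
enabled, inside the rectangular footprint extending `length_um` downstream
(+x) of any adhered cell with half-width `halfwidth_um`. Adhered cells
detach independently with first-order kinetics at rate *k_det* (memoryless;
bond-ageing effects are out of scope). With shadow off and *k_det* > 0 the
expected count follows the birth–death closed form
*N(t) = (aA/k)(1 − e^(−kt))*, which the tests check against the fitted
plateau.

Defaults encode the emulated assay: 30 min duration, 60 s frame interval,
0.61 µm/pixel, arrival rate 80 cells/(cm²·s) (the SL flux at the lowest
preset flow rate), hard-core radius 1 µm. The default shadow
(21 × 3 µm rectangle) is ~20× the cross-sectional area of a 1 µm-radius
cell — the simplest controllable-area shape for a mechanism whose published
estimates span roughly one to three orders of magnitude of the particle
cross-section. `scenario_from_transport` binds a flow condition to the
simulator: arrival_rate ← SL flux, and *k_det = k₀·D/F_ref* with defaults
k₀ = 10⁻³ s⁻¹, F_ref = 3.4×10⁻¹⁴ N. These two constants are **arbitrary
model choices** — no measured detachment kinetics exist to calibrate them —
and are exposed as parameters.

Determinism: one root seed fully determines a run; multi-field experiments
spawn independent child generators from the root seed.

The renderer draws each cell as a dark Gaussian blob (σ = 0.8 µm,
depth 120) on a light background (200) with additive Gaussian read noise
(σ = 8 by default), clipped to [0, 255] — a deliberately simple brightfield
stand-in. It does not emulate uneven illumination, focus drift, cell
rotation/elongation, or touching-cell occlusion; detection results on
synthetic frames therefore bound, rather than guarantee, performance on
real micrographs.

## Detection (`detect`)

`find_maxima` inverts the frame, smooths it with a Gaussian
(`smooth_sigma`, default 2 px), and extracts maxima of prominence ≥
`noise_tolerance` (default 10 intensity units) with an h-maxima transform;
plateau maxima report the plateau centroid pixel. Maxima closer than
`min_separation` (default 3 px ≈ 2 cell radii at 0.61 µm/px) are merged,
keeping the brighter (ties break to the smaller row-major index). The
smoothing step matters: prominence thresholds are meaningful only relative
to the post-smoothing noise level (≈ noise_sd/(2√π·σ) for white noise), and
without it pixel noise generates thousands of spurious maxima per frame.
Detection is invariant under global intensity offsets (prominence-based)
and equivariant under image flips.

`area_fraction` applies lighter smoothing (1 px), thresholds the inverted
image (Otsu by default; a fixed threshold is available), and reports the
covered-pixel percentage. A single-intensity frame returns 0 with a
warning. Note the rendered blob is optically larger than the cell body, so
synthetic coverage overestimates geometric coverage; the tests assert a
range (0–10% at 10⁶ cells/cm²), not a point value.

Coordinates are 0-based pixel indices, x = column, y = row, origin top-left.

## Two-phase kinetics (`kinetics`)

`fit_two_phase` fits two *independent* OLS lines (they need not meet at the
breakpoint, mirroring the practice of running two separate regressions) with
the breakpoint chosen by grid search over the observation times inside a
window (default 5–9 min) to minimise total SSE. The first segment takes
t ≤ t_b, the second t > t_b, each with ≥ 3 points. SSE ties break to the
latest candidate: on noiseless piecewise-linear data the kink observation
lies on both lines, the two adjacent candidates tie at SSE = 0, and the
latest one recovers the true kink exactly. Slopes are reported in
cells/(cm²·min); the rate reduction is (1 − s₂/s₁)·100 and is
scale-invariant. Since the two-line model nests the single line, its SSE
never exceeds the single-line SSE.

`compare_rates` computes the one-way ANOVA F statistic from between/within
sums of squares and Tukey's HSD for all pairs
(q = |Δmean|/√(MSW/2·(1/nᵢ+1/nⱼ))), with tail probabilities from scipy's F
and studentized-range distributions. The implementation is cross-checked in
the tests against statsmodels' `pairwise_tukeyhsd` and against a vectorised
Monte-Carlo null (type-I error within [0.04, 0.06] at α = 0.05).

## Blocking analysis (`blocking`)

The pair-correlation map is a (2R_max+1)² histogram of neighbour
displacements in 1-px bins (R_max default 50 px ≈ 30.5 µm), self-pairs
excluded, with reference cells restricted to ≥ R_max from every field edge
so each reference sees the complete disc (no pair-wise edge-correction
factors needed; neighbours may lie anywhere). Fields are pooled before
normalisation; the in-disc bins sum to 1, making each bin a probability
mass. For a homogeneous pattern the per-bin level is ≈ 1/(πR_max²) =
1.27×10⁻⁴ at R_max = 50. Sub-pixel displacements are assigned to the
nearest-integer bin, and disc membership is decided on the binned
displacement so the support is exactly the pixel disc.

In unordered mode every displacement is accumulated with its mirror, so the
map is exactly centro-symmetric by construction — a one-sided downstream
shadow is invisible in this mode (its mirror fills it in), and only a
symmetric along-axis depletion can register. Time-ordered mode accumulates
only neighbours that attached strictly later than the reference and is the
sensitive test for one-sided shadowing when attachment times are available.

The flow-axis depletion index is the observed pair mass in a cone of
half-angle θ (default 30°) and radius r_s (default 34 px, the default
shadow length in pixels) about the flow axis, divided by the rotationally
uniform expectation (angular fraction 2θ/360, doubled in unordered mode
where both cones are pooled). The permutation test computes the same index
from the raw displacement vectors and builds the null by rotating each
displacement independently by a uniform angle — preserving the radial
structure, destroying direction — with
p = (1 + #{null ≤ observed})/(1 + n_perm), one-sided for depletion. In
unordered mode the test statistic deduplicates mirror pairs: a pair and its
mirror have identical two-sided-cone membership, so counting both would
halve the effective sample size and make the rotation null anti-conservative
(measured: 4/20 false rejections at α = 0.05 before deduplication, 4/60
after). Fewer than 50 pairs triggers a warning and a caveat flag on the
result.

## Pipeline and outputs (`pipeline`, `cli`)

`run_pipeline` executes transport → (simulate | detect | load coordinates) →
two-phase kinetics → blocking for every configured flow condition, writing
CSVs with fixed 6-significant-digit float formatting so reruns with the same
seed are byte-identical, plus a JSON manifest (config echo, version, file
list, stage timings). The `flowadhesion` CLI exposes `transport`,
`simulate`, `detect`, `kinetics`, `blocking`, `run` and `preset`
subcommands; `--preset flowcell` loads the bundled six-flow-rate operating
point.

## Problem sizes used in the tests

The verification suite runs entirely on synthetic data generated at call
time: uniformity and map-level checks pool 10–12 fields of 1000×1000 px at
10⁶ cells/cm² (≈ 3 700 cells/field, ≈ 2×10⁶ mirror-counted pairs);
permutation calibration/power use 199 permutations over 20 runs (null) and
10 simulated shadowed fields (alternative); detachment-kinetics checks use
20 seeded 30-min runs on 400–600 µm fields; detection checks use 100-cell
renders at signal-to-noise ratios of 5–15. These sizes were chosen so the
statistical assertions have comfortable margins while the whole suite runs
in well under a minute of compute.

## Known limitations

- The SL flux is a perfect-sink upper bound; no surface-chemistry or
  energy-barrier correction is modelled.
- No CFD: wall shear quantities for real channels must be supplied; the
  analytic slot formula ignores side walls.
- The simulator's arrivals are point events — no Brownian-dynamics
  near-wall trajectories, no rolling/sliding, no bond ageing, no growth.
- The renderer is a Gaussian-blob cartoon of brightfield imaging (see
  above); detection parameters tuned on it may need adjustment on real
  micrographs.
- Unordered pair-correlation maps cannot, even in principle, reveal
  one-sided blocking; conclusions about blocking from snapshot data rest on
  the absence of *symmetric* along-axis depletion plus the time-ordered
  test where times exist.
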