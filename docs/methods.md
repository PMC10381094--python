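# Methods

`imctplan` is a desk-scale planning sandbox for intensity-modulated
carbon-ion therapy (IMCT): several scanned pencil-beam fields deliver
deliberately non-uniform dose distributions that only sum to the
prescription, which makes plans sensitive to range and setup errors. The
package implements the full chain — phantom, beam model, dose influence,
mixed-beam radiobiology, robust optimization, scenario evaluation — with
every component exposed and testable. This note records the models, the
parameter choices, and the places where the design was genuinely open.

## Phantoms and geometry

Two programmatically built phantoms drive all studies (right-handed mm
coordinates, isocenter at the phantom center; x = LR, y = AP, z = SI):

* **Benchmark cylinder** (232 mm diameter, 80 mm long, water, RSP 1.0;
  air outside): a C-shaped CTV (annulus of inner/outer diameter 18/40 mm,
  40 mm long, with a 90° opening sector facing the 0° port) wrapped around
  a cylindrical OAR (30 mm diameter, 40 mm long). As printed, the annulus
  and the OAR overlap radially (annulus radii 9–20 mm vs OAR radius 15 mm),
  so the CTV is defined as the annulus minus the opening sector **minus the
  OAR cylinder** (configurable gap, default 0); the masks are then disjoint
  and the CTV forms a 4–5 mm shell flanking the OAR on three sides. The
  opening angle and the heterogeneous inserts (air RSP 0.001 / bone RSP
  1.53 slabs, 20 mm thick, laterally adjacent to the CTV on the ±x sides)
  are configurable: the benchmark convention fixes them only pictorially,
  not numerically.
* **Donut phantom**: a 160 mm water cube holding a donut target (inner/
  outer diameter 25/100 mm, 100 mm long, axis along z) whose central hole
  is the OAR; five cylindrical flask ROIs (radius 10 mm, height 10 mm)
  sit at the midplane, four on a 31 mm ring inside the target, one centered
  in the hole.

WEPL (water-equivalent path length) is the line integral of relative
stopping power. The standalone `wepl_along_ray` uses trapezoidal sampling
at `min(spacing)/2`. The dose engine instead builds one beam's-eye-view
(BEV) grid per field — RSP resampled onto a beam-aligned grid at
`min(spacing)` and cumulated with the **midpoint rule**, which is exact for
material boundaries lying on voxel faces and half-step accurate otherwise;
the trapezoidal variant biased the surface by half a step, visibly shifting
the Bragg peak on a 2 mm grid.

## Machine model

The beam library is synthetic and analytic-but-tabulated; its magnitudes
are ordinary for scanned carbon beams but no agreement with any physical
beamline is claimed. All shape parameters live in one serializable JSON
document (`MachineModel.to_dict`) so a measured library can be swapped in.

* Depth dose `D(z; R)` (Gy·mm²/MU): a slowly rising entrance plateau (30%
  of peak, complementary-error-function cutoff at the peak), a Gaussian
  Bragg peak of width σ_R = 1.0 + 0.012·R mm (range straggling plus ripple
  filter), and a small (4%) exponential fragmentation tail beyond the peak.
  Single maximum within 2 mm of the nominal range R by construction.
* Lateral spread: a single Gaussian with σ(z) = 2.5 + 0.004·z +
  1.2·10⁻⁵·z² mm, truncated at 3.5 σ. (A measured triple-Gaussian model
  with beam splitting is deliberately out of scope.)
* Dose-averaged LET: 13 keV/µm at the entrance rising as (z/R)⁸ to
  130 keV/µm at the peak, falling exponentially toward 30 keV/µm distally.
* LQM tables: α(LET) = 0.10 + 1.35·(1 − e^(−LET/75)) Gy⁻¹ (monotone,
  saturating; ≈ α_X at entrance LET), β(LET) = 0.0615·(1 − 0.35·(1 −
  e^(−LET/120))) Gy⁻² (slowly decreasing).

Spot placement: energy layers every 3 mm WEPL snapped to a 1 mm range
ladder, lateral pitch 4 mm (engineering choices, not inferred machine settings, sized so a full benchmark study runs in minutes on one
CPU). Conventional and spot-control plans expand coverage by the clinical
2 mm geometrical margin; the worst-case planner instead covers the union of
target footprints over its scenario set — its "automatic safety margin".

## Dose influence and scenarios

For spot j and calculation voxel i,
`d_ij = D(ρ_s·w_i; R_j) · G₂(u_i − u_j, v_i − v_j; σ(w_i))`, where `w_i` is
the voxel's own WEPL along the field direction. LQM-weighted entries
`α_ij d_ij`, `β_ij d_ij` use α, β at the LET of the voxel's scenario-scaled
depth. Entries below 10⁻⁴ of the spot's maximum are dropped (changes total
dose by < 0.1%, tested).

A scenario is (ρ, t): ρ scales every WEPL multiplicatively (±3.5% range
error; ρ > 1 means effectively shorter penetration — range errors are
symmetric everywhere, so only the pair {1−r, 1+r} matters), and t is a
rigid patient translation. For parallel beams only t's component lateral to
each field matters: spot axes shift by −t·û, −t·v̂ while every voxel keeps
the WEPL of its own unchanged ray. A shift along a field's axis therefore
leaves that field's dose untouched — physically right for a source at
infinity — and with three non-parallel ports every scenario shift affects
at least two fields.

Scenario sets: worst-case optimization uses {1±3.5%} × {nominal, ±2 mm on
each axis} = 14; evaluation uses {1±3.5%} × {6 single-axis, 8 corner
(±2,±2,±2)} = 28. The 6+8 composition is the unique natural 14-element
shift set built from ±2 mm axis moves; the nominal position is reported
separately rather than as a 15th member.

Calculation voxels default to the ROI union dilated by 10 mm (bounded
memory); the canned studies optimize and evaluate on the exact CTV ∪ OAR
(∪ flasks) set, which is all the objectives and DVH statistics read, and
use the dilated set only for dose display and the independent gamma check.

## Mixed beam model

Per-voxel mixed LQM parameters are dose-weighted means over all beams:
α_i = Σα_ij d_ij x_j / d_i, β_i = Σβ_ij d_ij x_j / d_i (β mixes linearly
in dose weight exactly as specified; classical √β mixing is available as a
config switch, default off). The biological effect e_i = α_i d_i + β_i d_i²
equals the bilinear form a_i + b_i d_i, which is what the optimizer
differentiates. Biological (photon-equivalent) dose inverts
α_X d + β_X d² = e with the standard HSG constants α_X = 0.313 Gy⁻¹,
β_X = 0.0615 Gy⁻² (inherited from the mixed-beam-model lineage, not
re-fitted here). Clinical dose is F_c × biological dose with F_c = 1.442,
calibrated so that 5.88 Gy(RBE) is exactly the photon 10%-survival dose
(e = ln 10 → d_bio = 4.082 Gy → 4.082 × 1.442 ≈ 5.88). Surviving fraction
is SF = e^(−e); per-flask SF is the voxel-mean of e^(−e_i) (survival-
weighted mean, which dominates survival-at-mean-dose for heterogeneous
fields).

## Optimization

All penalties act in biological-effect space so every term shares units.
Spot weights are minimized under x ≥ 0 by bound-constrained L-BFGS-B with
analytic gradients (every gradient is verified against central finite
differences — the master correctness oracle). Initialization is uniform
weights scaled so the mean target effect hits the prescribed effect;
iteration cap 300 (conventional/SC) and relative-change tolerance 10⁻⁶.

* **Nominal term**: Σ_T w_T (e_i − e_presc)² + Σ_O w_O max(0, e_i − e_max)²
  as plain per-voxel sums with w_T = 1, w_O = 0.3 and an OAR effect ceiling
  at 50% of the prescription. The exact functional form and its scale were
  open; per-voxel sums make the named SC recipes' penalty magnitudes
  (below) land in a workable balance, and a global `robust_scale`
  multiplier is exposed because the penalty scales interact with this
  choice.
* **Spot-control (SC)** penalties, nominal scenario only, with the named
  recipes K0 = 0.5, K1 = 10, K2 = 5, G0 = 0.5 (heterogeneity-robust uses
  K0, gradient-robust uses G0):
  - heterogeneity: K0 × weight-weighted mean of the per-spot density index
    m_j = Σ (L_j − L_i)², the squared WEPL differences between the spot's
    central ray and 8 parallel rays on a 5 mm circle at the spot's range
    depth;
  - in-field gradient: G0 × Σ over fields and **ordered** target voxel
    pairs within Δr = 6 mm of ((e_{l,i} − e_{l,k})/r_ik)², where e_{l,i}
    is the single-field effect; the pair list is seeded-subsampled above
    50 000 pairs with a compensating scale factor;
  - OAR sparing: weight-weighted mean of K1·P_R + K2·P_S with geometric
    risk indices P = e^(−Δ/λ), λ = 5 mm: Δ_peak is the smallest distance
    from the Bragg-peak positions under {1, 1±3.5%} range scaling to the
    OAR, Δ_path the smallest lateral distance from the ±2 mm-shifted beam
    axis (upstream of the peak) to the OAR. The risk index is specified here
    concretely as an exponential distance decay; only its qualitative
    behaviour (rising as peak or path approach the OAR) is standard.
* **Voxel-wise worst case (WC)**: F_Dnom + p_w [Σ_T w_T((min_s e_i^s −
  e_ref)² + (max_s e_i^s − e_ref)²) + Σ_O w_O θ(max_s e_i^s − e_max)(…)²],
  p_w = 1 by default, e_ref = prescribed effect (nominal-scenario effect is
  a config switch). The per-voxel argmin/argmax selection is re-computed at
  **every objective evaluation**, so L-BFGS-B descends the true piecewise-
  smooth minimax objective with its subgradient; freezing the selection for
  a block of inner iterations (the textbook outer-loop smoothing) overfit
  the stale selection on the benchmark case and stalled far above the
  subgradient run, so it is not the default (a frozen-selection evaluation
  mode remains available for testing). Scenario influence matrices are
  stored in float32 to bound memory; iteration cap 150.

## Evaluation

DVH statistics use an inverse cumulative DVH with linear interpolation
between order statistics; D98 is the dose received by at least 98% of the
structure, Dmax the single-voxel maximum, both reported normalized to the
prescription. Robustness of a plan is the spread (max − min) of CTV D98
and OAR Dmax over the 28 evaluation scenarios recomputed with fixed
weights; the nominal volume is included in the envelope so the reported
nominal value always lies inside [min, max].

The gamma comparison is 3D and locally normalized (per-voxel reference
dose), 2 mm / 3% with a 10% low-dose threshold: the evaluated volume is
searched over a ball of 3× the distance criterion at 0.5 mm steps with
trilinear subvoxel interpolation; offsets are distance-sorted so the search
terminates early.

The independent check rebuilds the dose of a finished plan from its
serialized spot list by a literal per-spot summation over all calculation
voxels with **independently ray-traced WEPL** (no BEV grid, no candidate
window, no sparsity floor) and compares by gamma plus the isocenter RBE
difference. Because the WEPL discretizations differ, a small fraction
(<1%) of grazing-incidence voxels on the curved cylinder surface can
exceed the local 3% criterion; on flat-entry phantoms the paths agree
everywhere, and the matrix-vs-summation identity with shared kernels is
exact.

## Study sizing

Study problem sizes are the package's own desk-scale choices: benchmark
cylinder studies run at a 2 mm grid, 4 mm spot pitch, 3 mm layers
(≈ 4 700–5 100 spots, three fields at 0°/90°/270°); the donut survival
study runs at a 4 mm grid, 8 mm pitch, 5 mm layers with the 14-scenario WC
plan (couch 0°/180°/270°, horizontal port) and a 60-iteration cap. A full
four-planner benchmark study with 28-scenario evaluation completes in well
under 15 minutes on one CPU core.

## What the synthetic data does and does not show

The generator emulates the *structure* of a scanned carbon-ion planning
problem — sharp Bragg peaks, LET-dependent radiosensitivity, mixed-field
RBE, range/setup uncertainty propagation — with documented analytic curves.
It does not emulate nuclear-halo lateral tails, fragmentation spectra,
measured machine data, CT calibration, organ motion, or biological
variability of real cell assays. Passing tests therefore demonstrate the
correctness and the qualitative robustness behaviour of the algorithms
(worst-case and gradient-suppressed plans degrade far less over the error
scenarios than conventional IMCT, and the worst-case plan keeps the highest
minimum-scenario target coverage), not agreement with any clinical system's
absolute numbers: conventional-plan robustness indices here are larger than
in a clinical setting because the synthetic Bragg peak is sharp relative to
the 3 mm layer spacing and no SOBP smoothing beyond layer stacking is
applied.

## Numerical choices and degenerate inputs

Zero-dose voxels get α = β = e = 0 (the dose-weighted mixing is undefined
there). Ratio-form SC terms are defined 0 at Σx = 0 and are invariant under
uniform weight scaling. The WC planner with p_w = 0 and the SC planner with
all penalties 0 reduce bit-identically to the conventional planner.
Non-finite objective values abort the solver with a diagnostic. Every CLI
study writes a manifest (config hash, seed, library versions) sufficient to
reproduce its outputs bit-identically.

## Known limitations

Parallel-beam geometry (no divergence or inverse-square falloff); single-
Gaussian lateral model; per-voxel-ray pencil beam (no lateral heterogeneity
splitting); physical-dose-only gamma on the calculation-voxel region;
single-fraction biology (no fractionation, oxygen, or repair kinetics);
patient CT cases are out of scope.
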