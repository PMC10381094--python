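# imctplan

A desk-scale planning sandbox for **intensity-modulated carbon-ion therapy
(IMCT)** with scanned pencil beams: physical dose influence on voxel
phantoms, mixed-beam-model radiobiological dose, **spot-control (SC)** and
**voxel-wise worst-case (WC)** robust optimization, scenario-based
robustness evaluation, 3D local gamma validation and clonogenic
surviving-fraction prediction.

It is written for medical physicists and algorithm developers who want a
small, fully inspectable implementation of robust radiobiological
optimization — every kernel, objective term and gradient is plain
NumPy/SciPy and is tested against independent oracles — rather than a
clinical treatment planning system.

## The model in brief

Physical dose at calculation voxel *i* is linear in the spot weights
(MU): *d_i(x) = Σ_j d_ij x_j*. Carbon ions kill cells more effectively
near the Bragg peak, so each influence element carries linear-quadratic
parameters α_ij, β_ij driven by the local dose-averaged LET. The **mixed
beam model** forms per-voxel parameters as dose-weighted means,

    α_i = (1/d_i) Σ_j α_ij d_ij x_j,     β_i = (1/d_i) Σ_j β_ij d_ij x_j,

giving the biological effect *e_i = α_i d_i + β_i d_i²*, the
photon-equivalent dose *d_bio = (√(α_X² + 4 β_X e) − α_X)/(2 β_X)* (HSG
constants α_X = 0.313 Gy⁻¹, β_X = 0.0615 Gy⁻²), the clinical dose
*1.442 × d_bio* in Gy(RBE), and the surviving fraction *SF = e^(−e)*.

Plans are found by `minimize_{x≥0} F(x)`:

* **conventional** — quadratic target-effect deviation plus one-sided OAR
  overshoot, nominal scenario only;
* **SC** — adds per-spot penalties (lateral-WEPL heterogeneity index,
  in-field effect-gradient suppression, geometric OAR risk indices for
  range/setup errors) in the nominal scenario;
* **WC** — adds the voxel-wise worst case over an explicit 14-scenario set
  (±3.5% range, ±2 mm setup): each voxel is penalized at its own worst
  (and best) scenario effect.

Robustness is reported as the spread Δ = max − min of CTV D98 and OAR
Dmax over 28 evaluation scenarios, normalized to the prescription.

## Worked example

A full benchmark study on the homogeneous cylinder phantom (C-shaped CTV
around a rod OAR, 4.8 Gy(RBE), three ports at 0°/90°/270°):

```python
from imctplan.experiments import run_rtog_study

res = run_rtog_study(heterogeneous=False,
                     planners=("conventional", "sc_gradient", "wc"),
                     seed=1, outdir="out/rtog")
print(res["summary"].to_string(index=False))
```

prints (normalized to the prescription; a few minutes on one CPU):

```
        plan structure metric  nominal      max      min    delta
conventional       CTV    D98 0.908928 0.908928 0.235522 0.673406
conventional       OAR   Dmax 0.753489 1.168616 0.692583 0.476033
 sc_gradient       CTV    D98 0.923827 0.923827 0.550653 0.373173
 sc_gradient       OAR   Dmax 0.823081 0.957705 0.724833 0.232873
          wc       CTV    D98 0.874374 0.884248 0.802098 0.082150
          wc       OAR   Dmax 0.849345 0.930624 0.849345 0.081278
```

Reading: the conventional plan covers the target well nominally
(D98 ≈ 0.91 of the prescription) but collapses in the worst error
scenario (D98 → 0.24, the distal layers lose their Bragg peaks under a
+3.5% range error). Gradient suppression roughly halves the spread; the
worst-case plan cuts ΔD98 from 0.67 to 0.08 and keeps the highest
minimum-scenario coverage, at a small cost in nominal conformity — the
directional behaviour expected of these algorithms.

The biological study plans the donut target at 5.88 Gy(RBE) — the 10%
survival level of HSG cells — and predicts per-flask survival:

```python
from imctplan.experiments import run_donut_sf_study
print(run_donut_sf_study(seed=1).to_string(index=False))
#  flask region  sf_calc
# FLASK1    CTV 0.104887   <- ~10% survival inside the target
# ...
# FLASK5    OAR 0.345001   <- the spared hole survives far more
```

There is also a CLI: `imctplan rtog-study`, `imctplan sf-study`,
`imctplan plan`, `imctplan evaluate`, `imctplan gamma`,
`imctplan build-phantom` (see `imctplan --help`).

## Layout

```
src/imctplan/
  phantoms.py     voxel phantoms, ROI masks, WEPL ray tracing, NIfTI I/O
  machine.py      synthetic beam model (depth dose, σ, LET, LQM tables), spots
  scenarios.py    14-scenario optimization / 28-scenario evaluation sets
  influence.py    BEV WEPL grids, sparse influence matrices, dose engine
  rbe.py          mixed beam model, biological/clinical dose, survival
  optimize.py     objective terms, gradients, L-BFGS-B solvers
  evaluate.py     DVH, robustness report, 3D local gamma
  experiments.py  canned studies, independent recomputation check, manifests
  cli.py          command-line verbs
docs/methods.md   models, parameter choices, limitations
```
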