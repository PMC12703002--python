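# atriatwin

Synthetic biatrial digital-twin electrophysiology: volumetric universal
atrial coordinates (UACs), rule-based anatomical labeling, anisotropic
eikonal activation, a lead-field 12-lead P-wave forward model, and
quasi-Monte-Carlo P-wave calibration — all exercised on a deterministic
synthetic biatrial + torso geometry generator.

## Who this is for

Computational cardiac electrophysiology groups building "digital twin"
pipelines need the functional stages between an anatomical mesh and a
calibrated P-wave to be testable in isolation from clinical imaging.
`atriatwin` provides those stages as a library with a fully synthetic
anatomy: two thick-walled ellipsoidal atria with nine labeled orifice
rings (MV, LSPV, LIPV, RSPV, RIPV; TV, SVC, IVC, CS), appendage patches,
a transmural fossa-ovalis bridge, and a surrounding torso with the nine
standard ECG electrodes.  Every construction rule that a patient-specific
pipeline would apply to imaging-derived meshes runs here on geometry whose
ground truth is known, so the rules themselves can be verified.

## The models at the core

* **Laplace–Dirichlet labeling** — 15 harmonic fields `−Δφ = 0` in each
  atrial wall Ω with Dirichlet data on orifice rims, appendages and
  surfaces drive the marking of SAN (2.5 mm sphere), fossa-ovalis annulus
  (2 mm), Bachmann-bundle band (2 mm around a Dijkstra geodesic), terminal
  crest and pectinate muscles, plus a gradient-based surrogate fiber field.
* **Volumetric UACs** — per node (α, β, γ, side): each atrium maps to a
  unit cuboid via per-subdomain Laplace solves with Bi-Eikonal
  (`s = d0/(d0+d1)`) boundary parameterization, the caval/PV orifices
  embedded as radius-R half-circles (R = 0.1), and a linear-elasticity
  normalization that lands the CS, LIPV and RIPV rings on circles of
  radius r = 0.04 at (α, β) = (0.2, 0.8), (0.25, 0.25), (0.75, 0.25).
* **Eikonal activation** — `sqrt(∇τ·V∇τ) = 1`,
  `V = v_l² ffᵀ + v_t²(I − ffᵀ)`, solved by a numba-compiled
  fast-iterative method; inter-atrial cables deliver `τ + l/v` delays;
  a Dijkstra oracle bounds the solution from above.
* **Lead-field P-wave** — `φ_e(t) = Σ V_e ∇Z·(G_i ∇V_m)` with
  `V_m = U(t − τ(x))`; analytic, bounded-sphere closed-form and FEM lead
  fields; standard 12-lead assembly, 0.5–150 Hz zero-phase conditioning,
  scale 0.2.
* **Calibration** — 24 parameters (velocity ratio, five regional
  velocities, six epicardial activation sites as UAC (α, β) plus onset t)
  sampled with nested Sobol' sequences; best fit by lead-averaged
  `ℓ2 = sqrt(Σ(φ_v−φ_r)²/N)` after a 60 Hz low-pass.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```sh
atriatwin simulate --config examples/coarse.yaml -o out/
```

with `examples/coarse.yaml` requesting a quick 2.4 mm model:

```yaml
geometry:
  target_edge_length: 2.4
  la_wall_thickness: 2.5
  ra_wall_thickness: 2.8
```

builds the synthetic atria, labels them, computes UACs, connects the
Bachmann-bundle cable, runs a sinus activation from the SAN and writes the
conditioned 12-lead P-wave.  It prints:

```
total activation time: 123.4 ms
```

a physiological biatrial activation time; `out/pwave.csv` holds the
traces (columns `time_ms, aVL, I, -aVR, II, aVF, III, V1..V6`) and
`out/activation.vtu` the activation map.  Comparing the P-wave with
itself through the metrics stage,

```sh
atriatwin metrics --sim out/pwave.csv --ref out/pwave.csv -o out/
# RMSE 0.00%  l2 0 mV  PWD 92.5 ms
```

reports the per-lead RMSE%, ℓ2 misfit and the sloping-detector P-wave
duration (92.5 ms here — the onset-to-offset duration of atrial
depolarization in this model).  A calibration sweep against a reference
P-wave runs with

```sh
atriatwin calibrate --config examples/coarse.yaml --ref out/pwave.csv --n 64 --seed 1 -o out/
```

writing one row per sample (24 parameters + per-lead ℓ2 + mean) to
`out/sweep.csv` and the best-fit P-wave to `out/best_pwave.csv`.

Equivalent library calls live in the test suite; the Python API mirrors
the stages (`synthgeo`, `labeling`, `uac`, `activation`, `ecg`, `metrics`,
`calibration`).

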