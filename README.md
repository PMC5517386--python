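# cardiophantom

In-silico study of how gated myocardial-perfusion SPECT ejection-fraction
estimates depend on the reconstruction, built around a digital twin of a
dynamic left-ventricle (LV) phantom.

Clinical gated SPECT reports the end-diastolic volume (EDV), end-systolic
volume (ESV) and ejection fraction

EF = (EDV − ESV) / EDV × 100 %,

but these numbers depend strongly on the acquisition protocol and on the
number of iterative-reconstruction updates — the *equivalent iterations*
EI = iterations × subsets of an OSEM reconstruction.  This package lets you
reproduce that dependence quantitatively on a fully synthetic, fully
ground-truthed phantom:

1. **`phantom`** — a dynamic two-membrane LV phantom with fixed ESV and an
   EF-dialled EDV (nominal settings 45/55/65/70 %, ESV ≈ 33 ml).  It emits
   analytic ground-truth volume curves, gated CT (HU) volumes with Gaussian
   noise, and myocardial activity maps.
2. **`ct`** — gated-CT volumetry: isotropic long-axis resampling (cubic),
   a double-Gaussian histogram fit by Nelder–Mead simplex search, a
   water/membrane threshold at the midpoint of the two fitted peaks, 3-D
   morphological clean-up, and EF from the volume-curve extrema (EF_true).
3. **`spect`** — gated acquisition simulation for a conventional 128-view
   parallel-hole protocol (LEHR-like, 180°) and a 34-view cardio-focused
   protocol (IQ-SPECT-like, 204°, 2× central magnification), with
   depth-dependent collimator blur and Poisson counting noise in 8 gate bins.
4. **`recon`** — OSEM with resolution recovery, exact-transpose projector
   pair, per-gate reconstruction, EI snapshots along a single run.
5. **`quant`** — two transparent endocardial-delineation surrogates
   (radial wall-peak sampling; count-threshold crossing) standing in for
   proprietary clinical packages, yielding per-gate volumes and EF.
6. **`report`** — the EI sweep over protocols and methods, percentage
   differences to ground truth, best-EF selection, tables and figures.

## Worked example

Validate the phantom's 65 % setting with the gated-CT pipeline:

```python
import cardiophantom as cp

cfg = cp.PhantomConfig(ef_nominal=65, seed=1)
series, truth = cp.simulate_gated_ct(cfg, n_phases=21, fov_mm=115.2, matrix=128)
curve, ef = cp.ct_pipeline(series)
print(f"EDV {ef.edv_ml:.1f} ml  ESV {ef.esv_ml:.1f} ml  EF {ef.ef_percent:.1f} %")
```

prints

```
EDV 94.3 ml  ESV 33.0 ml  EF 65.0 %
```

i.e. the 21-phase CT segmentation recovers the dialled EF to a tenth of a
percentage point (the analytic ground truth is EDV 94.3 ml, ESV 33.0 ml).
The same study end-to-end through SPECT:

```python
result = cp.run_study(cfg, protocols=("LEHR", "IQSPECT"),
                      methods=("radial_gaussian",), seed=12,
                      matrix=64, nz=32, out_dir="study_out")
print(result.table())
```

The emitted table shows the characteristic convergence behaviour: at EI = 2
both protocols overestimate EF by 5–10 points (the blurred reconstruction
hides the small systolic cavity), volumes grow monotonically with EI while
the stroke volume levels off after roughly ten updates, and the 34-view
focused protocol underestimates both volumes more than the 128-view
parallel-hole protocol at every matched EI.

The same stages are scriptable from a shell (`cardiophantom simulate-ct`,
`analyze-ct`, `simulate-spect`, `reconstruct`, `run-study`); see
`cardiophantom --help`.

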