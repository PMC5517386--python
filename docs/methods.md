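# Methods

## The phantom model

The physical device emulated here is a pump-driven two-membrane LV phantom:
water is pumped in and out of an elastic chamber immersed in a water bath,
so the end-systolic volume (ESV) is fixed by the relaxed membrane while the
end-diastolic volume (EDV) — and hence the ejection fraction
EF = (EDV − ESV)/EDV × 100 % — is set by the stroke volume of the pump.
During emission scans a "myocardial" compartment surrounding the chamber
holds the Tc-99m solution; there is no background activity and no
surrounding anatomy.

**Tracked volume.**  The quantity every stage of the pipeline measures is
the LV chamber volume out to the outer surface of the inner membrane
(water plus membrane), which is what a CT segmentation of the
water/membrane interface delineates.  The model defines this volume — not
the bare water volume — as the curve with extrema exactly at `esv_ml`
(default 33.0 ml) and `edv_from_ef(esv_ml, ef_nominal)`.  The membrane
shell extends *inward* from that surface.  This convention makes the
nominal EF, the analytic ground-truth curve, and the CT-measured EF
mutually consistent by construction; an outward shell of any appreciable
thickness would make the measured EF differ from the nominal one by several
points (a constant added volume deflates the EF of the summed curve).

**Geometry.**  Nested prolate ellipsoids with long/short axis ratio 1.8
(configurable), semi-axes scaled isotropically with the cube root of the
enclosed volume, and a uniform membrane thickness of 1.8 mm.  The thickness
balances two constraints: it must span at least ~2 voxels at the CT
resolutions used (0.9 mm in the defaults) so the membrane HU class is
well-defined in the histogram, and it must stay thin enough that the water
cavity the SPECT delineation recovers has nearly the same EF as the
enclosed volume (the gap grows with thickness; at 1.8 mm it is ≈ 1 EF
point, at 3 mm it exceeds 4).  Real latex membranes are of this order.

**Volume waveform.**  A raised-cosine systole/diastole profile with
systolic duty fraction 0.35: V(0) = EDV, V(0.35) = ESV, C1-smooth and
cyclic, extrema exactly attained.  `ground_truth_volumes(n)` samples a
uniform n-point phase grid with the nonzero grid point nearest the systolic
phase replaced by the exact systolic phase, so the sampled curve attains
both extrema for every n ≥ 2 and Eq.-style EF arithmetic on the curve
reproduces the nominal setting to < 1e-6 points.

**Rasterization.**  Voxels mix compartment intensities by a
surface-coverage fraction approximated as a one-voxel linear ramp of the
(first-order) signed distance to each ellipsoid surface; integrated volumes
are then accurate to O(h²) and a half-coverage threshold sits on the true
surface.  CT noise is additive Gaussian (default sd 15 HU; membrane 800 HU,
water and bath 0 HU — the classes must satisfy
`membrane_hu − water_hu > 10 × ct_noise_sd`).  All randomness flows through
seeded `numpy.random.Generator`s; identical seeds give identical volumes.

## Gated-CT volumetry

Per phase, independently: resample onto an isotropic grid aligned with the
LV long axis (cubic interpolation; identity fast-path when already
aligned), histogram the volume over the 0.1–99.9 percentile range padded by
2 % (256 bins), fit a double-peaked Gaussian, threshold at the midpoint of
the two fitted peak locations (equal to half the membrane CT number when
water sits at 0 HU; a literal `mu2/2` rule is provided as an option),
binarize, then clean with closing (6-connected ball, radius 1 voxel), 3-D
hole filling and largest-component selection.  EF comes from the extrema of
the per-phase volume curve.

The double-Gaussian fit is a derivative-free simplex search
(`scipy.optimize.minimize(method="Nelder-Mead")`).  Two robustness measures
matter in this phantom regime where the water class can outnumber the
membrane class 500:1: the second mode is located after excising ±5
half-widths around the dominant mode (a global prominence cut cannot see
the small class), and each mode is first fitted alone on its own ±4
half-width window before a joint 6-parameter refinement — a cold joint fit
reliably collapses both components onto the dominant (near-delta in the
noise-free case) peak.  Unimodal histograms and non-convergent searches
raise explicit errors.  The per-slice visual checks a human operator would
perform are replaced by a QC table (per-phase thresholds, fitted peaks,
volume outlier flags).

On the default 128³ / 0.9 mm grid the pipeline recovers the nominal EF to
within 0.1–0.3 points noise-free across all four settings and to well
within 1 point at 15 HU noise (test suite, seeds 1–10).

## SPECT simulation

Rotation-based projector: per view the activity grid is rotated about the
scanner axis by a sparse bilinear operator, blurred in the detector plane
with a depth-dependent Gaussian σ(d) = σ₀ + slope·d, summed along the ray
direction, and (focused protocol only) magnified transaxially about the
isocenter.  Design choices:

- **Exact adjoint.**  Rotations and the magnification are explicit sparse
  matrices, the depth blur is symmetric, so the backprojector is the exact
  transpose of the forward projector.  This makes MLEM's log-likelihood
  monotonicity hold to floating-point precision rather than approximately.
- **Blur grouping.**  Depth planes are grouped by σ quantized to 0.2 px
  (≈1 mm, well below the resolution scale); the same quantized model is
  used in both directions, preserving the transpose pairing.
- **Protocols.**  LEHR-like: 180°, 128 views at 1.4°, 25 s/view, circular
  250 mm orbit (the clinical non-circular auto-contoured orbit is not the
  object of study).  IQ-SPECT-like: 204°, 34 views at 6.12°, 30 s/view,
  constant 280 mm cardio-centric orbit, 2× transaxial central magnification
  (≈ the published sensitivity gain of the variable-focus collimator,
  implemented without flux renormalisation so total counts double).  The
  focused collimator's resolution at the cardio-centric focus is modelled
  as LEHR-like (σ₀ = 1.5 mm, slope = 0.012); its slower quantitative
  convergence is then driven by the sparse 34-view sampling and the
  magnified geometry — the mechanism the study design itself points to —
  rather than by an assumed worse PSF.
- **Gating.**  8 bins centred on phases k/8 (an R-wave-aligned left edge
  would clip the end-diastolic extremum by ~10 % of stroke volume at 8
  bins); activity is averaged over 4 sub-phases per bin (intra-gate motion
  blur).  The sub-phase grids of the bins tile the cycle uniformly, so
  gate-binned totals sum exactly to the ungated total.
- **Counts.**  Mean counts = rate × time-per-view × sensitivity / n_gates,
  Poisson-sampled with a seeded generator.  The default activity
  concentration (2000 counts s⁻¹ ml⁻¹ effective) puts peak gated pixel
  counts in the 10³–10⁴ range — a deliberately high-statistics regime that
  isolates iteration effects from noise effects.
- Not modelled: attenuation, scatter, septal penetration, decay, dead time,
  dual-head geometry (a single synthetic head covers the arc; only count
  statistics matter here).

## Reconstruction

Standard multiplicative OSEM with interleaved subsets (view i → subset
i mod S), uniform positive initialisation inside the cylindrical FOV, no
post-filter, PSF in the system model unless disabled, non-negativity floor
1e-12, each gate reconstructed independently.  With one subset the
algorithm is exactly MLEM and a per-iteration Poisson log-likelihood trace
is recorded.  Quality is indexed by EI = iterations × subsets; an EI sweep
is produced by snapshotting one OSEM run (2 subsets by default, so every
even EI in the grid {2, 4, 8, 12, 16, 20, 24, 30, 34, 40} is one full
iteration count) rather than re-reconstructing per EI.  The simulator and
the reconstruction share the projector implementation (matched modelling);
Poisson noise still decouples data from model.

## LV quantification

Proprietary clinical delineation packages are represented by two
transparent surrogates operating on radial intensity profiles sampled from
the LV centre on a 16×24 latitude/longitude grid about the detected long
axis (principal axis of the hole-filled suprathreshold blob — filling
matters, because blur dims the high-curvature apex of the bare shell and
can flip the principal axis):

- `radial_gaussian`: wall peak per ray by intensity-weighted moments of the
  contiguous region above 25 % of the ray maximum; endocardial radius =
  peak location − `offset_sigma_frac` × fitted width.  The default offset
  is 0 (mid-wall surface): for a thin-membrane phantom the mid-wall surface
  reproduces the nominal EF with the least structural bias, because any
  constant inward radial offset hits the small systolic cavity relatively
  harder and inflates EF by several points even on a converged
  reconstruction.  The offset is configurable in [0, 2].
- `count_threshold`: endocardial radius at the first outward crossing of
  `threshold_frac` (default 0.5) × the ray's wall-peak counts; a profile
  already above the level at the centre (blur-filled cavity, EI ≈ 2) has
  no cavity on that ray.

Cavity volume is the solid-angle quadrature of r³/3 over the ray grid
(smooth in EI, no voxel-quantization jitter); a voxel mask is also produced
for QC.  Both methods are exactly invariant to global intensity scaling.
More than 20 % failed rays aborts with diagnostics; isolated failures are
filled with the mean surface radius.

The two surrogates deliberately differ: the threshold method needs a
partially resolved cavity before it reports any volume at all, so it
collapses to zero at EI = 2 and converges more slowly than the wall-peak
method — the software-dependence of volume estimates is a finding, not a
nuisance, and the package exposes it.  Directional convergence claims in
the test suite (EF overestimation at low EI, stroke-volume stabilisation,
protocol ordering) are therefore asserted on the wall-peak surrogate, and
per-gate volume monotonicity on both.

## Study sizes and defaults

- CT: 128³ voxels at 0.9 mm (FOV 115.2 mm), 21 phases; chosen so the full
  multi-seed validation stays tractable while keeping ≥2 voxels across the
  membrane.
- SPECT: 64×64×32 voxels at the protocol's 4.8 mm pixel; the phantom spans
  ≈90 mm axially.
- EI sweep: both protocols × both surrogates × 8 gates over the grid above,
  one OSEM run per protocol (~1 minute on one CPU).

## Known limitations

- The simulated-vs-real gap: vendor reconstructions, true variable-focus
  ray geometry, attenuation/scatter and anatomical delineation models are
  not emulated, so the sweep's percentage volume differences are
  qualitative reproductions of the convergence behaviour, not calibrated
  predictions of any scanner's output.  In particular the surrogates'
  EF converges to the truth from above for both protocols, so the "best
  EF" record saturates at the top of the EI grid instead of crossing the
  truth at a protocol-specific EI as anatomically modelled software does.
- Passing tests on the synthetic phantom demonstrate internal consistency
  of the pipeline under the stated noise and geometry model; real gated
  data add attenuation, scatter, background uptake, motion and anatomy
  that this phantom intentionally omits.
- The first-order signed-distance rasterization is exact for spheres and
  slightly approximate at the apex of eccentric ellipsoids; the volume
  error is below the 2 % discretization tolerance at all tested grids.
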