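# Methods

`acval` quantifies, at desk scale, how the choice of attenuation-correction
(AC) μ-map biases PET quantification on a simultaneous PET/MR system, using
fully synthetic digital phantoms in place of scanner and patient data. This
note records the models, the numerical choices, and what the synthetic
setting does and does not establish.

## Physical model

Emission data are 2-D parallel-beam projections of an activity image
`f` (relative kBq/mL), attenuated by Beer–Lambert survival factors:

    E[y(θ, s)] = c · a(θ, s) · (P f)(θ, s),   a = exp(−P μ_true)

where `P` is the Radon transform in physical mm, `μ_true` the ground-truth
511 keV linear-attenuation map (mm⁻¹), and `c` a scale fixed so the expected
total equals the requested count level. Observed counts are Poisson with a
seeded generator. Scatter, randoms, normalisation, decay, dead time and
time-of-flight are deliberately absent: every reconstruction arm consumes
the identical sinogram and differs only in the AC μ-map, so any SUV
difference between arms is attributable to attenuation correction alone.

### Projector

`P` is an exact Siddon operator: per ray, the intersection length with every
pixel, assembled once per (grid, geometry) as a sparse matrix and cached.
The backprojector is the matrix transpose, so ⟨Px, y⟩ = ⟨x, Pᵀy⟩ holds to
machine precision — the property the EM updates assume. We chose the exact
sparse-matrix form over an interpolated ray-sampling projector because it
makes the adjoint exact by construction, is faster after the one-time build
(sparse matvecs dominate the studies), and reduces the projector-accuracy
question to a test against an independent per-pixel ray-clipping integrator
(`tests/_reference.py`), which shares no construction with the production
path. Radial bins have the voxel pitch; an even bin count keeps rays off
pixel-edge gridlines at axis-aligned angles.

### Reconstruction

Attenuation-weighted OSEM with the system model `A = diag(a_AC) · P`:

    x ← x · PᵀΦ(a · y / (a · P x)) / Pᵀ a      (per subset)

Protocol defaults mirror a clinical whole-body setting: 20 subsets,
3 iterations, 256×256 matrix at 2.4 mm, 3 mm FWHM Gaussian post-filter
applied once after the final iteration. Choices the protocol leaves open,
fixed here: angles are assigned to subsets by stride (angle *i* → subset
*i* mod 20) in a fixed order; initialisation is 1 inside the sensitive
field of view; zero-count/zero-forward bins follow the 0/0 → 0 convention;
the Gaussian filter uses nearest-edge padding (constants are invariant,
and sums are preserved exactly for interior-supported objects); the output
is divided by the sinogram count scale so it is in activity units.
Reconstruction is bitwise deterministic for fixed inputs.

## Attenuation maps

* **Continuous CT** — bilinear HU→LAC: `0.0096·(1 + HU/1000)` mm⁻¹ below
  0 HU (floored at 0), `0.0096 + 5.1×10⁻⁶·HU` above. A single linear
  segment cannot pass through air, water and bone simultaneously; the
  two-segment form is the standard reading of a "linear transformation"
  from CT. Since the repository has no scanner CT, a synthetic CT is
  produced by inverting this map class-wise on the ground-truth LACs
  (optionally with seeded Gaussian HU noise); noiseless, the round trip
  reproduces `μ_true` to 1e-6 mm⁻¹, so the continuous-CT arm is an exact-AC
  reference.
* **Segmented CT** — LAC thresholds with half-open bins: `[0, 0.003)` → 0
  (air), `[0.003, 0.009)` → 0.008 (fat), `[0.009, 0.011)` → 0.0096 (water),
  `[0.011, ∞)` → 0.0161 mm⁻¹ (bone); lung voxels are overridden to
  0.0032 mm⁻¹ by a mask *after* binning, because the lung value falls
  inside the fat bin and no threshold logic can produce it. Each assigned
  non-lung value lies inside its own bin, making the operation idempotent
  for a fixed lung mask.
* **MRAC** — four tissue classes with scanner LACs (soft 0.096, fat 0.080,
  lung 0.032, air 0 cm⁻¹, stored internally in mm⁻¹). Bone is not a class:
  bony voxels receive the soft-tissue value, the central MRAC limitation.
  Lung membership comes from the phantom's ground-truth labels (standing in
  for the vendor's learned lung segmentation, which is out of scope).
  Rigid-hardware μ-maps, known to the scanner from CT, are composited in by
  voxelwise maximum when requested; truncation completion is a no-op here
  because no truncation is simulated.

## Phantoms

**Cylinder** — a 200 mm uniform disk (soft-tissue LAC) replicated as five
independent-noise slices for the multi-slice uniformity layout. Hardware
configurations are cumulative: bed track (8 mm slab, LAC 0.020 mm⁻¹), bed
(12 mm slab, 0.020), spine-coil arc (104–112 mm shell over ±60° below,
0.012), head-coil base (lower half of a 115–121 mm shell, 0.012) and full
head coil (complete shell). Hardware LACs are not published; aluminium-like
slabs and lighter composite shells are plausible magnitudes, and the studies
only require hardware attenuation to be material (a vertical ray through the
full configuration loses ~40% of its counts).

**Body slice** — an elliptical body (280×190 mm) with a 10 mm fat rim, two
lungs, a liver-analog ellipse, a vertebra and a sternum analog (the latter
hosts the "normal bone" ROI so the vertebral lesion cannot contaminate it),
plus one soft-tissue lesion and one lesion in/around the vertebra. Truth
LACs (mm⁻¹): lung 0.0032, fat 0.0088, soft/liver 0.0096, bone 0.0161.
Relative uptake: soft 1.0, liver 1.2, bone 0.6, fat 0.4, lung 0.3, lesions
uniform in 3–5× (always ≥2× local background). Per-phantom seeds jitter
lesion position (±6 mm soft, ±4 mm bone), radius (6–10 / 4–6 mm) and uptake,
emulating a cohort; anatomy is otherwise fixed. The fat truth value 0.0088
sits deliberately above the segmented fat assignment 0.008, so the segmented
CT and MRAC arms share a small fat under-attenuation while only MRAC
mis-handles bone — the mechanism behind the expected ordering
|RD2| ≤ |RD1| in soft tissue.

## Studies and statistics

**Uniformity study.** Per hardware configuration: five slices simulated at
5×10⁶ counts each with the true μ (phantom + hardware), reconstructed with
AC that includes the hardware μ-map; an ablation arm omits it. On each
slice, four 60 mm circles (B1–B4, on an axial cross at ±45 mm — a symmetric
placement that keeps the circles inside the phantom with margin) and a
central 120 mm circle (A1) give

    slice uniformity = max(|max(B) − A1|, |min(B) − A1|) / A1,

and the whole-image uniformity is the maximum over the five slices at
0/±30/±60 mm. Both signed deviations are evaluated and the larger magnitude
reported, so a cold defect degrades uniformity exactly as a hot one does.

**AC comparison.** A cohort of seeded body phantoms (default 20); per
phantom one Poisson dataset, reconstructed with truth, continuous-CT,
segmented-CT and MRAC AC. Organ SUV_mean from 20 mm ROIs at fixed anatomical
positions (voxel-centre membership, no partial-volume weighting); lesion
SUV_mean/SUV_max from a 50% SUVmax isocontour (inclusive threshold,
connected component containing the maximum) drawn once on the continuous-CT
arm and applied to every arm, preserving the paired same-regions design.
Relative differences RD1 = (SUV_MR − SUV_CT)/SUV_CT and
RD2 = (SUV_MR − SUV_CTSeg)/SUV_CTSeg in percent are summarised as
mean ± SD across phantoms with Pearson correlations between arms, and a
paired t-test compares |RD1| with |RD2| (the paired design makes the paired
test the primary comparison; a one-way ANOVA adds nothing under identical
sinograms). Degenerate zero-variance differences are guarded: identical
magnitudes return (t=0, p=1); constant nonzero differences get a
machine-epsilon SE floor.

## Problem sizes and determinism

The studies run on the 256×256, 2.4 mm protocol grid with 180 views (the
projector build is cached, ~10 s; each slice reconstruction <1 s); unit and
property tests use 64–128 grids with proportionally fewer views. All
randomness (Poisson counts, lesion jitter, CT noise) flows from explicit
integer seeds through `numpy.random.SeedSequence`-derived children, so every
table in the studies is reproducible bit for bit.

## Limitations

* Geometry is a single 2-D transaxial slice. Every line of response through
  a bony region then traverses the full attenuation mismatch, whereas in a
  3-D scanner oblique sampling dilutes it; the *magnitude* of the MRAC bone
  underestimation is therefore strongly exaggerated here (tens of percent
  for the small, low-uptake bone structures, versus ≈ −19% reported
  clinically for SUV_mean in bone). The validated claims are directional:
  the bone RD is systematically negative, and shared segmentation bias
  makes |RD2| ≤ |RD1| in soft tissue.
* Lung heterogeneity, respiratory motion, Dixon MR simulation, bias fields,
  coregistration error and truncation are not modelled; lung segmentation is
  taken from ground truth, so the lung RD here reflects only cross-talk from
  other tissues, not lung-density error.
* Count levels are a free parameter (default 5×10⁶ per slice): scanner
  sensitivity cannot be mapped to desk scale, so absolute noise levels are
  nominal, not calibrated.
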