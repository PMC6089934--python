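# Methods

This note documents the models behind `sparsebone`, the constants that
matter, and the choices made where the design was genuinely open.

## Synthetic phantoms

**Three-material model.** Every phantom is a labelled volume with classes
background (air), soft tissue and bone, mapped to attenuation values
(0, 0.25, 1.5) mm⁻¹ — representative of water and mineralized bone at a
~50 kVp micro-CT spectrum.  The values only set contrast; line integrals
through the ~1 mm samples come out of order one, which is what makes the
Poisson transmission-noise model meaningful.  The sample is a cylinder
(radius 0.42 × the transverse field of view) so that all three classes are
present in every scan.

**Analytic primitives.** Parallel-slab and rod-lattice phantoms carry exact
ground truth (slab thickness/spacing, rod diameter, analytic fill
fractions) and serve as oracles for the thickness and ellipsoid-factor
operators.  Rods are centred on voxel centres; with the half-integer
centring the discrete inscribed sphere loses almost two voxels of diameter.

**Trabecular texture.** The trabecular region is a thresholded Gaussian
random field.  A plain smoothed field at ~50 % fill is a bicontinuous
sponge: its ellipsoid factor is ≈ 0 and tells rods from plates only
unreliably, whereas real subchondral trabecular bone is strongly
plate-like (EF around −0.2).  The generator therefore uses stationary
Gaussian fields with an *oscillatory* covariance: white noise filtered
with a Gabor kernel (wavelength `corr_um`, Gaussian envelope 1.5
wavelengths) along z and a smooth Gaussian kernel (σ = 0.45 wavelengths)
in-plane.  Thresholding produces layered plates normal to z.  A second,
independent field with the mirrored construction contributes vertical
struts fixed at 10 % of the bone volume; the primary threshold is then
bisected so the union hits the target BV/TV exactly (the achieved fraction
is deterministic up to voxel discretization, tolerance ±0.5 points).  The
struts both mimic the plate-and-strut architecture of subchondral bone and
keep the network connected — isolated layers would be swept away by the
keep-largest despeckling step.  Setting the anisotropy ratio above 1.25
mirrors the construction (rods plus sparse connecting plates, EF > 0); a
ratio near 1 degenerates to the isotropic sponge.

**Calibration.** BV/TV is pinned by the quantile threshold.  Tb.Th is set
through the structural wavelength via a shipped lookup table
(`calibration.json`, rebuilt by `scripts/build_calibration.py`: a sweep
over wavelength × BV/TV, four seeds each, measured with this package's own
morphometry).  Tb.S is *emergent*: at ~50 % fill the model ties separation
to thickness (both ≈ half a wavelength), so the printed Tb.S targets
(~290–310 µm against Tb.Th ~200–215 µm) cannot be matched simultaneously;
cohort separations come out near the thickness values instead.  Plate
thickness is constructed directly (a slab of the drawn thickness with 5 %
spherical pores punched in, so the pore-filling/closing chain has work to
do).  The ellipsoid factor is not a calibration target; it lands at
−0.2…−0.3 as a property of the layered architecture.

**Cohorts.** Per-sample parameters are drawn from normal distributions at
the group's mean ± SD, truncated at ±3 SD and physical bounds.  Group
structure enters *only* through these targets (operated group: BV/TV
47.7 ± 4.4 %, Tb.Th 202.9 ± 18.2 µm, Tb.S 311.6 ± 45.0 µm, Pl.Th
531.8 ± 90.7 µm; control: 51.9 ± 3.4, 214.7 ± 16.1, 285.6 ± 25.9,
485.0 ± 99.7); no osteoarthritis biology beyond those numbers is modelled.
Everything is deterministic under the cohort base seed.

## Forward model

Geometries are parallel 2-D, fan 2-D and small-angle cone 3-D; the default
acquisition is the short scan: 260 views at 0.7° (span 181.3°).  Default
distances are SAD 50 mm / SDD 100 mm, giving a fan angle of ~0.9° so that
the 181.3° span satisfies the short-scan condition (span ≥ 180° + fan); a
wider fan is configurable but then needs a wider span.  Conventions are
pinned for reproducibility: volume axes (z, y, x), voxel-centred
coordinates with the origin at the volume centre, angles counter-clockwise
from the +x detector axis, detector element 0 at the negative edge.

The projector is a Joseph-style ray-driven kernel: one step per voxel
plane along the ray's dominant axis, linear interpolation transversely,
weights = voxel size / |dominant direction cosine|.  The sampling weights
are assembled lazily into a sparse system matrix per geometry (the
repeated CGLS/DART applications then run as sparse mat-vecs over all
slices at once), and the back projector is its exact transpose — the
adjoint identity holds to rounding error, which CGLS correctness depends
on.  A Siddon (exact intersection-length) projector is kept as an
independent cross-check oracle, not the default.  2-D geometries applied
to a 3-D volume project every z-slice with the same in-plane system; the
stack is treated as one block-diagonal linear system throughout, so TV and
DART act on true 3-D neighbourhoods.

Noise: per detector element, `frames_m` independent Poisson counts with
mean I₀·exp(−p) are averaged (after the counts, not the logs), clipped at
one count to keep the logarithm finite, and re-logged.  Defaults I₀ =
5·10⁴, m = 2 frames.

## Reconstruction

* **FBP/FDK** (reference): ramp filter apodized by the Hamming window
  W(ν) = α + (1−α)cos(πν/ν_N), α = 0.54, applied with 2× zero padding;
  pixel-driven backprojection.  Parallel beam uses plain FBP (views beyond
  180° dropped); fan beam uses the flat-detector weighting with Parker
  short-scan weights (effective half-fan angle (span − 180°)/2); cone beam
  uses standard FDK cone weighting.  Insufficient angular coverage is an
  error that names the deficit.
* **CGLS**: conjugate gradients on the normal equations from the zero
  image, 25 iterations by default, residual history recorded.
* **TV-BB**: minimizes ½‖Au−b‖² + λ Σ √(‖∇u‖² + ε²) (forward differences,
  isotropic, replicated boundary) by Barzilai–Borwein (BB1, sᵀs/sᵀy) steps
  safeguarded into [10⁻⁸, 10⁸], with a power-iteration 1/L first step and
  fallback on negative curvature; 25 steps from zero; the returned iterate
  never has a worse objective than the start.  ε defaults to 1.5·10⁻⁴
  (10⁻⁴ × the bone attenuation).  λ is selected on a logarithmic grid by
  the L-curve corner — maximum three-point Menger curvature on the
  (log residual, log penalty) curve, endpoints assigned curvature zero,
  ties resolved to the smaller λ.
* **DART**: initial reconstruction = 25 CGLS iterations; each of 25 DART
  passes segments the image with the gray prior (thresholds default to
  midpoints), fixes non-boundary voxels at their class value with
  probability 0.99 (boundary = any face neighbour of a different class),
  solves for the free voxels with 10 CGLS iterations against the residual
  data (warm-started from the current free values), and smooths the free
  voxels with a radius-1 mean filter at blend 0.1.  The fix probability
  and smoothing blend follow the conventions of the discrete-tomography
  literature; both are configurable.  The output is the segmented image
  (a flag exposes the continuous iterate).  "25 base iterations" is read
  as 25 outer DART passes.
* **CNR** = (μ_bone − μ_bg)/σ_bg on a single slice near the volume centre;
  a constant background (typical for discrete DART output) returns +inf as
  an undefined marker.

## Segmentation

Median filter (cubic, radius 1) → unsharp mask v + 0.5(v − mean₃(v))
(uniform mean blur; the radius is shared) → global 3-D Otsu threshold over
a 256-bin histogram (ties to the lowest cut) → keep-largest despeckling at
26-connectivity, applied *per analysis region* (trabecular VOI and plate
VOI separately; a global sweep could delete a plate that is not connected
to the trabecular network).  The plate mask is additionally pore-filled
(background components not reaching the border) and closed with a discrete
ball of radius 2.  The ball uses the blunted bound d² ≤ r(r+1): the plain
Euclidean ball has single-voxel axial tips that fit into one-voxel pits,
so a closing with it never removes small surface pores.

## Morphometry

Local thickness is the largest-inscribed-sphere model: with the Euclidean
distance map d(c), the sphere at c contains voxel v iff ‖v−c‖ < d(c)
(strictly closer to the centre than the centre's nearest background
voxel; all comparisons in integer squared distances) and scores diameter
2d(c)−1 voxels.  The map is computed exactly by one distance transform per
distinct radius, descending, and agrees voxel-for-voxel with the
brute-force sphere sweep.  Tb.Th, Tb.S (complement within the VOI) and
Pl.Th are volume-weighted means of this map; analytic phantoms are
recovered within one voxel.  Tb.N uses the direct-model identity
(BV/TV)/Tb.Th — the convention uniquely consistent with published
data tables of this parameter set.

The ellipsoid factor seeds candidate ellipsoids at up to 200 skeleton
points (3-D skeletonization; distance-ridge fallback for slab-like masks
that thin to nothing), grows semi-axes adaptively (doubling/halving steps,
stop below a quarter voxel) under a containment test that samples 240
Fibonacci-sphere surface points against the trilinearly interpolated mask,
for three orientations per seed (identity plus two seeded random
rotations, one fixed set shared by all seeds).  Each foreground voxel
takes EF = a/b − b/c of the largest ellipsoid containing it; the mean is
over covered voxels.  Prolate structures score positive under this
convention; a `sign_convention` flag flips the reported sign for
comparison with sources that print the opposite orientation.  Stability
choices (evenly spaced seeds, shared orientations, 240 surface samples)
keep the estimator's response to small mask perturbations at ±0.01 EF;
with fewer surface samples ellipsoids punch through thin walls and the
estimate jitters by ±0.1.

## Statistics

The Mann–Whitney U test is exact and tie-aware: midranks, doubled to
integers, with the permutation distribution of the rank sum computed by
full enumeration for n₁+n₂ ≤ 14 and by the dynamic-programming shift
algorithm otherwise.  The one-tailed p covers the observed direction; the
two-tailed p doubles the smaller tail (capped at 1) — the convention that
reproduces published one-tailed/two-tailed pairs — with the exact central
tail mass available behind a flag.  Relative errors are
|IR − reference| / reference × 100 per sample, aggregated to mean ± SD per
algorithm × level × parameter; zero references exclude the sample with a
warning.

## The desk-scale study

Defaults: 6 + 6 samples on a (64, 32, 32) lattice at 25 µm voxels
(plate ~21 voxels, ~43 trabecular slices), fan-beam slices with the
260-view geometry, detector 48 × 50 µm, I₀ = 5·10⁴ with 2-frame
averaging, reductions ×2/×4/×6, 25 base iterations everywhere, TV λ by
L-curve on one pilot sample per reduction level (reused across the
cohort), EF with 120 seeds and one EF seed per sample shared across all
ten reconstructions (so EF differences between algorithms reflect mask
differences only).  The full study runs in ~4 minutes on one CPU and is
byte-deterministic under its master seed.

**What this scale shows — and does not.**  At 32² in-plane resolution even
44 views × 48 detector elements over-determine each slice, so all three
iterative methods reconstruct the (noise-moderate) phantom essentially
exactly and their morphometry coincides; the relative errors against the
full-data FBP reference (≈ 2–3 % mean over the six parameters, dominated
by EF and plate thickness) measure the analytic reference's own noise and
band-limitation bias rather than differences between iterative methods.
The ill-posed regime of a full-resolution scan (hundreds of thousands of
unknowns per slice from 44 views), where CGLS degrades visibly and the
discrete prior pays off, is outside this package's default problem size;
the pipeline supports larger lattices unchanged.  Passing the study
checks therefore validates the machinery end to end — projector,
algorithms, segmentation, morphometry, statistics — not a claim that the
desk-scale cohort discriminates between the iterative algorithms.

Other things the synthetic cohorts do not model: anatomical condyle shape,
cartilage, cortical/marrow distinction beyond three classes, beam
hardening, scatter, detector blur, ring artifacts and misalignment (real
scans correct these in preprocessing; the synthetic data never has them),
and any osteoarthritis biology beyond the printed group statistics.  With
6 + 6 samples and generator sampling noise added to the group SDs, the
Mann–Whitney tests rarely reach significance at any reduction level; the
significance-preservation comparison (DART vs CGLS) is therefore a weak
check at this scale.

## Degenerate inputs and tie rules

Constant volumes cannot be Otsu-thresholded (error).  Empty masks are
errors for thickness, despeckling and EF.  Otsu ties take the lowest
threshold; despeckle component ties take the component holding the first
voxel in (z, y, x) scan order; L-curve curvature ties take the smaller λ.
σ_bg = 0 makes CNR undefined (+inf marker).  A detector too small for the
volume shadow warns rather than errors (corners truncate); insufficient
angular span for FBP is an error naming the deficit.
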