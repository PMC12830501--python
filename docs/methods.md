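# Methods

## Positron transport and kernel generation

Kernels are the voxelised probability distribution of the annihilation
position around a ⁶⁸Ga decay in a homogeneous medium, computed by a
condensed-history Monte Carlo:

1. **Energy sampling.** Kinetic energies are drawn by inverse-CDF sampling
   from the allowed Fermi β⁺ spectrum
   `N(E) ∝ F(Z, W) · p · W · (Q − E)²` with the nonrelativistic Coulomb
   factor `F = 2πη / (1 − e^{−2πη})`, `η = −Z α W/p`. Constants from
   nuclear data: endpoint `Q = 1.899 MeV`, daughter `Z = 30` (⁶⁸Zn). The
   sampled mean is 0.84 MeV.
2. **Slowing down.** Particles advance in steps chosen in mass-thickness
   units (12% of the residual CSDA range, floored at 5 × 10⁻⁴ g/cm²,
   capped at 1.4 mm geometric length in heterogeneous media). Energy loss
   follows a total stopping-power table for water (ICRU-style values,
   10 keV – 2.5 MeV) integrated into a CSDA range, interpolated
   log–log. Media are density-scaled water (same effective composition):
   water 1.00, lung 0.26, bone 1.90 g/cm³, densities chosen so that
   density-scaled maximum ranges reproduce the sizing values below.
3. **Scattering.** Per step, the direction is deflected by two independent
   Gaussian projected angles with the Highland width
   `θ₀ = 13.6 MeV/(βpc) · √t · max(1 + 0.038 ln t, 0.25)`, `t` the step in
   radiation lengths (X₀ = 36.08 g/cm² for water).
4. **Annihilation.** The particle annihilates where its kinetic energy
   falls below 10 keV (annihilation-in-flight is neglected, as is
   positronium chemistry). In water the 99.9th-percentile displacement is
   ≈ 7.3 mm and the mean ≈ 2.7 mm.

Because steps are chosen in mass units, the trajectory in a medium of
density ρ is exactly the water trajectory scaled by 1/ρ under a fixed seed;
this is tested as the density-scaling property.

**Voxelisation.** Displacements are binned by nearest voxel centre on the
PET grid (2.73 × 2.73 × 2.80 mm³). The kernel half-width per axis is the
nearest integer (half away from zero) of `max_range / pitch`; the default
maximum-range preset is water 8.8 mm, lung 32.3 mm, bone 4.5 mm, giving
7³, 25³ and 5³ kernels (the same sizes follow from either the transverse
or the axial pitch). Weights are divided by the number of simulated decays
and then renormalised to sum exactly to one, so the correction operator
conserves counts in homogeneous regions; the captured (pre-renormalisation)
fraction is recorded in the kernel metadata. An `"auto"` sizing mode uses
the 99.99th percentile of the simulated displacement magnitudes instead of
the preset. Defaults: 10⁶ decays per kernel, seed 20220901; the experiment
driver uses 3 × 10⁵ decays per kernel, a deliberate desk-scale choice (the
kernels' voxel weights are then known to ≲ 2% relative at the centre, far
below the effects being measured).

### Heterogeneous transport for lesion insertion

`transport_in_density_map` runs the same physics through a per-voxel
density map derived from the CT tissue classification (air identified at
HU < −900). It is used to generate the ground-truth positron-range effect
of each inserted lesion (`mc_annihilation_image`): decays are sampled from
the lesion's activity distribution, transported, and the annihilation
positions deposited back on the grid. A positron emitted in a water lesion
that escapes into lung keeps its residual range and travels far — the
physics the mask-based operator itself approximates. This is the default
lesion ground truth; the mask-operator ("tdsv") and
homogeneous-lesion-kernel ("lesion_kernel") alternatives are selectable,
and comparing them is instructive: the "tdsv" ground truth makes the
reconstruction mismatch vanish by construction, while "lesion_kernel"
ignores positron escape entirely.

## Segmentation

CT volumes are resampled to the PET grid by volume-weighted block averaging
when the CT is an integer factor finer with aligned extents, and trilinear
interpolation otherwise; averaging is preferred because the HU value then
feeds a nearest-neighbour decision and aliasing at tissue boundaries would
flip classes. Each voxel is assigned to the material with the nearest
reference HU (water 3, lung −695, bone 1226; configurable). Exact midpoint
ties go to the lower-HU material. Masks are stored as one integer label
volume, materials ordered by ascending reference HU (lung, water, bone) for
reproducible serialisation.

## The correction operator

The TDSV operator applies, per tissue, convolution with that tissue's
kernel followed by masking, and sums the per-tissue results
(convolve-then-mask, which is what makes it spatially variant at
boundaries). Convolutions are zero-padded at the volume border (activity
outside the FOV is zero) and evaluated spectrally with cached kernel FFTs;
agreement with direct convolution is tested at 10⁻⁸ relative. Delta
kernels short-circuit to the identity, so a correction built from delta
kernels is bitwise transparent to the reconstruction. The exact transpose
(`Σᵢ flip(Kernelᵢ) ⊗ (img ⊙ Maskᵢ)`) is implemented and verified by
inner-product tests at 10⁻¹⁰ relative.

Counts are conserved for activity away from grid borders and tissue
boundaries; at tissue boundaries the operator is intentionally
non-conservative (each output voxel takes exactly one tissue's
convolution), a property inherent to the formulation.

## Acquisition model and reconstruction

Geometry is 2D parallel beam over independent axial planes: `n_angles`
projections over 180°, radial bins at the transverse voxel pitch. The
projector is voxel-driven — each voxel's activity content (concentration ×
voxel volume in mL) is split between the two nearest radial bins by linear
interpolation — so each view's total equals the total activity exactly and
the backprojector is the literal sparse-matrix transpose. Attenuation uses
a piecewise-linear HU→μ map at 511 keV (air −1000 HU → 0, water 0 HU →
0.0096 mm⁻¹, slope halved above 0 HU, clipped at 0) applied along the full
line of response. Detector resolution is an isotropic image-space Gaussian
(default FWHM 4.5 mm) inside both projection directions. Time-of-flight,
scatter, randoms, dead time, decay and normalisation are not simulated and
therefore not corrected.

OSEM uses balanced round-robin angle subsets in natural order,
multiplicative updates with ratio and sensitivity floors of 10⁻¹²,
zero-sensitivity voxels frozen at zero, and an initial estimate of ones
inside the attenuating body (μ > 0). Study settings are 4 iterations with
34 subsets (170 angles) and post-reconstruction 3D Gaussian filters of
6.0 mm FWHM (all variants) plus 4.0 mm for the tissue-dependent correction
in lung analyses.

**Backprojection of the correction.** By default the range-correction
operator is re-applied in its forward form in the backprojection step
(`prc_backprojection="forward"`), i.e. the correction is applied
identically in both projection directions. The exact-adjoint alternative
(`"adjoint"`) is available. The default was chosen because the matched
adjoint funnels the model's overestimated lung halo of a dense lesion back
into the lesion through the wide lung kernel, systematically suppressing
lung-lesion recovery, whereas the forward form reproduces the expected
behaviour of corrections applied "in the forward and backward projection
steps"; the operator-level adjoint remains exact and tested.

**Calibration.** Simulated sinograms carry a `scale` linking expected
counts to the forward projection of the physical activity; reconstructions
divide by it so images return in Bq/mL and activity recovery can be read
against the inserted truth.

## Synthetic torso and artificial lesions

The phantom is an elliptical body (HU ≈ 30) with two large lung fields
(HU ≈ −700, activity 0.3× soft tissue), a liver (high uptake, 3× soft
tissue), and a posterior spine cylinder (HU ≈ 1200). Geometry scales with
the field of view; the default grid is 128 × 128 × 96 at the PET voxel
size, and the study grid 128 × 128 × 48 (a 134 mm axial stack). Lung
fields are large enough that interior points lie > 40 mm from any
boundary — essential, because the lung kernel reaches 33 mm and a phantom
whose lungs are all boundary cannot represent a thorax. Activity carries a
smooth ±10% multiplicative field (Gaussian-filtered noise, σ = 4 voxels)
so the half-split subtraction has realistic structure to cancel.

Seven spherical lesions (radius 5.0 mm) reproduce the artificial-lesion
design: soft-tissue lesions in liver (3:1) and in low-uptake soft tissue
(16:1); a bone lesion and a soft-tissue lesion inside bone (both 16:1);
soft-tissue lesions inside lung (16:1 and 3:1) and at the lung–liver
boundary (10:1). Centres are placed at interior maxima of each host
region's distance transform (boundary lesions at the interface minimum),
at least 30 mm apart and away from the volume border; ratios are applied
against the mean pre-insertion activity in a 5–10 mm shell around the
sphere. Rasterisation is binary centre-inclusion for both activity and HU
(homogeneous lesions); the CT inside the sphere takes the lesion tissue's
reference HU so the tissue masks update at the lesion. Discretisation is
quantified by a supersampling oracle in the tests.

Lesions are inserted in the sinogram domain: a Poisson realisation of the
lesion-only expected sinogram (with the MC ground-truth range blur) is
added to the observed background sinogram — matching the additivity of
independent Poisson processes. Half-count acquisitions are two independent
Poisson draws at half expectation, the exact analog of splitting a
scan into two equal time segments.

## Quantification and statistics

Artificial lesions are measured in 5.0 mm spherical VOIs at the known
ground-truth centres, mapped index-identically across reconstructions
(grids are congruent by construction). Background VOIs take same-tissue
voxels — tissue read from a 10 mm shell around the lesion — farther than
5.0 mm from the VOI, nearest first, up to a minimum volume. The minimum is
10 mm³ by default, honouring the stated rule verbatim even though that is
below one PET voxel (≈ 20.9 mm³); the experiment driver overrides it to
1500 mm³ so SD_background is estimable. CNR = (mean_lesion −
mean_background)/SD_background; activity recovery = mean_lesion / inserted
activity × 100%. Patient-style tools are included: 50% isocontour VOIs
(26-connectivity, greedy ascent to the local maximum from the seed, no
background correction), exclusion of lesions > 10 cm³, and retention of at
most the five largest lesions per tissue class per patient. Half-split
noise is the SD of the difference of the two half reconstructions in a
20 mm-radius sphere (radius reduced automatically if the region cannot
contain it), with no √2 correction since only ratios across
reconstructions are compared.

Statistics follow the paired design: per-lesion percentage changes,
D'Agostino–Pearson normality screening (n ≥ 8), two-sided Wilcoxon
signed-rank (exact null for n ≤ 25 without ties, tie-corrected normal
approximation otherwise, zero differences dropped), Bonferroni adjustment
with an explicit family size (default m = 3), α = 0.05.

## What the synthetic study does and does not show

The torso study reproduces the mechanism-level findings: near-identical
behaviour of both corrections in soft tissue, overcorrection of bone by
the water kernel, the tissue-dependent advantage in lung with the largest
relative gain for the low-contrast lung lesion, strong lung noise
reduction at matched filtering and its equalisation direction under a
4.0 mm filter, and unchanged liver noise at 6.0 mm with a large increase
at 4.0 mm. It does not reproduce cohort percentages: those depend on real
anatomy, clinical count levels (the study uses 5 × 10⁶ counts over the
stack), tracer biodistribution and ToF reconstruction. One known
divergence is documented by a deliberately failing check: at these count
levels the tissue-independent correction slightly *reduces* the measured
SUV_max/CNR of the low-contrast lung lesion, because its deconvolution
gain there is negligible while it removes the spill-in pedestal and the
noise that inflate the uncorrected maximum.

## Numerical and reproducibility choices

Every stochastic operation takes an explicit seed; the experiment driver
derives per-stage seeds from a master seed by fixed offsets
(`derive_seed`, values kept below 2³¹). Reruns with the same master seed
are bitwise identical. FFT convolution uses `scipy.fft.next_fast_len`
padding; Gaussian filters use zero boundary (`mode="constant"`), which
keeps them self-adjoint. Volumes are NIfTI-2 (float64 affine, so the
anisotropic voxel size round-trips exactly); kernels and sinograms are
`.npz` archives with JSON metadata plus a plain-text radial-profile CSV
per kernel.

## Known limitations

- Positron transport treats all tissues as density-scaled water; no
  tissue-specific composition, no annihilation in flight, no magnetic
  field effects.
- The mask-based operator does not model energy loss across tissue
  boundaries (a dense lesion's positrons are smeared with the host
  kernel); the heterogeneous MC ground truth deliberately retains this
  mismatch in the data.
- The scanner model is 2D parallel-beam multi-slice without ToF, scatter
  or randoms; absolute noise levels and convergence rates differ from a
  clinical 3D ToF system.
- SUV scaling requires dose and weight; the driver reports
  activity-concentration units, on which all percentage-change endpoints
  are invariant.
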