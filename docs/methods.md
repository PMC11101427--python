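# Methods

This note documents the models, numerical choices and deliberate design
decisions behind `trophomech`, and what the synthetic-data validation does
and does not establish about real microscopy data.

## Displacement estimation (PIV)

Bead displacements between the t = 0 reference frame and each later frame
are estimated by multi-pass windowed cross-correlation. Every frame is first
rigidly registered to the reference by whole-frame cross-correlation
(Fourier-upsampled subpixel peak, plain rather than phase-whitened
normalization — whitening degrades accuracy on sparse spot images). The
correlation passes then use progressively smaller interrogation windows,
128 → 64 → 48 px by default, each pass offsetting the deformed-image window
by the previous pass's field (median-smoothed 3×3 and bilinearly
interpolated onto the new lattice) so only the residual shift has to be
resolved.

Numerical details:

* Windows are mean-subtracted and correlated by zero-padded FFT (linear, not
  circular, correlation — circular wrap biases windows whose content
  straddles the window edge). The peak is searched within ±window/4 of zero
  lag, which is also the precondition imposed on synthetic displacement
  amplitudes (one-quarter rule).
* Subpixel peak position comes from a 3-point Gaussian fit (log-parabola);
  when a neighbouring sample is non-positive the fit falls back to a
  parabola, and the offset is clamped to ±1 px.
* Near the image border, a window whose predictor offset would leave the
  frame is not truncated; instead both windows slide inward together,
  preserving the full offset. The vector is still attributed to the lattice
  point (exact for locally uniform motion, O(shift × gradient) otherwise).
* The per-vector quality measure is the normalized correlation coefficient
  at the (integer) peak. Vectors below the acceptance threshold (0.6) are
  replaced by the median of their valid 8-neighbours, iterating until no
  invalid vector has a valid neighbour; a field with more than half its
  vectors rejected is flagged `quality_ok=False`. Degenerate (flat)
  correlation planes mark the vector invalid and fall back to the
  predictor value.
* The final lattice spacing equals the final window size (non-overlapping
  windows): 48 px × 0.3086 µm/px = 14.81 µm. A half-window overlap rule is
  available (`final_spacing_rule="half-window"`).

Inter-pass smoothing and overlap conventions differ among PIV
implementations; the ones above are declared choices, selected for
stability, not inferred from any particular tool.

## Traction reconstruction (FTTC)

The substrate is modelled as a semi-infinite, homogeneous, isotropic
linear-elastic half-space with defaults E = 3900 Pa, ν = 0.457, imaged at
0.3086 µm/px. Displacement and traction are related per wavevector by the
Boussinesq surface tensor (see `trophomech.fttc`); the inverse problem is
solved with 0th-order Tikhonov regularization.

* **Regularization λ** carries the units of G̃² and defaults to
  100 × (smallest kernel eigenvalue at the Nyquist wavevector)², which
  damps the worst-conditioned mode's inverse gain about 100-fold. It is
  exposed in `FTTCConfig`; λ = 0 is allowed (with a noise-amplification
  warning). Absolute reconstructed magnitudes scale with λ, so group
  contrasts — not absolute pascals — are the comparable quantity.
* **Padding.** Fields are zero-padded 2× before the FFT to suppress
  periodic wrap-around. Zero padding is exact for the forward solve of a
  compact traction patch but truncates the slowly decaying displacement
  tails in the inverse solve; the resulting error concentrates at the field
  boundary (verified <0.2% in the central half of the domain, a few percent
  globally for a patch well inside the field). ROIs should therefore sit
  away from the image edge, as they do in all shipped scenarios.
* The k = 0 mode is indeterminate for a half-space and set to zero, and the
  recovered field is re-centred after cropping, enforcing zero net force.
* Tractions are relative to the t = 0 configuration because the PIV
  reference is the t = 0 frame throughout.

## Stress decomposition around fusion sites

Each ROI (syncytial patch or mononucleated control; the control's undilated
area must match within 5%) is dilated by an 80 px Euclidean disk —
implemented via the exact distance transform, O(N) in image size — to
include the one-to-two cell rows outside the labelled region. The centroid
is always that of the *undilated* region: the centroid defines the fusion
site, dilation only widens sampling. The spatial mean runs over all lattice
points in the dilated mask (not an annulus; a lattice point coincident with
the centroid is excluded as directionless).

Sign convention: S_R > 0 points away from the centroid, so contraction into
the region appears as a negative radial mean. The tangential component is
rectified *before* spatial averaging (mean of |S_T|), whereas the radial
mean is signed. Per vector, S_R² + S_T² = |S|² exactly (orthonormal basis).

Time courses at each ROI are aggregated as unweighted means over
12 h ≤ t ≤ 48 h, skipping the onset transient, and groups are compared with
an independent two-sample equal-variance t-test (both groups constant and
equal → t = 0, p = 1 by convention).

## Fusion metrics

With T total nuclei, F nuclei inside syncytia, S syncytia and FS
Syndecan-1⁺ nuclei:

* E-cadherin efficiency = 100·(F−S+1)/T, **defined as 0 when S = 0**: the
  "+1" presumes at least one syncytium (it makes a single fully fused sheet
  score exactly 100%), and without it an unfused field would be credited
  1/T.
* Syndecan-1 efficiency = 100·FS/T; nuclear density = T / 0.34 mm² by
  default; spheroid fusion (AU/µm³) = total integrated marker density /
  (Σ slice areas × 10 µm slice spacing, both configurable).
* Counting on masks uses connected components; a nucleus belongs to a
  region when its **centroid pixel** lies inside the region's component
  (robust to partial boundary overlap). Components holding fewer than two
  nucleus centroids are not counted as syncytia, consistent with the
  definition of a syncytium as ≥2 cells sharing a membrane.
* Because fusion competence drifts with passage number, treated values are
  reported as folds over the mean of their batch's control.

## Osmotic-compression mechanics

For a homogeneous isotropic linear-elastic body loaded by a uniform
pressure p on its free surfaces with a frictionless roller support, the
uniform stress state σ = −p·I satisfies equilibrium and all boundary
conditions simultaneously, so it is the *exact* solution of the
axisymmetric boundary-value problem — a finite-element solve of the same
problem adds only discretization error. Every linear dimension then
contracts by ε = p(1−2ν)/E, with E = 2G(1+ν) from shear rheometry
(defaults G = 5150 Pa, ν = 0.457 → E = 15 007 Pa).

Strain is diametral, not volumetric (volumetric ≈ 3× for small strains),
matching how compaction is measured: effective diameters d = 2√(A/π) from
projected areas assuming sphericity, referenced to t = 0, compression
positive. The inverse map p = εE/(1−2ν) is undefined at ν = 0.5
(incompressible) and both maps are homogeneous of degree one. Pressure
recovery from a track averages the strain over all post-reference
timepoints; negative mean strains (apparent swelling) clamp to zero
pressure, and a calibration disc that swells reports zero pressure with a
warning. The printed dextran calibration anchors (~2 kPa at 25 mg/mL,
~3 kPa at 50 mg/mL) serve as plausibility scales for synthetic scenarios;
they are not recomputable without the underlying disc diameters.

## Synthetic data: what it emulates, and what it does not

* **Bead images** are isotropic Gaussian spots (σ = 1.2 px, near the
  diffraction limit for 0.5 µm beads at 0.3086 µm/px) over a uniform
  background with additive Gaussian camera noise (2% of spot amplitude by
  default). Bead density defaults to 0.05 beads/µm² (~11 beads per final
  48 px window, comfortably above the PIV sparsity limit). Beads are
  sampled over the frame **plus a margin**, since the real gel extends
  beyond the field of view — without this, beads vanishing at the border
  bias edge vectors. Deformed frames move bead *centres* through the
  ground-truth field (forward warping); pixels are never resampled, so the
  ground truth carries no interpolation bias.
* **Contraction movies** place a Gaussian annulus of inward traction at the
  rim of a circular patch (rim width = radius/4 by default), ramping
  linearly over 2 h after onset (default 6 h) and then constant — the
  simplest time course consistent with an onset transient followed by a
  plateau. Peak traction defaults to 80 Pa, in the tens-of-pascals range
  typical of soft-gel traction experiments. Displacements come from the
  same forward Boussinesq solve on the pixel lattice (one solve, scaled by
  the ramp).
* **Fusion label masks** lay nuclei (4 px disks) on a collision-free 14 px
  grid, syncytia as shrunk rectangles over their nuclei's cells, and
  Syndecan-1 positivity as a seed-deterministic subset of syncytia
  (`fraction_syndecan` is interpreted as the fraction of syncytia marked
  positive). Tallies are exact by construction.
* **Spheroid tracks** step to the linear-elastic equilibrium diameter for
  every t > 0 (no relaxation dynamics are invented) with additive Gaussian
  measurement noise on post-reference timepoints; t = 0 stays exact so the
  strain reference is clean.

Not emulated: photorealistic microscopy (PSF structure, shot noise,
bleaching), bead polydispersity, nuclear texture, 3D light-sheet optics,
viscoelastic or poroelastic tissue response, and biological variability in
fusion timing. Passing the synthetic validation therefore establishes the
*correctness of the computational chain* under known ground truth — not the
robustness of any particular biological conclusion to real-world imaging
artefacts.

All generators are bit-deterministic under their seed.

## Problem sizes

Shipped scenarios use 384×384 px fields (≈118 µm square) sampled every 2 h
over 48 h, with seven replicate pairs for the patch-vs-control comparison,
and 96×96-point lattices for the reconstruction checks: large enough that
every pipeline stage operates in its intended regime, small enough that the
full validation runs in about a minute on one CPU. The staged CLI defaults
are smaller still (24 h, 3 h steps, two replicate pairs) to keep
interactive runs short; all sizes are configurable.

## Known limitations

* Absolute traction magnitudes depend on the regularization choice; only
  patterns and group contrasts are comparable across analyses.
* The inverse FTTC step truncates displacement tails at the field boundary;
  keep ROIs (after dilation) away from the image edge.
* No window deformation in PIV: strong displacement gradients inside one
  window average toward the bead-weighted mean (visible as scatter on
  short-wavelength fields).
* Finite substrate thickness, 3D traction components and intercellular
  (monolayer) stress recovery are out of scope.
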