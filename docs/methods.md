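# Methods

## Problem

Quantitative FDG-PET metrics — SUVmax, SUVmean and threshold-delineated
metabolic tumour volume (MTV) — depend on the reconstruction algorithm.
Resolution-recovery ("PSF") reconstructions sharpen images but overshoot
at sharp activity transitions (Gibbs artifacts), inflating SUVmax and
shrinking threshold-based volumes, and the size of the effect depends on
the lesion's signal-to-background ratio (SBR). `petphanq` implements the
phantom-side analysis used to characterise these effects: radial-profile
resolution estimation, Gibbs-artifact quantification, SUV reference
computation and threshold delineation — exercised end-to-end on a
synthetic phantom-image generator, because the original scanner
reconstructions are not publicly available.

## Phantom and study conditions

The simulated phantom is a 20-cm-diameter water cylinder (6,595 ml,
height 210 mm implied by the volume) containing four cold-wall sphere
inserts of inner diameter 29.9, 39.8, 49.9 and 69.7 mm with 1.2-mm
inactive walls. Three fill levels define the measurements:

| measurement | administered (MBq) | spheres (kBq/ml) | background (kBq/ml) | SBR |
|---|---|---|---|---|
| SBR1 | 34.2 | 36.8 | 2.3 | 16.0 |
| SBR2 | 53.6 | 28.9 | 4.8 | 6.0 |
| SBR3 | 124.8 | 20.9 | 9.0 | 2.3 |

The reference SUV is `concentration / (administered / weight)` with the
phantom weight 6.595 kg (1 g/ml), giving 7.1 / 3.6 / 1.1.

Spheres are coplanar in the central slice, near the radial centre of the
field of view: the largest on a 45-mm ring, the others on a 60-mm ring at
equal azimuthal slots, largest opposite second-largest. This keeps every
surface-to-surface gap above 15 mm and — deliberately — keeps the largest
sphere's background-estimation shell inside the cylinder; a single ring
wide enough to separate the spheres would push that shell through the
cylinder wall. Positions are configurable.

Images are generated on the scanner grid: 200 × 200 in-plane with
4.1 × 4.1-mm voxels and 3- or 5-mm slices, voxel-centre coordinate
convention (the centre of voxel (i,j,k) is `origin + (i+½, j+½, k+½)·v`).

## Reconstruction emulation

Tomographic reconstruction itself is out of scope. Its net effect on the
image is emulated by linear filtering of the painted ground truth:

1. **Painting.** Each voxel value is the exact volume-weighted mixture of
   sphere, wall (zero) and background concentrations; boundary voxels are
   resolved by `supersample³` sub-voxel sampling (cylinder edge
   separably in 2D). Total painted activity matches the analytic region
   volumes to well under 0.5% at supersample 4.
2. **Blur / ringing.** The image is convolved with an isotropic Gaussian
   PSF of width `psf_fwhm`, optionally sharpened by a
   difference-of-Gaussians (DoG) kernel
   `(1+α)·G(fa') − α·G(fb')` (branch FWHMs combine the PSF and kernel in
   quadrature), then smoothed by the routine 2-mm Gaussian post-filter.
   With α = 0 this is plain blur; with α > 0 it produces the
   overshoot/undershoot pattern of resolution-recovery algorithms. The
   DoG choice is what makes the generator testable: the resulting radial
   profile has a closed form (`dog_ringing_profile`), so every downstream
   stage has an analytic oracle. By linearity the absolute overshoot
   scales with the edge jump (S − B), which automatically reproduces the
   observed decline of Gibbs artifacts with falling SBR.
3. **Sampling model.** Convolution is evaluated in the frequency domain
   on a zero-padded grid (padding ≥ 4× the largest kernel FWHM; no
   wrap-around, mass conserved exactly at DC). Painted voxels are volume
   averages, i.e. box-filtered point samples; reconstructed PET voxels
   are better modelled as point estimates of a smooth field. The voxel
   box transfer function is therefore divided out (default; gain ≤ 1.6
   within the representable band). Residual spectral folding from
   sampling the sharp edge at 4.1 mm still biases fitted FWHM by about
   −0.2 mm; `simulate_reconstructed(..., oversample=3)` paints and
   convolves on a 3× finer grid and decimates to the scanner voxel
   centres, reducing the bias to ≈0.01 mm at 27× the convolution volume.
   Fidelity studies (oracle tests) use oversample 3; the factorial
   experiment, which asserts only orderings, uses 1.
4. **Noise.** Optional Gaussian noise with variance proportional to the
   local mean (`sd = cv·sqrt(v·v̄)`, v̄ the sphere concentration) — a
   surrogate for reconstructed-image noise, not a sinogram-level Poisson
   model. Seeded and bit-reproducible.

The default emulation labels span the algorithm families: two pure-blur
settings (`fbp_like` 6.0 mm constant; `osem_like` 5.0→6.0 mm with
falling SBR) and two ringing settings (`psf_like`, `psf_tof_like`) with
per-measurement (psf_fwhm, α) declining from (4.0, 1.5) at SBR1 to
(6.0, 0.5) at SBR3. The contrast dependence emulates the
contrast-dependent convergence of iterative reconstruction; α = 1.5 was
chosen so the 70-mm sphere's GA at SBR1 is ≈6%, the scale reported for
PSF reconstructions. These are emulations of families, not calibrations
of a particular scanner; all parameters are configuration.

## Radial profiles and resolution

For each sphere the centre is refined to the intensity-weighted centroid
of voxels ≥ 50% of the local maximum, then every voxel centre within
`r_max` is converted to an (r, value) sample (`r_max` = nominal radius +
4× expected FWHM, capped at half the gap to the nearest neighbour and at
the cylinder wall). The spatial resolution is the FWHM of the Gaussian
PSF in the cold-wall profile model

    f(r) = S·P(r; R, σ) + B·[1 − P(r; R+d, σ)],

where `P` is the closed-form profile of a unit sphere convolved with a
3D Gaussian,

    P(r) = ½[erf((R+r)/√2σ) + erf((R−r)/√2σ)]
           − σ/(r√2π)·[e^−(R−r)²/2σ² − e^−(R+r)²/2σ²],

with the removable r→0 singularity evaluated by its analytic limit below
r = 10⁻⁶σ. The formula is validated against a brute-force voxelised 3D
convolution (0.25-mm grid) to sup-norm < 10⁻³ before use. The fit is
unweighted bounded least squares (trust-region) over (S, B, R, FWHM)
with the wall fixed at 1.2 mm, on the unbinned samples (binning is used
only for the spline and plots); initialisation S = 99th percentile,
B = median beyond R + 3 voxels, R = nominal, FWHM = 1.5 voxels; up to
three seed-jittered restarts on non-convergence, which is flagged, not
raised. Samples are voxel values while the model is pointwise; with the
oversampled generator this voxelisation bias is negligible, and at the
plain scanner grid it stays within the stated recovery tolerances.

## Gibbs-artifact magnitude

A count-weighted cubic smoothing spline (smoothing chosen by generalised
cross-validation, rescalable by a multiplier) is fitted to the 1-mm
binned profile. A⁺ is the spline's local maximum closest to the fitted
sphere boundary; A⁻ is the curve minimum interior to that maximum. For a
single Gaussian-type ripple the interior profile rises monotonically
from the plateau to the overshoot, so the relevant minimum can sit at
the plateau rather than at a strict sign change of the derivative — with
oscillatory (multi-ripple or noisy) profiles the rule reduces to the
ordinary "minimum immediately inside the maximum". Then

    GA = (A⁺ − A⁻) / (A⁺ + A⁻),

reported in percent. GA is flagged non-determinable when the fitted
radius is below 2×FWHM (opposite-edge ringing overlaps, which would
underestimate GA — in practice this restricts GA to the 50- and 70-mm
spheres), when no interior maximum exists (monotone pure-blur profiles),
or when A⁺ − A⁻ ≤ 1% of A⁺ (an order of magnitude below the artifact
scale of interest; spline ripples on noise-free blur profiles sit well
below this floor). Extrema are located on a 0.05-mm evaluation grid.

## Delineation and quantification

All methods operate in a per-sphere ROI box (margin 2×FWHM plus shell
allowance); in the multi-sphere phantom the hottest-voxel search is
seeded to the sphere's nominal extent so an equal-activity neighbour
grazing the box corner cannot hijack the mask. Masks are 26-connected
components containing the hottest voxel; argmax ties break to the lowest
linear index.

- **t40/t50/t60**: threshold at the given fraction of the measured
  maximum. A mask touching the ROI boundary means the threshold fell
  below the local background; the result is flagged not applicable
  (at SBR3 this reproduces "t40 not applicable").
- **tBC**: initial mask at 50% of the maximum; iterate {background =
  mean over the shell of voxels at 26-connected dilation distance
  (3, 6] voxels from the mask; re-threshold at B + 0.39·(max − B)} until
  the mask is stable (typically ≤ 3 iterations noise-free; oscillation
  at the iteration cap is flagged). The result is independent of the
  initial fraction whenever the initial threshold exceeds the
  background. The shell geometry of the original implementation is not
  published; ours is explicit configuration.
- **SUV**: concentration / (administered activity / phantom weight);
  SUVmax/SUVmean over the mask; signed deviations
  100·(measured − reference)/reference. MTV reference in the synthetic
  experiment is the exact geometric volume of the simulated sphere (the
  printed insert volumes 13.6/33.3/64.7/176.8 ml, which are measured
  fill volumes 2–3% away from the geometric values, remain available as
  `ReferenceValues` defaults for real data).

## What the synthetic experiment does and does not show

The generator reproduces: partial-volume loss and its growth for smaller
spheres; cold-wall delineation bias; SBR-dependent Gibbs overshoot with
its SUVmax inflation and threshold-volume shrinkage; threshold
ballooning when a fixed threshold approaches the background; and tBC's
background-corrected stability. It does not model tomographic noise
correlations, non-Gaussian or spatially varying PSFs, scatter/randoms,
attenuation, or the oscillatory (sinc-like) ripple structure of real
resolution-recovery kernels — real PSF reconstructions inflate SUVmax
by noise peaking on top of the overshoot, which a noise-free emulation
cannot reproduce numerically. Directional conclusions (orderings across
algorithms and SBRs) are therefore the claim; the published deviation
magnitudes from scanner data are not reproducible on synthetic images
and are not asserted.

One consequence shapes the directional test: at SBR3 the fixed t50
threshold of a pure-blur image sits barely above background, so its mask
balloons (+14–22% noise-free); this background-proximity effect, not
ringing, dominates fixed-threshold gaps at low contrast. The
contrast-dependence ("effects shrink at low SBR") is therefore asserted
on the background-corrected method, where the simulation reproduces the
published convergence of PSF-like and conventional reconstructions at
SBR3, while "volumes biased low with ringing" is asserted on t40/t50 at
SBR1 where thresholds are safely above background.

## Numerical choices

- Geometry validation rejects overlapping spheres and spheres crossing
  the cylinder wall or end caps.
- Painting supersample default 4 (interior-volume change < 0.5% when
  doubled); profile bins 1 mm; spline evaluation grid 0.05 mm.
- Fit bounds: S, B ≥ 0; R ∈ [0.5, 1.5]× nominal; FWHM ∈ [0.5 voxel,
  4× nominal radius].
- All randomness (noise seeds, restart jitter) derives from explicit
  seeds; identical configuration ⇒ bit-identical results tables.
- Degenerate inputs: constant neighbourhoods raise a degenerate-input
  error in centre refinement; empty masks and non-positive references
  raise; non-determinable GA and non-applicable segmentations are
  result states, not errors.

## Problem sizes

Default factorial experiment: 3 measurements × 4 emulation labels × 2
slice thicknesses × 4 spheres (~25 s per slice arm on one CPU). Oracle
and recovery tests use single-sphere grids (≈ 40–60 voxels per axis,
oversample 3) and a 0.25-mm brute-force convolution oracle with draws
R ∈ [6, 15] mm, σ ∈ [1, 3] mm.
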