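# petphanq

Quantitative analysis of PET sphere-phantom images: spatial resolution,
Gibbs (edge-ringing) artifacts, SUV and threshold-based volume
delineation — with a synthetic phantom-image generator so the whole
pipeline runs and is tested without any scanner data.

## Who this is for

PET physicists and image-analysis developers studying how reconstruction
choices — in particular resolution-recovery ("PSF") and time-of-flight
algorithms — affect quantitative measures (SUVmax, SUVmean, metabolic
tumour volume) at different signal-to-background ratios (SBR). The
package reproduces the phantom-side methodology: a 20-cm cylinder
(6,595 ml) with four cold-wall spheres (inner diameters 29.9–69.7 mm)
filled at three contrasts (SBR ≈ 16:1, 6:1, 2.3:1), imaged on a
200 × 200 grid with 4.1 × 4.1 mm voxels and 3- or 5-mm slices.

## The model

**Resolution.** The radial activity profile of a homogeneous sphere of
radius R (activity S, cold wall d, background B) blurred by an isotropic
3D Gaussian PSF has the closed form

    f(r) = S·P(r; R, σ) + B·[1 − P(r; R + d, σ)]
    P(r) = ½[erf((R+r)/√2σ) + erf((R−r)/√2σ)]
           − σ/(r√2π)·[e^−(R−r)²/2σ² − e^−(R+r)²/2σ²]

with FWHM = 2√(2 ln 2)·σ. Fitting f to the unbinned 3D radial samples
around each sphere (wall fixed at its known 1.2 mm) estimates the
effective spatial resolution in the reconstructed image.

**Gibbs artifacts.** A count-weighted smoothing spline through the
binned profile yields the edge overshoot A⁺ (local maximum nearest the
boundary) and the interior level A⁻; the artifact magnitude is
GA = (A⁺ − A⁻)/(A⁺ + A⁻), determinable only for spheres large enough
that opposite-edge ringing does not overlap (the 50- and 70-mm spheres).

**Quantification.** SUV = concentration / (administered activity /
phantom weight); delineation by fixed thresholds (t40/t50/t60, % of the
measured maximum) and by iterative background-corrected thresholding
(tBC: estimate the local background from a shell around the mask,
re-threshold at B + 0.39·(max − B) until stable). Results are reported
as signed relative deviations from the reference SUV and volumes.

**Simulation.** Ground truth is painted by exact sub-voxel mixing;
reconstruction is emulated by Gaussian blur plus an optional
difference-of-Gaussians sharpening whose edge overshoot mimics
resolution-recovery reconstructions — and whose radial profile has a
closed form, so every stage of the pipeline is testable against an
analytic oracle. See `docs/methods.md` for the full model description
and its limitations.

## Worked example

```python
import numpy as np
from petphanq import (
    GridSpec, PhantomSpec, ReconEmulation, SphereSpec,
    simulate_reconstructed, extract_profile, bin_profile, fit_profile,
    smooth_profile, gibbs_magnitude, roi_for_sphere, segment_fixed,
    segment_tbc, to_suv, suv_stats, signed_deviation,
)

# 70 mm cold-wall sphere at SBR 16, PSF-like emulation with edge ringing
sphere = SphereSpec(center=(0, 0, 0), inner_diameter=69.7)
spec = PhantomSpec(sphere_concentration=36.8, background_concentration=2.3,
                   administered_activity=34.2, spheres=(sphere,))
recon = ReconEmulation(psf_fwhm=4.0, ringing_alpha=1.5,
                       ringing_fwhm_pair=(0.0, 6.0), post_filter_fwhm=2.0)
grid = GridSpec(shape=(41, 41, 45), voxel_size=(4.1, 4.1, 3.0))
img = simulate_reconstructed(spec, grid, recon, oversample=3)

profile = extract_profile(img, sphere.center, r_max=sphere.inner_radius + 18)
fit = fit_profile(profile, nominal_radius=sphere.inner_radius, voxel_size=3.0)
print(f"fitted FWHM      : {fit.params.fwhm:.2f} mm")

curve = smooth_profile(bin_profile(profile, 1.0))
ga = gibbs_magnitude(curve, fit.params.radius, fit.params.fwhm)
print(f"Gibbs artifact GA: {ga.ga_percent:.1f} %")

suv_img = to_suv(img, administered=34.2, weight=6.595)
roi = roi_for_sphere(grid, sphere.center, sphere.outer_radius, margin_mm=30.0)
for seg in (segment_fixed(img, roi, 0.50), segment_tbc(img, roi)):
    suv_max, suv_mean = suv_stats(suv_img, seg)
    dmtv = signed_deviation(seg.mtv, sphere.inner_volume_ml)
    dsuv = signed_deviation(suv_max, 7.1)
    print(f"{seg.method:>3}: MTV {seg.mtv:6.1f} ml ({dmtv:+.1f} %)  "
          f"SUVmax {suv_max:.2f} ({dsuv:+.1f} %)  SUVmean {suv_mean:.2f}")
```

prints

```
fitted FWHM      : 2.52 mm
Gibbs artifact GA: 6.3 %
t50: MTV  176.1 ml (-0.7 %)  SUVmax 8.07 (+13.7 %)  SUVmean 7.11
tBC: MTV  179.1 ml (+1.0 %)  SUVmax 8.07 (+13.7 %)  SUVmean 7.05
```

Reading: the ringing emulation steepens the apparent edge, so the
fitted FWHM (2.5 mm) is well below the 4.5-mm pure-blur width of the
same chain; the overshoot registers as GA = 6.3% and inflates SUVmax
by ~14% over the reference SUV of 7.1, while SUVmean over the
delineated volume stays close to the reference — exactly the
behaviour pattern of resolution-recovery algorithms at high contrast.

The same pipeline runs factorially over measurements × emulations ×
slice thicknesses × spheres from the command line:

```sh
petphanq run --out results/ --seed 1        # full default experiment
petphanq simulate --out volumes/ --seed 1   # write NIfTI volumes + sidecars
petphanq report --in results/               # re-render summary tables
```

`run` writes per-cell records (CSV/JSON) plus summary tables of
resolution (mean (min to max) per emulation per SBR), GA for the two
largest spheres, and SUVmax/SUVmean/MTV deviations per method.

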