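# Methods

This note documents the models behind `sirtiq`: what the synthetic data
generator emulates, which parameters matter and why their defaults are what
they are, the numerical choices in the analysis stack, and what the package
deliberately does not model.

## Phantom model

The image-quality phantom is an elliptical water cylinder (transverse
semi-axes 150 mm × 115 mm, interior length 180 mm — the standard torso-shaped
IQ-phantom cross-section; all dimensions overridable) containing

* six coplanar fillable spheres, inner diameters 10, 13, 17, 22, 28, 37 mm,
  centered on a 57.2 mm-radius ring at 60° spacing, ascending diameter;
* a cylindrical low-density lung insert (50 mm diameter) on the long axis;
* a fillable background compartment (everything else inside the shell);
* optionally a 30 mm water-equivalent outer shell emulating an obese patient.

The phantom long axis is the grid y axis; the sphere plane is transverse
(z, x). Voxelization is by center-point inclusion on half-open extents with
boundary precedence sphere > lung > background > shell > outside, which makes
rasterization deterministic and test-stable. Voxelized sphere volumes
converge to the analytic volume as the grid refines (measured error < 2% at
1 mm and < 0.5% at 0.5 mm voxels for the 37 mm sphere).

Activity fillings assign one concentration to all spheres and one to the
background (lung insert, shell and exterior are cold). The packaged setups
(`sirtiq.setups`) are the measured concentrations of the three clinical-style
fillings per isotope — spheres-only ("extrahepatic deposition"), 8:1
("hypervascular tumor"), 4:1 ("moderate uptake") — at scan time. One ⁹⁹ᵐTc
8:1 repeat row carries a tabulated ratio (7.86) that cannot be reproduced
from its own concentration pair (419.6/44.6 = 9.41); it is retained but
flagged `consistent=False` and excluded from quantitative checks. Contrast
computations always use the *realized* ratio c_spheres/c_background, not the
nominal 8 or 4.

## Planar simulation

For one view (anterior/posterior = projection along ±y):

1. **Attenuated projection.** Each voxel's emission is attenuated by
   `exp(−∫μ dl)` along the view axis through phantom material
   (μ = ln2 / HVL; the lung insert attenuates at 0.3× water). Default water
   HVLs are the textbook narrow-beam values 45.9 mm (141 keV) and 39.6 mm
   (81 keV); their ratio (~1.16) is what drives the relative obese-phantom
   degradation of the two isotopes, and both are configurable.
2. **System blur** with an isotropic Gaussian of the camera's
   `system_fwhm_mm`, applied on the 256×256 pixel raster
   (pixel = FOV/256, FOV default 533.3 mm).
3. **Count scaling** such that, absent attenuation and dead time, the
   expected photopeak total equals `sensitivity × activity(MBq) × duration`.
   Default sensitivities are the measured planar photopeak values
   93.1 (⁹⁹ᵐTc/LEHR), 125.3 (⁹⁹ᵐTc/MELP) and 16.4 cps/MBq (¹⁶⁶Ho/MELP).
4. **Scatter model.** Detected photopeak counts are split into a primary
   share, a wide-Gaussian-kernel share (`scatter_fraction`, kernel FWHM
   80 mm) and a spatially uniform haze (`uniform_haze_fraction`) standing in
   for bremsstrahlung septal penetration and lead X-rays. The scatter-window
   image carries exactly the scatter term divided by the k-factor, so DEW
   subtraction with the configured k (0.5 ⁹⁹ᵐTc, 1.4 ¹⁶⁶Ho) removes the
   scatter identically in expectation — a closure property the tests verify
   to machine precision on noiseless images. Defaults: ⁹⁹ᵐTc 0.15 + 0.02;
   ¹⁶⁶Ho 0.30 + 0.35. The large ¹⁶⁶Ho haze is calibrated so the uncorrected
   apparent lung shunt of the 8:1 filling lands at the ~10–13% level
   characteristic of uncorrected ¹⁶⁶Ho planar imaging; with a small haze the
   scatter-correction mechanism has nothing to correct.
5. **Dead time**: one global paralyzable factor `exp(−τ·R_tot)` from the
   total incident rate in both windows — the whole-detector formulation of
   the paralyzable model, not a per-pixel effect. Default τ = 0; dead-time
   studies set it explicitly.
6. **Poisson sampling** per pixel with an explicit seed (bit-identical
   reproducibility given seed and configuration). Expectation mode
   (`sample_noise=False`) returns the real-valued expected images.

## SPECT volume surrogate

Tomographic projection and OSEM reconstruction are intentionally not modeled;
the analysis operates on reconstructed volumes, and a blur + noise surrogate
exposes the metric behaviors of interest (partial volume, noise–time scaling,
contrast stability) at desk scale:

1. blur the activity map with the system PSF, then with the 9 mm Gaussian
   post-reconstruction filter (so the effective resolution is
   √(system² + 9²));
2. add a residual scatter haze: `residual_scatter_fraction` times the 80 mm
   wide-blurred volume, representing scatter and reconstruction bias
   surviving the in-reconstruction correction — this is what puts counts in
   the cold lung insert (ΔN_lung ≈ 18% ⁹⁹ᵐTc, ≈ 27% ¹⁶⁶Ho at defaults);
3. inject noise: a white Gaussian field smoothed with the post-filter kernel
   and renormalized to unit variance (reconstructed noise is correlated on
   the filter scale, which keeps local-maximum statistics realistic), scaled
   to SD `σ_rel · sqrt(value · ref_level)` per voxel, where
   `σ_rel = noise_scale/√N_detected` and
   `N_detected = sensitivity × activity × t_proj × n_proj`. The
   `sqrt(value)` weighting mirrors Poisson statistics — hot spheres are
   relatively quieter than background — and is what keeps CRC stable across
   projection times while `CV_BG ∝ t^(−1/2)` holds exactly. A plain
   multiplicative (uniform relative) noise model was tried first and moved
   CRC by up to ~8 points across 5–20 s projection times purely through
   threshold inflation; the Poisson weighting reduces this to < 3 points,
   matching the observed count-statistics insensitivity of contrast recovery.

Calibrated defaults: `system_fwhm_mm` = 8.24 / 11.11 / 12.25 mm and
`noise_scale` = 785 / 815 / 1285 for ⁹⁹ᵐTc-LEHR / ⁹⁹ᵐTc-MELP / ¹⁶⁶Ho-MELP,
chosen so the analysis reports FWHM ≈ 12.2 / 14.3 / 15.2 mm and
CV_BG ≈ 7.6 / 6.8 / 18% on the standard 20 s × 120-projection 8:1
acquisition. These are operating-point calibrations, not physics
predictions: the simulator makes the reported tables a self-consistency
surface. The obese shell adds 0.04 mm of PSF width per mm of shell (a
source–detector-distance proxy) and enters the planar attenuation integrals
directly.

## Segmentation and ROIs

* **Spheres**: 3D isocontour at the background-adapted 50% threshold
  `T = bg + 0.5·(P − bg)`, with P the maximum in a ball of 1.5× the nominal
  diameter around the expected center and `bg` the mean over the three
  background cylinders, computed *before* any sphere segmentation (breaking
  the circular dependence). The mask is the 26-connected component ≥ T
  (ties included) containing the hottest voxel. If P does not exceed bg the
  sphere is reported "not evaluable" rather than silently dropped —
  the very-noisy-image outcome. Both the 0.5 factor and the search ball are
  configurable. The segmentation is invariant under global intensity
  scaling. Note that for spheres much smaller than the blur the 50% contour
  tracks the half-maximum of the *blurred* profile, so the mask volume grows
  with blur even as the recovered contrast shrinks; partial volume manifests
  in the contrast, not the contour volume.
* **Background/lung VOIs**: three 45 mm × 150 mm cylinders parallel to the
  phantom axis at ring radius 100 mm, angles 30°/150°/210° (between the
  sphere ring and the wall, on the wide side of the ellipse), and a central
  30 mm × 130 mm lung cylinder. Placement is validated against the geometry
  (inside the compartment, clear of spheres and insert).
* **Planar ROIs**: the "liver" ROI is the projected body outline eroded by
  one pixel; the "lung" ROI is an equal-area full-width rectangle starting
  10 mm above the body projection. Apparent lung shunt combines conjugate
  views by geometric mean per ROI before the ratio (standard conjugate-view
  practice; single views pass through).

## Metrics

CRC, ΔN_lung, CV_BG and CNR as defined in the README. σ_BG is the
*population* SD over all voxels pooled across the three background cylinders
(the sample/population difference is negligible at VOI sizes; fixed for
determinism, configurable in spirit by pooling your own VOIs). All four are
invariant under global intensity scaling; CNR is additionally unchanged by a
constant offset. CNR is reported as `None` on noiseless images (σ_BG = 0),
and CRC as `None` for the spheres-only filling (ratio undefined).

## Resolution

The radial profile around a sphere center (1.2 mm bins, default radius 2×
the nominal sphere radius) is fitted with the closed-form radial profile of
a uniform ball (radius ρ, amplitude a, background b) convolved with an
isotropic 3D Gaussian σ; FWHM = 2√(2 ln 2)·σ. The closed form was verified
against direct numerical 3D convolution (max deviation ~1.5e-3 at 0.8 mm
voxels). Free parameters (a, b, ρ, σ); ρ starts at the nominal radius, σ at
the 25–75% edge width / 1.349; bins are weighted by √(voxel count); bounded
least squares with two jittered restarts (fixed restart seed). Estimates at
or below 1.2× the voxel size are flagged resolution-limited. The
per-acquisition FWHM is the mean over the 28 and 37 mm spheres (smaller
spheres couple ρ and σ too strongly); the two estimates agree within 1 mm on
default simulations, and known blur kernels of 8–18 mm are recovered within
0.1 mm noiseless and 0.35 mm at default noise (20-seed medians). A
moment-based edge-derivative estimate is provided as a rough cross-check
only.

## Dead time

The paralyzable model is fitted to (activity, count-rate) series by weighted
least squares with Poisson-motivated weights 1/max(C, 1) on squared
residuals (the fitting weights are a package choice; unweighted fits differ
negligibly on well-sampled series). α initializes from the low-activity
third's slope, τ at 0, both bounded below at zero; a strictly linear series
pins τ to ~0 with a warning since the threshold is then unbounded. Noiseless
model-generated series are recovered to 1e-6 relative; Poisson series at
300 s/point recover α and τ to ≪1%. The count-loss inversion
`A(p) = −ln(1−p)/(ατ)` matches brute-force root finding to 1e-6, and the
peak-rate location 1/(ατ) was checked against a dense grid search.

## DEW correction and its small-count bias

`corrected = max(photopeak − k·scatter_window, 0)`, element-wise, clamped
*before* any ROI summation; negative corrected pixels are not propagated.
This clamping has a quantifiable consequence: in an activity-free region
where the photopeak pixel is Pois(μ) scatter and the scatter window
estimates μ/k, the corrected pixel expectation is E[max(X, 0)] ≈
0.4·√(μ(1+k)) rather than 0. Summed over a large lung ROI at realistic
planar count levels (~10⁶ photopeak counts, μ of a few per pixel), this
leaves a residual apparent lung shunt of a few percentage points even though
the correction removes the scatter *exactly in expectation* — the corrected
LLS approaches the scatter-free value only as counts grow or the ROI
shrinks. Users comparing corrected LLS against a scatter-free reference
should expect this floor; the uncorrected-versus-corrected contrast (≈10% →
≈5% on the default ¹⁶⁶Ho 8:1 filling) is the robust signal.

## What the generator does not emulate

Monte-Carlo photon transport, collimator hole geometry and septal
penetration physics, energy spectra, tomographic projection/reconstruction
(iteration-count effects appear only through the configurable PSF and noise
scale), CT-based attenuation correction (SPECT surrogates are implicitly
attenuation-corrected; planar images are not), phantom wall thickness,
sphere stems, and scanner file formats. Passing tests therefore demonstrate
the *internal consistency* of the metric stack and the qualitative
mechanisms (partial volume, count statistics, scatter correction, dead
time), not absolute agreement with any particular scanner.

## Problem sizes

The default grid is 126×80×152 voxels at 2.4 mm (~1.5M voxels). Stochastic
checks use seed medians sized for desk-scale runs: 20 replicates for
dead-time recovery and lung-shunt medians, 10–20 seeds per blur kernel for
FWHM recovery, 5–6 seeds per projection time for the count-statistics
scans. The complete test suite runs in about a minute; the acceptance script
in about half a minute.
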