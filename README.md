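# sirtiq

Synthetic NEMA-IQ-phantom simulation and gamma-camera image-quality analysis
for SIRT (Selective Internal Radiation Therapy) pre-treatment imaging.

Before radioembolization of liver tumors, a scout dose — ⁹⁹ᵐTc-labeled
particles or a small ¹⁶⁶Ho microsphere activity — is imaged with a gamma
camera to estimate the liver–lung shunt and predict the intrahepatic activity
distribution. The two isotopes image very differently: ¹⁶⁶Ho emits its 81 keV
gamma with only 6.7% probability and rides on a heavy bremsstrahlung
continuum, so its planar and SPECT images are noisier, blurrier and more
scatter-contaminated than ⁹⁹ᵐTc's. `sirtiq` packages the full quantitative
stack used to characterize that difference on a torso-shaped image-quality
phantom (six fillable spheres of 10–37 mm inner diameter on a ring, a cold
cylindrical lung insert, a fillable background compartment, and an optional
3 cm water-equivalent "obese" shell), together with a desk-scale synthetic
data generator so every metric can be exercised end to end without scanner
data.

## What it computes

With N̄ the mean counts in a volume of interest (VOI), σ_BG the pooled
standard deviation over three 45 mm × 150 mm background cylinders, and R the
realized sphere-to-background activity concentration ratio:

* **Contrast recovery coefficient** per hot sphere,
  `CRC = 100% · (N̄_S/N̄_BG − 1) / (R − 1)`, on spheres delineated by a 3D
  isocontour at the background-adapted 50% threshold
  `T = bg + 0.5 (P − bg)`;
* **Image noise** `CV_BG = 100% · σ_BG / N̄_BG` and **detectability**
  `CNR = (N̄_S − N̄_BG) / σ_BG`;
* **Lung count error** `ΔN_lung = 100% · N̄_lung / N̄_BG` in a 30 mm × 130 mm
  cylinder inside the cold insert;
* **Apparent lung shunt** from planar conjugate views,
  `LLS = 100% · C_lung / (C_lung + C_liver)`, with and without
  dual-energy-window (DEW) scatter correction
  `corrected = max(photopeak − k · scatter_window, 0)` (k = 0.5 for ⁹⁹ᵐTc,
  1.4 for ¹⁶⁶Ho);
* **Spatial resolution** as the FWHM of the effective point-spread function,
  fitted from radial profiles through the largest spheres with the analytic
  uniform-ball ⊛ 3D-Gaussian model;
* **Dead time**: weighted fits of the paralyzable detector model
  `C(A) = α·A·e^(−τ·α·A)` and the closed-form activity at a given count loss
  `A(p) = −ln(1 − p)/(α·τ)`.

The synthetic generator renders 256×256 planar count images in photopeak and
scatter windows (attenuated projection, system blur, measured-sensitivity
count scaling, wide-kernel scatter plus uniform bremsstrahlung haze,
paralyzable dead time, Poisson sampling) and SPECT-like volumes on a 2.4 mm
grid (PSF + 9 mm post-filter blur, residual scatter haze, correlated
Poisson-weighted noise). See `docs/methods.md` for the model and its limits.

## Worked example

```python
import sirtiq

geometry = sirtiq.build_geometry("standard")
labels   = sirtiq.rasterize(geometry, sirtiq.default_grid())
rec      = sirtiq.get_setup("ho166", "8to1")          # packaged filling
activity = sirtiq.assign_activity(labels, rec.setup)

volume = sirtiq.simulate_spect(activity, sirtiq.default_camera("ho166"),
                               sirtiq.ISOTOPES["ho166"],
                               time_per_projection_s=20.0, n_projections=120,
                               seed=42)
result  = sirtiq.analyze_volume(volume, geometry, rec.setup)
fwhm, _ = sirtiq.estimate_volume_fwhm(volume, geometry)

print(f"realized ratio R = {sirtiq.realized_ratio(rec.setup, ndigits=2)}")
print(f"FWHM = {fwhm:.1f} mm, CV_BG = {result.cv_bg_percent:.1f} %, "
      f"dN_lung = {result.lung_error_percent:.1f} %")
for d, s in sorted(result.per_sphere.items()):
    print(f"  sphere {d:4.0f} mm: CRC = {s.crc_percent:5.1f} %, CNR = {s.cnr:5.1f}")
```

prints

```
realized ratio R = 8.39
FWHM = 14.3 mm, CV_BG = 17.6 %, dN_lung = 26.4 %
  sphere   10 mm: CRC =  10.8 %, CNR =   4.5
  sphere   13 mm: CRC =  10.1 %, CNR =   4.2
  sphere   17 mm: CRC =  15.7 %, CNR =   6.6
  sphere   22 mm: CRC =  34.3 %, CNR =  14.4
  sphere   28 mm: CRC =  42.1 %, CNR =  17.7
  sphere   37 mm: CRC =  52.7 %, CNR =  22.1
```

— a ¹⁶⁶Ho acquisition at the 8:1 sphere-to-background filling: ~15 mm
resolution, ~18% background noise, strong partial-volume loss of contrast
below ~22 mm sphere diameter, and residual counts in the cold lung insert
from the scatter/bremsstrahlung haze. Swapping in `"tc99m"` shows the
sharper, quieter ⁹⁹ᵐTc picture (≈12 mm, ≈7.5% noise, CNR roughly 3× higher).

A command-line front end mirrors the library:

```bash
sirtiq fixtures                         # packaged activity setups as CSV
sirtiq simulate experiment.yaml out/    # render an experiment to NIfTI + sidecars
sirtiq analyze out/                     # report.csv / report.json
sirtiq deadtime-fit rates.csv           # paralyzable fit + count-loss thresholds
```

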