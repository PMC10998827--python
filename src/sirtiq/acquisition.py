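"""Forward simulation of planar count images and SPECT-like volume surrogates.

The planar simulator models the full detection chain at desk scale: attenuated
parallel projection, system blur, count-rate scaling via the measured planar
sensitivity, a two-component scatter model (a wide Gaussian scatter kernel
plus a uniform "haze" standing in for bremsstrahlung/septal-penetration
contamination), paralyzable dead-time loss, and Poisson counting noise.  Two
energy-window images are produced per view (photopeak and scatter window),
constructed such that dual-energy-window subtraction with the configured
k-factor removes the scatter term exactly in expectation.

The SPECT "reconstruction" is a surrogate: the activity map is blurred with
the system PSF and a 9 mm Gaussian post-filter, a residual scatter haze is
added, and spatially correlated multiplicative noise is injected with relative
standard deviation inversely proportional to the square root of the total
detected counts.  Tomographic projection/OSEM reconstruction is deliberately
not modeled; the surrogate exposes the metric behaviors (partial volume,
noise-vs-time scaling, contrast stability) that the analysis stack measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import VoxelGrid
from .phantom import LABEL_LUNG, LABEL_OUTSIDE, ActivityVolume, LabelVolume

__all__ = [
    "IsotopeModel",
    "CameraModel",
    "PlanarImage",
    "SpectVolume",
    "ISOTOPES",
    "default_camera",
    "simulate_planar",
    "simulate_spect",
    "matched_time",
    "decay_correct",
    "apply_correlated_noise",
    "attenuation_map",
    "FWHM_TO_SIGMA",
]

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian.
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

#: Relative linear attenuation of the low-density lung insert vs. water.
LUNG_DENSITY_FACTOR = 0.3


@dataclass(frozen=True)
class IsotopeModel:
    """Physical decay/emission properties of an imaging isotope."""

    name: str
    half_life_h: float
    gamma_energy_keV: float
    emission_probability: float
    hvl_water_mm: float

    def __post_init__(self) -> None:
        if self.half_life_h <= 0 or self.gamma_energy_keV <= 0 or self.hvl_water_mm <= 0:
            raise ValueError("isotope physical constants must be positive")
        if not 0 < self.emission_probability <= 1:
            raise ValueError("emission probability must be in (0, 1]")

    @property
    def mu_water_per_mm(self) -> float:
        return math.log(2.0) / self.hvl_water_mm


# Half-lives and gamma lines of the two SIRT imaging isotopes.  The water
# half-value layers are textbook narrow-beam values at the respective gamma
# energies (their ratio, ~1.16, is what governs the relative obese-phantom
# degradation); both are configurable.
ISOTOPES: dict[str, IsotopeModel] = {
    "tc99m": IsotopeModel("Tc-99m", half_life_h=6.0, gamma_energy_keV=141.0,
                          emission_probability=0.89, hvl_water_mm=45.9),
    "ho166": IsotopeModel("Ho-166", half_life_h=26.8, gamma_energy_keV=81.0,
                          emission_probability=0.067, hvl_water_mm=39.6),
}


@dataclass(frozen=True)
class CameraModel:
    """Isotope/collimator-specific camera operating point.

    ``sensitivity_cps_per_MBq`` is the planar photopeak sensitivity;
    ``system_fwhm_mm`` the Gaussian system PSF width; ``scatter_fraction`` and
    ``uniform_haze_fraction`` the shares of detected photopeak counts carried
    by the wide-kernel scatter term and by the uniform haze (their sum must be
    < 1, the remainder being primary counts); ``k_factor`` the dual-energy
    window scatter calibration factor; ``dead_time_tau_s`` the paralyzable
    dead time; ``residual_scatter_fraction`` the post-correction scatter/bias
    haze of the volume surrogate; ``noise_scale`` the calibration constant of
    the surrogate's count-statistics noise model.
    """

    collimator: str  # 'LEHR' | 'MELP'
    sensitivity_cps_per_MBq: float
    system_fwhm_mm: float
    scatter_fraction: float = 0.0
    scatter_kernel_fwhm_mm: float = 80.0
    uniform_haze_fraction: float = 0.0
    dead_time_tau_s: float = 0.0
    k_factor: float = 1.0
    residual_scatter_fraction: float = 0.0
    noise_scale: float = 700.0

    def __post_init__(self) -> None:
        if self.collimator not in ("LEHR", "MELP"):
            raise ValueError(f"collimator must be LEHR or MELP, got {self.collimator!r}")
        if self.sensitivity_cps_per_MBq <= 0 or self.system_fwhm_mm <= 0:
            raise ValueError("sensitivity and system FWHM must be positive")
        if not 0 <= self.scatter_fraction < 1 or not 0 <= self.uniform_haze_fraction < 1:
            raise ValueError("scatter fractions must be in [0, 1)")
        if self.scatter_fraction + self.uniform_haze_fraction >= 1:
            raise ValueError("scatter_fraction + uniform_haze_fraction must be < 1")
        if self.dead_time_tau_s < 0 or self.k_factor <= 0:
            raise ValueError("dead time must be >= 0 and k-factor > 0")

    @property
    def primary_fraction(self) -> float:
        return 1.0 - self.scatter_fraction - self.uniform_haze_fraction


# Default operating points.  Sensitivities are the measured planar photopeak
# sensitivities of the three isotope/collimator combinations.  System FWHM
# values are calibrated such that the resolution module reports ~12.2 mm
# (Tc-99m/LEHR), ~14.3 mm (Tc-99m/MELP) and ~15.2 mm (Ho-166/MELP) after the
# 9 mm post-filter: system = sqrt(reported^2 - 9^2).  Scatter fractions and
# the Ho-166 haze reflect the heavy bremsstrahlung contamination of the 81 keV
# window; k-factors are the isotope-specific DEW calibration values.
_DEFAULT_CAMERAS: dict[tuple[str, str], CameraModel] = {
    ("tc99m", "LEHR"): CameraModel(
        collimator="LEHR", sensitivity_cps_per_MBq=93.1, system_fwhm_mm=8.24,
        scatter_fraction=0.15, uniform_haze_fraction=0.02, k_factor=0.5,
        residual_scatter_fraction=0.25, noise_scale=785.0),
    ("tc99m", "MELP"): CameraModel(
        collimator="MELP", sensitivity_cps_per_MBq=125.3, system_fwhm_mm=11.11,
        scatter_fraction=0.15, uniform_haze_fraction=0.02, k_factor=0.5,
        residual_scatter_fraction=0.30, noise_scale=815.0),
    ("ho166", "MELP"): CameraModel(
        collimator="MELP", sensitivity_cps_per_MBq=16.4, system_fwhm_mm=12.25,
        scatter_fraction=0.30, uniform_haze_fraction=0.35, k_factor=1.4,
        residual_scatter_fraction=0.40, noise_scale=1285.0),
}


def default_camera(isotope: str, collimator: str | None = None, **overrides) -> CameraModel:
    """Default camera model for an isotope/collimator pair.

    Tc-99m defaults to the LEHR collimator, Ho-166 to MELP.  Keyword overrides
    replace individual fields.
    """
    if collimator is None:
        collimator = "LEHR" if isotope == "tc99m" else "MELP"
    try:
        cam = _DEFAULT_CAMERAS[(isotope, collimator)]
    except KeyError:
        raise KeyError(f"no default camera for {isotope!r} with {collimator!r}") from None
    return replace(cam, **overrides) if overrides else cam


@dataclass(frozen=True)
class PlanarImage:
    """A 256x256 planar count image in one energy window.

    ``counts`` are integers after Poisson sampling; simulations run in
    expectation mode (``sample_noise=False``) return the real-valued expected
    counts instead.  Pixel centers along each image axis sit at
    ``(i - (n - 1) / 2) * pixel_size_mm``; rows index the world z axis
    ("above the phantom" = higher row coordinate) and columns the x axis.
    """

    counts: np.ndarray
    pixel_size_mm: float
    view: str  # 'anterior' | 'posterior'
    window: str  # 'photopeak' | 'scatter'
    duration_s: float

    def __post_init__(self) -> None:
        if self.view not in ("anterior", "posterior"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.window not in ("photopeak", "scatter"):
            raise ValueError(f"unknown window {self.window!r}")
        if self.pixel_size_mm <= 0 or self.duration_s <= 0:
            raise ValueError("pixel size and duration must be positive")
        if np.issubdtype(self.counts.dtype, np.integer) and (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """World (z, x) coordinates of pixel centers (1D arrays)."""
        n0, n1 = self.counts.shape
        z = (np.arange(n0) - (n0 - 1) / 2.0) * self.pixel_size_mm
        x = (np.arange(n1) - (n1 - 1) / 2.0) * self.pixel_size_mm
        return z, x


@dataclass(frozen=True)
class SpectVolume:
    """Reconstructed-volume surrogate: nonnegative values on a voxel grid."""

    grid: VoxelGrid
    values: np.ndarray
    window: str = "photopeak"
    time_per_projection_s: float | None = None
    n_projections: int | None = None

    def __post_init__(self) -> None:
        if tuple(self.values.shape) != self.grid.shape:
            raise ValueError("value array shape does not match grid shape")
        if (self.values < 0).any():
            raise ValueError("volume values must be nonnegative")

    @classmethod
    def from_activity(cls, activity: ActivityVolume) -> "SpectVolume":
        """Wrap an activity map as an ideal (noise- and blur-free) volume."""
        return cls(activity.grid, activity.concentration_kBq_per_ml.astype(float))


def matched_time(t_ref_s: float, p_ref: float, p_other: float) -> float:
    """Acquisition time matching count statistics across emission probabilities.

    Scales a reference time by the ratio of gamma emission probabilities:
    ``t_ref * p_other / p_ref``.  Report rounded to 0.1 s for tables.
    """
    if t_ref_s <= 0:
        raise ValueError("reference time must be positive")
    if not (0 < p_ref <= 1 and 0 < p_other <= 1):
        raise ValueError("emission probabilities must be in (0, 1]")
    return t_ref_s * p_other / p_ref


def decay_correct(activity_MBq: float, isotope: IsotopeModel, elapsed_h: float) -> float:
    """Physically decay an activity over ``elapsed_h`` hours."""
    if activity_MBq < 0:
        raise ValueError("activity must be nonnegative")
    return activity_MBq * 2.0 ** (-elapsed_h / isotope.half_life_h)


def attenuation_map(labels: LabelVolume, isotope: IsotopeModel) -> np.ndarray:
    """Linear attenuation coefficient (1/mm) per voxel.

    Water-equivalent everywhere inside the phantom (background, spheres,
    shell); the low-density lung insert attenuates at a reduced rate; zero
    outside.
    """
    mu = np.zeros(labels.grid.shape, dtype=np.float64)
    inside = labels.labels != LABEL_OUTSIDE
    mu[inside] = isotope.mu_water_per_mm
    mu[labels.labels == LABEL_LUNG] = isotope.mu_water_per_mm * LUNG_DENSITY_FACTOR
    return mu


def _attenuation_factors(mu: np.ndarray, dy_mm: float, view: str) -> np.ndarray:
    """Per-voxel survival factor for emission toward the detector.

    The path integral runs from each voxel center along +y (anterior) or -y
    (posterior): half the voxel's own attenuation plus the full attenuation of
    all voxels beyond it.
    """
    if view == "anterior":
        flipped = mu[:, ::-1, :]
        beyond = np.cumsum(flipped, axis=1) - flipped
        beyond = beyond[:, ::-1, :]
    else:
        beyond = np.cumsum(mu, axis=1) - mu
    path = (beyond + 0.5 * mu) * dy_mm
    return np.exp(-path)


def simulate_planar(
    activity: ActivityVolume,
    camera: CameraModel,
    isotope: IsotopeModel,
    view: str = "anterior",
    duration_s: float = 300.0,
    seed: int | None = 0,
    *,
    labels: LabelVolume | None = None,
    fov_mm: float = 533.3,
    n_pixels: int = 256,
    sample_noise: bool = True,
) -> tuple[PlanarImage, PlanarImage]:
    """Simulate one planar view; returns (photopeak, scatter-window) images.

    Pipeline: attenuated parallel projection along the view axis (if
    ``labels`` is given), system blur, count scaling (absent attenuation and
    dead time the expected photopeak total equals
    ``sensitivity x activity[MBq] x duration``), scatter-term formation,
    global paralyzable dead-time factor, Poisson sampling.

    The scatter-window image carries the scatter term divided by the camera's
    k-factor, so dual-energy-window subtraction with that k removes the
    scatter exactly in expectation.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if view not in ("anterior", "posterior"):
        raise ValueError(f"unknown view {view!r}")
    if sample_noise and seed is None:
        raise ValueError("a seed is required when Poisson sampling is enabled")

    grid = activity.grid
    conc = activity.concentration_kBq_per_ml
    if labels is not None:
        if labels.grid != grid:
            raise ValueError("label grid does not match activity grid")
        att = _attenuation_factors(attenuation_map(labels, isotope), grid.voxel_size_mm[1], view)
        weighted = conc * att
    else:
        weighted = conc

    # Parallel projection along y, deposited onto the pixel raster by nearest
    # pixel center.
    proj = weighted.sum(axis=1)  # (nz, nx)
    px = fov_mm / n_pixels
    zc, _, xc = grid.axis_coords()
    iz = np.floor(zc / px + n_pixels / 2.0).astype(int)
    ix = np.floor(xc / px + n_pixels / 2.0).astype(int)
    if iz.min() < 0 or iz.max() >= n_pixels or ix.min() < 0 or ix.max() >= n_pixels:
        raise ValueError("activity grid does not fit inside the planar field of view")
    flat_idx = (iz[:, None] * n_pixels + ix[None, :]).ravel()
    dep = np.bincount(flat_idx, weights=proj.ravel(), minlength=n_pixels * n_pixels)
    dep = dep.reshape(n_pixels, n_pixels)

    sigma_px = camera.system_fwhm_mm * FWHM_TO_SIGMA / px
    base = gaussian_filter(dep, sigma_px, mode="constant")

    # Count scaling: sensitivity is defined for an unattenuated source.
    expected_total = camera.sensitivity_cps_per_MBq * activity.total_activity_MBq() * duration_s
    unattenuated_sum = float(conc.sum())
    scale = expected_total / unattenuated_sum if unattenuated_sum > 0 else 0.0

    f_s, f_h = camera.scatter_fraction, camera.uniform_haze_fraction
    scatter_term = np.zeros_like(base)
    if f_s > 0:
        wide_sigma_px = camera.scatter_kernel_fwhm_mm * FWHM_TO_SIGMA / px
        scatter_term += f_s * gaussian_filter(base, wide_sigma_px, mode="constant")
    if f_h > 0:
        scatter_term += f_h * base.sum() / base.size

    photopeak = scale * (camera.primary_fraction * base + scatter_term)
    scatter_window = scale * scatter_term / camera.k_factor

    if camera.dead_time_tau_s > 0:
        incident_rate = (photopeak.sum() + scatter_window.sum()) / duration_s
        factor = math.exp(-camera.dead_time_tau_s * incident_rate)
        photopeak = photopeak * factor
        scatter_window = scatter_window * factor

    if sample_noise:
        rng = np.random.default_rng(seed)
        photopeak = rng.poisson(photopeak).astype(np.int64)
        scatter_window = rng.poisson(scatter_window).astype(np.int64)

    make = lambda arr, win: PlanarImage(arr, px, view, win, duration_s)  # noqa: E731
    return make(photopeak, "photopeak"), make(scatter_window, "scatter")


def apply_correlated_noise(
    values: np.ndarray,
    sigma_rel: float,
    rng: np.random.Generator,
    corr_sigma_vox: float,
    ref_level: float | None = None,
) -> np.ndarray:
    """Gaussian noise with a Gaussian correlation structure, Poisson-weighted.

    A white Gaussian field is smoothed with ``corr_sigma_vox`` and rescaled to
    unit variance, so neighbouring voxels remain correlated on the smoothing
    scale -- mimicking the texture of filtered reconstructions.  With
    ``ref_level`` given, the local noise SD is ``sigma_rel * sqrt(value *
    ref_level)`` (variance proportional to the signal, as for Poisson counting
    statistics), so a voxel at the reference level carries relative noise
    ``sigma_rel`` while hotter voxels are relatively quieter.  Without
    ``ref_level`` the noise is plain multiplicative (relative SD ``sigma_rel``
    everywhere).  Values are clipped at zero.
    """
    if sigma_rel < 0:
        raise ValueError("noise level must be nonnegative")
    if sigma_rel == 0:
        return values.copy()
    field = rng.standard_normal(values.shape)
    if corr_sigma_vox > 0:
        field = gaussian_filter(field, corr_sigma_vox, mode="reflect")
    field = (field - field.mean()) / field.std()
    if ref_level is None:
        noisy = values * (1.0 + sigma_rel * field)
    else:
        noisy = values + sigma_rel * np.sqrt(values * ref_level) * field
    return np.clip(noisy, 0.0, None)


def simulate_spect(
    activity: ActivityVolume,
    camera: CameraModel,
    isotope: IsotopeModel,
    time_per_projection_s: float = 20.0,
    n_projections: int = 120,
    seed: int | None = 0,
    *,
    post_filter_fwhm_mm: float = 9.0,
    sample_noise: bool = True,
    extra_blur_mm: float = 0.0,
    transmission: float = 1.0,
) -> SpectVolume:
    """Simulate a reconstructed-volume surrogate.

    The activity map is blurred with the system PSF (plus ``extra_blur_mm``
    for source-detector-distance effects such as the obese shell), then with
    the Gaussian post-reconstruction filter; a residual scatter haze (wide
    Gaussian of the blurred map, scaled by ``residual_scatter_fraction``) is
    added; finally correlated Poisson-weighted noise is injected whose
    relative SD at the typical in-phantom level is
    ``noise_scale / sqrt(N_detected)``, with ``N_detected`` equal to
    ``sensitivity x activity x time_per_projection x n_projections x
    transmission`` (see :func:`apply_correlated_noise`).
    """
    if time_per_projection_s <= 0:
        raise ValueError("time per projection must be positive")
    if n_projections < 1:
        raise ValueError("at least one projection is required")
    if not 0 < transmission <= 1:
        raise ValueError("transmission must be in (0, 1]")
    if sample_noise and seed is None:
        raise ValueError("a seed is required when noise injection is enabled")

    grid = activity.grid
    vox = np.asarray(grid.voxel_size_mm)
    fwhm = math.sqrt(camera.system_fwhm_mm**2 + extra_blur_mm**2) if extra_blur_mm else \
        camera.system_fwhm_mm
    sigma_sys = fwhm * FWHM_TO_SIGMA / vox
    sigma_post = post_filter_fwhm_mm * FWHM_TO_SIGMA / vox

    values = gaussian_filter(activity.concentration_kBq_per_ml.astype(float),
                             sigma_sys, mode="constant")
    values = gaussian_filter(values, sigma_post, mode="constant")

    if camera.residual_scatter_fraction > 0:
        wide_sigma = camera.scatter_kernel_fwhm_mm * FWHM_TO_SIGMA / vox
        values = values + camera.residual_scatter_fraction * gaussian_filter(
            values, wide_sigma, mode="constant")

    if sample_noise and camera.noise_scale > 0:
        n_detected = (camera.sensitivity_cps_per_MBq * activity.total_activity_MBq()
                      * time_per_projection_s * n_projections * transmission)
        if n_detected <= 0:
            sigma_rel = 0.0
        else:
            sigma_rel = camera.noise_scale / math.sqrt(n_detected)
        rng = np.random.default_rng(seed)
        corr_sigma_vox = float(np.mean(sigma_post))
        # reference level for the Poisson weighting: typical in-phantom value
        support = values > 0.01 * values.max() if values.max() > 0 else values > -1
        ref_level = float(values[support].mean()) if support.any() else None
        values = apply_correlated_noise(values, sigma_rel, rng, corr_sigma_vox, ref_level)

    return SpectVolume(grid, values, "photopeak", time_per_projection_s, n_projections)
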