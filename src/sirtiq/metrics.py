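"""Quantitative image-quality metrics for phantom acquisitions.

Implemented metrics, with N̄ denoting VOI mean counts and σ_BG the pooled
background standard deviation:

* contrast recovery coefficient, ``CRC = 100 * ((N̄_S / N̄_BG) - 1) / (R - 1)``
  with R the realized sphere-to-background concentration ratio;
* relative lung-insert count error, ``ΔN_lung = 100 * N̄_lung / N̄_BG``;
* noise coefficient of variation, ``CV_BG = 100 * σ_BG / N̄_BG`` over all
  voxels pooled across the three background cylinders (population SD);
* contrast-to-noise ratio, ``CNR = (N̄_S - N̄_BG) / σ_BG``;
* apparent lung shunt from planar ROI counts,
  ``LLS = 100 * counts_lung / (counts_lung + counts_liver)``.

All intensity-ratio metrics are invariant under global scaling of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acquisition import SpectVolume
from .phantom import ActivitySetup, realized_ratio
from .segmentation import VoiSet

__all__ = [
    "SphereResult",
    "IQResult",
    "crc",
    "lung_count_error",
    "cv_bg",
    "cnr",
    "apparent_lung_shunt",
    "conjugate_view_counts",
    "evaluate",
]


def crc(mean_sphere: float, mean_bg: float, ratio: float) -> float:
    """Contrast recovery coefficient in percent.

    ``ratio`` must be the realized (measured) sphere-to-background
    concentration ratio and must exceed 1, otherwise the contrast is
    undefined.
    """
    if ratio <= 1:
        raise ValueError(f"contrast undefined for ratio <= 1 (got {ratio})")
    if mean_bg <= 0:
        raise ValueError("background mean must be positive")
    return 100.0 * ((mean_sphere / mean_bg) - 1.0) / (ratio - 1.0)


def lung_count_error(mean_lung: float, mean_bg: float) -> float:
    """Residual counts in the cold lung insert relative to background (%)."""
    if mean_bg <= 0:
        raise ValueError("background mean must be positive")
    if mean_lung < 0:
        raise ValueError("lung mean must be nonnegative")
    return 100.0 * mean_lung / mean_bg


def cv_bg(background_voxels: np.ndarray) -> float:
    """Noise coefficient of variation (%) over pooled background voxels.

    Uses the population standard deviation over all voxels (the distinction
    from the sample SD is negligible at VOI sizes but fixed for determinism).
    """
    vals = np.asarray(background_voxels, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("at least two background voxels are required")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("background mean must be positive")
    return 100.0 * vals.std(ddof=0) / mean


def cnr(mean_sphere: float, mean_bg: float, sd_bg: float) -> float:
    """Contrast-to-noise ratio; negative for cold objects, by sign convention."""
    if sd_bg <= 0:
        raise ValueError("background standard deviation must be positive")
    return (mean_sphere - mean_bg) / sd_bg


def apparent_lung_shunt(counts_lung_roi: float, counts_liver_roi: float) -> float:
    """Apparent lung-shunt fraction (%) from planar ROI count totals."""
    if counts_lung_roi < 0 or counts_liver_roi < 0:
        raise ValueError("ROI counts must be nonnegative")
    total = counts_lung_roi + counts_liver_roi
    if total <= 0:
        raise ValueError("total ROI counts must be positive")
    return 100.0 * counts_lung_roi / total


def conjugate_view_counts(counts_per_view: list[float]) -> float:
    """Combine per-ROI counts across conjugate views by geometric mean.

    Standard practice for anterior/posterior planar quantification; a single
    view passes through unchanged.
    """
    vals = np.asarray(counts_per_view, dtype=float)
    if vals.size == 0 or (vals < 0).any():
        raise ValueError("per-view counts must be a nonempty nonnegative list")
    if vals.size == 1:
        return float(vals[0])
    if (vals == 0).any():
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


@dataclass(frozen=True)
class SphereResult:
    """Per-sphere outcome; ``crc_percent``/``cnr`` are ``None`` when the
    sphere was not evaluable or the quantity is undefined for the setup."""

    diameter_mm: float
    evaluable: bool
    mean_counts: float | None = None
    crc_percent: float | None = None
    cnr: float | None = None
    reason: str | None = None


@dataclass(frozen=True)
class IQResult:
    """Image-quality metrics of one volume acquisition."""

    per_sphere: dict[float, SphereResult]
    mean_bg: float
    sd_bg: float
    cv_bg_percent: float | None
    lung_error_percent: float | None

    def evaluable_diameters(self) -> list[float]:
        return sorted(d for d, r in self.per_sphere.items() if r.evaluable)

    def crc_by_diameter(self) -> dict[float, float]:
        return {d: r.crc_percent for d, r in sorted(self.per_sphere.items())
                if r.evaluable and r.crc_percent is not None}


def evaluate(volume: SpectVolume, vois: VoiSet, setup: ActivitySetup) -> IQResult:
    """Compute all volume metrics for one acquisition.

    ``vois`` must contain the background and lung masks and the (possibly
    partially failed) sphere masks.  Spheres without a mask are reported as
    not evaluable rather than dropped.  For the spheres-only setup (zero
    background activity) CRC is undefined and reported as ``None``; CNR is
    ``None`` whenever the background SD is zero (ideal noiseless images).
    """
    if not vois.background_masks:
        raise ValueError("background masks are required")
    pooled = np.zeros(volume.grid.shape, dtype=bool)
    for m in vois.background_masks:
        pooled |= m
    bg_vals = volume.values[pooled]
    mean_bg = float(bg_vals.mean())
    sd_bg = float(bg_vals.std(ddof=0))

    cv = 100.0 * sd_bg / mean_bg if mean_bg > 0 else None
    lung = None
    if mean_bg > 0:
        lung = lung_count_error(float(volume.values[vois.lung_mask].mean()), mean_bg)

    ratio = None
    if setup.c_background_kBq_per_ml > 0:
        ratio = realized_ratio(setup)

    per_sphere: dict[float, SphereResult] = {}
    for diam, mask in sorted(vois.sphere_masks.items()):
        if mask is None:
            per_sphere[diam] = SphereResult(diam, evaluable=False,
                                            reason=vois.failures.get(diam, "segmentation failed"))
            continue
        mean_s = float(volume.values[mask].mean())
        sphere_crc = None
        if ratio is not None and ratio > 1 and mean_bg > 0:
            sphere_crc = crc(mean_s, mean_bg, ratio)
        sphere_cnr = cnr(mean_s, mean_bg, sd_bg) if sd_bg > 0 else None
        per_sphere[diam] = SphereResult(diam, evaluable=True, mean_counts=mean_s,
                                        crc_percent=sphere_crc, cnr=sphere_cnr)

    return IQResult(per_sphere=per_sphere, mean_bg=mean_bg, sd_bg=sd_bg,
                    cv_bg_percent=cv, lung_error_percent=lung)
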