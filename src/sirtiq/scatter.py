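"""Dual-energy-window (DEW) scatter correction.

The scatter contribution to the photopeak window is estimated from a second
energy window adjacent to the photopeak, scaled by a calibration k-factor:
``corrected = max(photopeak - k * scatter_window, 0)`` element-wise.  Tc-99m
conventionally uses a lower adjacent window with k = 0.5; Ho-166 uses an
upper window (dominated by down-scattered high-energy photons) with k = 1.4.

Negative corrected values are clamped to zero per element, before any ROI
summation; at low counts this clamping biases ROI totals slightly upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import PlanarImage, SpectVolume

__all__ = ["DewConfig", "DEW_DEFAULTS", "dew_correct", "dew_correct_planar"]


@dataclass(frozen=True)
class DewConfig:
    """Per-isotope DEW configuration."""

    k_factor: float
    isotope: str
    window_geometry: str = "lower_adjacent"  # or 'upper_adjacent'

    def __post_init__(self) -> None:
        if self.k_factor < 0:  # k = 0 is the degenerate no-correction limit
            raise ValueError("k-factor must be nonnegative")
        if self.window_geometry not in ("lower_adjacent", "upper_adjacent"):
            raise ValueError(f"unknown window geometry {self.window_geometry!r}")


DEW_DEFAULTS: dict[str, DewConfig] = {
    "tc99m": DewConfig(k_factor=0.5, isotope="tc99m", window_geometry="lower_adjacent"),
    "ho166": DewConfig(k_factor=1.4, isotope="ho166", window_geometry="upper_adjacent"),
}


def dew_correct(photopeak: np.ndarray, scatter_window: np.ndarray,
                config: DewConfig) -> np.ndarray:
    """Element-wise DEW subtraction with a zero clamp.

    Arrays must share a shape (and, implicitly, a pixel/voxel grid).
    """
    pp = np.asarray(photopeak, dtype=float)
    sw = np.asarray(scatter_window, dtype=float)
    if pp.shape != sw.shape:
        raise ValueError(f"shape mismatch: photopeak {pp.shape} vs scatter {sw.shape}")
    return np.maximum(pp - config.k_factor * sw, 0.0)


def dew_correct_planar(photopeak: PlanarImage, scatter_window: PlanarImage,
                       config: DewConfig) -> PlanarImage:
    """DEW-correct a planar image pair, preserving the image metadata."""
    if photopeak.window != "photopeak" or scatter_window.window != "scatter":
        raise ValueError("expected a (photopeak, scatter) image pair")
    if photopeak.pixel_size_mm != scatter_window.pixel_size_mm or \
            photopeak.counts.shape != scatter_window.counts.shape:
        raise ValueError("planar images are not on the same pixel grid")
    corrected = dew_correct(photopeak.counts, scatter_window.counts, config)
    return PlanarImage(corrected, photopeak.pixel_size_mm, photopeak.view,
                       "photopeak", photopeak.duration_s)


def dew_correct_volume(photopeak: SpectVolume, scatter_window: SpectVolume,
                       config: DewConfig) -> SpectVolume:
    """DEW-correct a volume pair on a shared grid."""
    if photopeak.grid != scatter_window.grid:
        raise ValueError("volumes are not on the same grid")
    corrected = dew_correct(photopeak.values, scatter_window.values, config)
    return SpectVolume(photopeak.grid, corrected, "photopeak",
                       photopeak.time_per_projection_s, photopeak.n_projections)
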