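"""VOI/ROI definitions: isocontour sphere segmentation, background and lung
cylinders, and the planar liver/lung ROI pair used for lung-shunt estimation.

Hot spheres are delineated with a background-adapted 50% isocontour: the
threshold is ``bg + 0.5 * (P - bg)`` where ``P`` is the local maximum in a
search ball around the expected sphere position, and the mask is the
26-connected component above threshold containing the seed.  Background and
lung VOIs are fixed cylinders (45 mm x 150 mm and 30 mm x 130 mm) parallel to
the phantom long axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import PlanarImage, SpectVolume
from .grid import VoxelGrid
from .phantom import LABEL_LUNG, PhantomGeometry, sphere_label

__all__ = [
    "SegmentationError",
    "PlacementError",
    "VoiSet",
    "PlanarRoiPair",
    "segment_sphere_isocontour",
    "place_standard_vois",
    "place_planar_rois",
    "estimate_background_level",
    "build_sphere_masks",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """A sphere could not be delineated (e.g. drowned in background noise)."""


class PlacementError(ValueError):
    """A VOI/ROI cannot be placed without violating its constraints."""


@dataclass
class VoiSet:
    """Masks for one acquisition: spheres (possibly unevaluable), background
    cylinders and the lung cylinder.  ``sphere_masks`` maps sphere diameter
    (mm) to a boolean volume, or to ``None`` with the failure reason recorded
    in ``failures``."""

    background_masks: list[np.ndarray]
    lung_mask: np.ndarray
    sphere_masks: dict[float, np.ndarray | None] = field(default_factory=dict)
    failures: dict[float, str] = field(default_factory=dict)


@dataclass(frozen=True)
class PlanarRoiPair:
    """Planar ROIs: one over the phantom ("liver"), one above it in the
    activity-free zone ("lung")."""

    liver_roi: np.ndarray
    lung_roi: np.ndarray

    def __post_init__(self) -> None:
        if (self.liver_roi & self.lung_roi).any():
            raise PlacementError("liver and lung ROIs overlap")


def segment_sphere_isocontour(
    volume: SpectVolume,
    seed_point_mm: tuple[float, float, float],
    bg_level: float,
    nominal_diameter_mm: float,
    *,
    search_ball_factor: float = 1.5,
    threshold_factor: float = 0.5,
) -> np.ndarray:
    """Background-adapted isocontour segmentation of one hot sphere.

    ``P`` is the maximum value within a ball of diameter
    ``search_ball_factor * nominal_diameter`` around the seed point; the mask
    is the 26-connected component of ``values >= bg + threshold_factor *
    (P - bg)`` containing the hottest voxel of the search ball.  Ties at
    exactly the threshold are included.

    Raises :class:`SegmentationError` when the local maximum does not exceed
    the background level (the sphere is then recorded as not evaluable).
    """
    if bg_level < 0:
        raise ValueError("background level must be nonnegative")
    grid = volume.grid
    dist = grid.distance_to(seed_point_mm)
    ball = dist <= search_ball_factor * nominal_diameter_mm / 2.0
    if not ball.any():
        raise SegmentationError("search ball contains no voxels")
    vals = volume.values
    in_ball = np.where(ball, vals, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(in_ball)), vals.shape)
    peak = float(vals[peak_idx])
    if peak <= bg_level:
        raise SegmentationError(
            f"local maximum {peak:.4g} does not exceed background level {bg_level:.4g}"
        )
    threshold = bg_level + threshold_factor * (peak - bg_level)
    above = vals >= threshold
    comp_labels, _ = ndimage.label(above, structure=_STRUCT_26)
    mask = comp_labels == comp_labels[peak_idx]
    return mask


#: Default background-cylinder placements: (ring radius mm, angle deg) in the
#: transverse (z, x) plane; angle 0 is the +x direction.  Chosen between the
#: sphere ring and the body wall on the wide side of the ellipse.
DEFAULT_BACKGROUND_POSITIONS: tuple[tuple[float, float], ...] = (
    (100.0, 30.0), (100.0, 150.0), (100.0, 210.0),
)


def place_standard_vois(
    geometry: PhantomGeometry,
    grid: VoxelGrid,
    *,
    background_diameter_mm: float = 45.0,
    background_length_mm: float = 150.0,
    background_positions: tuple[tuple[float, float], ...] = DEFAULT_BACKGROUND_POSITIONS,
    lung_diameter_mm: float = 30.0,
    lung_length_mm: float = 130.0,
) -> VoiSet:
    """Fixed cylindrical background and lung VOIs for a phantom acquisition.

    Background cylinders are parallel to the phantom axis, centered axially on
    the sphere plane, and must lie fully inside the background compartment
    (inside the body, clear of spheres and lung insert).  The lung VOI is
    concentric with the insert.  Sphere masks are left empty; fill them with
    :func:`build_sphere_masks`.
    """
    z, y, x = grid.meshgrid()
    ax, az = geometry.body_axes_mm
    y0 = geometry.sphere_plane_y_mm
    r_bg = background_diameter_mm / 2.0
    half_bg = background_length_mm / 2.0

    centers = np.asarray(geometry.sphere_centers_mm, float)
    radii = np.asarray(geometry.sphere_diameters_mm, float) / 2.0
    bg_masks = []
    for ring_r, angle_deg in background_positions:
        th = math.radians(angle_deg)
        cx, cz = ring_r * math.cos(th), ring_r * math.sin(th)
        # fully inside the body: conservative check against the ellipse shrunk
        # by the cylinder radius
        if (cx / (ax - r_bg)) ** 2 + (cz / (az - r_bg)) ** 2 > 1.0:
            raise PlacementError(
                f"background cylinder at r={ring_r}, {angle_deg} deg leaves the body")
        if math.hypot(cx, cz) - r_bg < geometry.lung_insert_diameter_mm / 2.0:
            raise PlacementError(
                f"background cylinder at r={ring_r}, {angle_deg} deg intersects the lung insert")
        for (sz, sy, sx), sr in zip(centers, radii):
            if abs(sy - y0) < half_bg + sr:  # axial overlap possible
                if math.hypot(cx - sx, cz - sz) < r_bg + sr:
                    raise PlacementError(
                        f"background cylinder at r={ring_r}, {angle_deg} deg intersects a sphere")
        if abs(y0) + half_bg > geometry.body_length_mm / 2.0:
            raise PlacementError("background cylinder extends beyond the body length")
        mask = ((x - cx) ** 2 + (z - cz) ** 2 <= r_bg**2) & (np.abs(y - y0) <= half_bg)
        bg_masks.append(np.broadcast_to(mask, grid.shape).copy())

    r_lung = lung_diameter_mm / 2.0
    if r_lung > geometry.lung_insert_diameter_mm / 2.0:
        raise PlacementError("lung VOI is wider than the lung insert")
    lung = (x**2 + z**2 <= r_lung**2) & (np.abs(y) <= lung_length_mm / 2.0)
    lung = np.broadcast_to(lung, grid.shape).copy()
    return VoiSet(background_masks=bg_masks, lung_mask=lung)


def estimate_background_level(volume: SpectVolume, vois: VoiSet) -> float:
    """Mean value over the pooled background cylinders.

    Computed before any sphere segmentation; this is the ``bg`` entering the
    background-adapted isocontour threshold.
    """
    pooled = np.zeros(volume.grid.shape, dtype=bool)
    for m in vois.background_masks:
        pooled |= m
    if not pooled.any():
        raise ValueError("background masks are empty")
    return float(volume.values[pooled].mean())


def build_sphere_masks(
    volume: SpectVolume,
    geometry: PhantomGeometry,
    vois: VoiSet,
    bg_level: float | None = None,
    **segment_kwargs,
) -> VoiSet:
    """Segment all six spheres, recording failures instead of raising.

    Seeds are the known sphere centers of the phantom geometry.  Spheres whose
    isocontour segmentation fails are stored as ``None`` with the reason in
    ``vois.failures`` (mirroring the "could not be evaluated" outcome on very
    noisy images).
    """
    if bg_level is None:
        bg_level = estimate_background_level(volume, vois)
    for center, diam in zip(geometry.sphere_centers_mm, geometry.sphere_diameters_mm):
        try:
            mask = segment_sphere_isocontour(volume, center, bg_level, diam, **segment_kwargs)
            vois.sphere_masks[diam] = mask
        except SegmentationError as exc:
            vois.sphere_masks[diam] = None
            vois.failures[diam] = str(exc)
    return vois


def place_planar_rois(
    image: PlanarImage,
    geometry: PhantomGeometry,
    *,
    gap_mm: float = 10.0,
) -> PlanarRoiPair:
    """Liver ROI over the projected body, lung ROI above the phantom.

    The liver ROI is the projected body outline (the transverse ellipse,
    including any obese shell) eroded by one pixel.  The lung ROI is a
    full-width rectangle starting ``gap_mm`` above the top of the body
    projection, grown row by row until it matches the liver ROI pixel count
    (equal-area ROIs).
    """
    zc, xc = image.pixel_coords()
    ax = geometry.body_axes_mm[0] + geometry.obese_shell_thickness_mm
    az = geometry.body_axes_mm[1] + geometry.obese_shell_thickness_mm
    inside = (xc[None, :] / ax) ** 2 + (zc[:, None] / az) ** 2 <= 1.0
    if inside[0].any() or inside[-1].any() or inside[:, 0].any() or inside[:, -1].any():
        raise PlacementError("phantom projection does not lie inside the image")
    liver = ndimage.binary_erosion(inside)
    n_target = int(liver.sum())
    if n_target == 0:
        raise PlacementError("projected body is empty after erosion")

    lung = np.zeros_like(liver)
    z_min = az + gap_mm
    rows = np.where(zc > z_min)[0]
    n_cols = lung.shape[1]
    remaining = n_target
    for row in rows:
        take = min(n_cols, remaining)
        lung[row, :take] = True
        remaining -= take
        if remaining == 0:
            break
    if remaining > 0:
        raise PlacementError(
            f"not enough room above the phantom for an equal-area lung ROI "
            f"({remaining} of {n_target} pixels missing)")
    return PlanarRoiPair(liver_roi=liver, lung_roi=lung)
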