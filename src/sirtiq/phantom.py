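"""Parametric torso (NEMA IQ style) phantom: geometry, rasterization, activity.

The phantom is a water-filled elliptical-cylinder body shell containing six
coplanar fillable spheres on a ring, a central cylindrical "lung" insert, and
optionally an extra water-equivalent shell wrapped around the body to emulate
an obese patient.  The long axis of the phantom is the grid y axis; the
transverse plane is (z, x).

Label conventions (one label per voxel):

====== =======================================
0      outside the phantom
1      fillable background compartment
2..7   spheres, in ascending diameter
8      lung insert
9      obese shell (water-equivalent wrap)
====== =======================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "PhantomGeometry",
    "ActivitySetup",
    "LabelVolume",
    "ActivityVolume",
    "build_geometry",
    "rasterize",
    "assign_activity",
    "realized_ratio",
    "SPHERE_DIAMETERS_MM",
    "LABEL_OUTSIDE",
    "LABEL_BACKGROUND",
    "LABEL_SPHERE_FIRST",
    "LABEL_LUNG",
    "LABEL_SHELL",
    "sphere_label",
]

#: Inner diameters of the six fillable spheres (mm), ascending.
SPHERE_DIAMETERS_MM: tuple[float, ...] = (10.0, 13.0, 17.0, 22.0, 28.0, 37.0)

LABEL_OUTSIDE = 0
LABEL_BACKGROUND = 1
LABEL_SPHERE_FIRST = 2  # labels 2..7 are spheres in ascending diameter
LABEL_LUNG = 8
LABEL_SHELL = 9

#: Radius of the ring on which the sphere centers sit (mm).
SPHERE_RING_RADIUS_MM = 57.2


class GeometryError(ValueError):
    """Invalid phantom geometry (overlaps, nonpositive dimensions...)."""


class RasterizationError(ValueError):
    """Phantom does not fit on the requested grid."""


def sphere_label(i: int) -> int:
    """Label of sphere ``i`` (0-based index in ascending-diameter order)."""
    return LABEL_SPHERE_FIRST + i


@dataclass(frozen=True)
class PhantomGeometry:
    """Parametric phantom description; all lengths in mm.

    ``body_axes_mm`` are the transverse semi-axes of the elliptical body shell
    (along x and along z).  Sphere centers are world points (z, y, x), all in
    one transverse plane (equal y).  The lung insert axis coincides with the
    phantom long axis (the y axis through x = z = 0).
    """

    body_axes_mm: tuple[float, float] = (150.0, 115.0)  # (semi-axis x, semi-axis z)
    body_length_mm: float = 180.0
    sphere_diameters_mm: tuple[float, ...] = SPHERE_DIAMETERS_MM
    sphere_centers_mm: tuple[tuple[float, float, float], ...] = ()
    lung_insert_diameter_mm: float = 50.0
    lung_insert_length_mm: float = 180.0
    obese_shell_thickness_mm: float = 0.0

    def __post_init__(self) -> None:
        if not self.sphere_centers_mm:
            object.__setattr__(self, "sphere_centers_mm", _default_sphere_centers())
        self.validate()

    def validate(self) -> None:
        ax, az = self.body_axes_mm
        if ax <= 0 or az <= 0 or self.body_length_mm <= 0:
            raise GeometryError("body dimensions must be positive")
        if self.lung_insert_diameter_mm <= 0 or self.lung_insert_length_mm <= 0:
            raise GeometryError("lung insert dimensions must be positive")
        if self.obese_shell_thickness_mm < 0:
            raise GeometryError("obese shell thickness must be nonnegative")
        nd, nc = len(self.sphere_diameters_mm), len(self.sphere_centers_mm)
        if nd != nc:
            raise GeometryError(f"{nd} sphere diameters but {nc} centers")
        if any(d <= 0 for d in self.sphere_diameters_mm):
            raise GeometryError("sphere diameters must be positive")
        ys = {c[1] for c in self.sphere_centers_mm}
        if len(ys) > 1:
            raise GeometryError(f"spheres must be coplanar (equal y), got y = {sorted(ys)}")
        centers = np.asarray(self.sphere_centers_mm, float)
        radii = np.asarray(self.sphere_diameters_mm, float) / 2.0
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                dist = float(np.linalg.norm(centers[i] - centers[j]))
                if dist < radii[i] + radii[j]:
                    raise GeometryError(
                        f"spheres {i} and {j} overlap: center distance {dist:.1f} mm "
                        f"< radii sum {radii[i] + radii[j]:.1f} mm"
                    )

    @property
    def sphere_plane_y_mm(self) -> float:
        return self.sphere_centers_mm[0][1]

    def outer_extent_mm(self) -> tuple[tuple[float, float], ...]:
        """Bounding box ((zmin, zmax), (ymin, ymax), (xmin, xmax)) of the phantom."""
        ax, az = self.body_axes_mm
        s = self.obese_shell_thickness_mm
        half_l = self.body_length_mm / 2.0
        zlo, zhi = -(az + s), az + s
        ylo, yhi = -half_l, half_l
        xlo, xhi = -(ax + s), ax + s
        for (cz, cy, cx), d in zip(self.sphere_centers_mm, self.sphere_diameters_mm):
            r = d / 2.0
            zlo, zhi = min(zlo, cz - r), max(zhi, cz + r)
            ylo, yhi = min(ylo, cy - r), max(yhi, cy + r)
            xlo, xhi = min(xlo, cx - r), max(xhi, cx + r)
        return ((zlo, zhi), (ylo, yhi), (xlo, xhi))


def _default_sphere_centers(
    ring_radius_mm: float = SPHERE_RING_RADIUS_MM, plane_y_mm: float = 0.0
) -> tuple[tuple[float, float, float], ...]:
    """Coplanar ring, spheres in ascending diameter at 60 degree spacing."""
    centers = []
    for k in range(6):
        theta = math.radians(60.0 * k)
        centers.append((ring_radius_mm * math.sin(theta), plane_y_mm,
                        ring_radius_mm * math.cos(theta)))
    return tuple(centers)


def build_geometry(variant: str = "standard", overrides: dict | None = None) -> PhantomGeometry:
    """Construct the phantom geometry for the ``standard`` or ``obese`` setup.

    The obese variant wraps a 30 mm water-equivalent shell around the body.
    ``overrides`` may replace any :class:`PhantomGeometry` field; the result is
    re-validated.
    """
    if variant not in ("standard", "obese"):
        raise ValueError(f"variant must be 'standard' or 'obese', got {variant!r}")
    geom = PhantomGeometry()
    if variant == "obese":
        geom = replace(geom, obese_shell_thickness_mm=30.0)
    if overrides:
        bad = set(overrides) - set(geom.__dataclass_fields__)
        if bad:
            raise ValueError(f"unknown geometry overrides: {sorted(bad)}")
        overrides = dict(overrides)
        for key in ("sphere_diameters_mm", "sphere_centers_mm", "body_axes_mm"):
            if key in overrides:
                overrides[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v for v in overrides[key]
                )
        geom = replace(geom, **overrides)
    return geom


@dataclass(frozen=True)
class LabelVolume:
    """Integer label per voxel; see module docstring for the label scheme."""

    grid: VoxelGrid
    labels: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.labels.shape) != self.grid.shape:
            raise ValueError("label array shape does not match grid shape")

    def volume_ml(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.grid.voxel_volume_ml

    def volume_mm3(self, label: int) -> float:
        return float(np.count_nonzero(self.labels == label)) * self.grid.voxel_volume_mm3


@dataclass(frozen=True)
class ActivityVolume:
    """Voxelized activity concentration map in kBq/ml."""

    grid: VoxelGrid
    concentration_kBq_per_ml: np.ndarray

    def __post_init__(self) -> None:
        if tuple(self.concentration_kBq_per_ml.shape) != self.grid.shape:
            raise ValueError("concentration array shape does not match grid shape")

    def total_activity_MBq(self) -> float:
        return float(self.concentration_kBq_per_ml.sum()) * self.grid.voxel_volume_ml / 1000.0


@dataclass(frozen=True)
class ActivitySetup:
    """Activity concentrations of one phantom filling.

    ``nominal_ratio`` is the intended sphere-to-background ratio (8.0, 4.0, or
    None for the spheres-only filling); the realized ratio actually used in
    contrast computations comes from :func:`realized_ratio`.
    """

    c_spheres_kBq_per_ml: float
    c_background_kBq_per_ml: float = 0.0
    nominal_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.c_spheres_kBq_per_ml < 0 or self.c_background_kBq_per_ml < 0:
            raise ValueError("activity concentrations must be nonnegative")
        if self.nominal_ratio is not None and self.nominal_ratio <= 0:
            raise ValueError("nominal ratio must be positive")


def realized_ratio(setup: ActivitySetup, ndigits: int | None = None) -> float:
    """Realized sphere-to-background concentration ratio.

    Raises ``ValueError`` for the spheres-only filling (background = 0), where
    the ratio is undefined.  ``ndigits`` rounds the result for tabulation
    (tables conventionally carry two decimals).
    """
    if setup.c_background_kBq_per_ml <= 0:
        raise ValueError("ratio undefined: background concentration is zero")
    ratio = setup.c_spheres_kBq_per_ml / setup.c_background_kBq_per_ml
    return round(ratio, ndigits) if ndigits is not None else ratio


def rasterize(geometry: PhantomGeometry, grid: VoxelGrid) -> LabelVolume:
    """Voxelize the phantom onto ``grid``.

    A voxel receives a label iff its center lies inside the corresponding
    region; precedence on boundaries is sphere > lung > background > shell >
    outside.  Raises :class:`RasterizationError` if the phantom extends beyond
    the grid.
    """
    gext = grid.extent_mm()
    pext = geometry.outer_extent_mm()
    for a, name in enumerate("zyx"):
        if pext[a][0] < gext[a][0] or pext[a][1] > gext[a][1]:
            raise RasterizationError(
                f"phantom extent {pext[a]} mm exceeds grid extent {gext[a]} mm along {name}"
            )

    z, y, x = grid.meshgrid()
    labels = np.zeros(grid.shape, dtype=np.uint8)
    ax, az = geometry.body_axes_mm
    half_l = geometry.body_length_mm / 2.0
    in_length = (y >= -half_l) & (y < half_l)

    shell = geometry.obese_shell_thickness_mm
    if shell > 0:
        in_outer = ((x / (ax + shell)) ** 2 + (z / (az + shell)) ** 2 <= 1.0) & in_length
        labels[np.broadcast_to(in_outer, grid.shape)] = LABEL_SHELL

    in_body = ((x / ax) ** 2 + (z / az) ** 2 <= 1.0) & in_length
    labels[np.broadcast_to(in_body, grid.shape)] = LABEL_BACKGROUND

    r_lung = geometry.lung_insert_diameter_mm / 2.0
    half_lung = geometry.lung_insert_length_mm / 2.0
    in_lung = (x**2 + z**2 <= r_lung**2) & (y >= -half_lung) & (y < half_lung) & in_body
    labels[np.broadcast_to(in_lung, grid.shape)] = LABEL_LUNG

    for i, (center, diam) in enumerate(
        zip(geometry.sphere_centers_mm, geometry.sphere_diameters_mm)
    ):
        cz, cy, cx = center
        r2 = (diam / 2.0) ** 2
        inside = (z - cz) ** 2 + (y - cy) ** 2 + (x - cx) ** 2 <= r2
        labels[np.broadcast_to(inside, grid.shape)] = sphere_label(i)

    return LabelVolume(grid, labels)


def assign_activity(labels: LabelVolume, setup: ActivitySetup) -> ActivityVolume:
    """Fill the labeled phantom with the setup's activity concentrations.

    Spheres receive the sphere concentration, the background compartment the
    background concentration; lung insert, shell and the region outside the
    body carry zero activity.
    """
    conc = np.zeros(labels.grid.shape, dtype=np.float64)
    conc[labels.labels == LABEL_BACKGROUND] = setup.c_background_kBq_per_ml
    sphere_mask = (labels.labels >= LABEL_SPHERE_FIRST) & (labels.labels < LABEL_LUNG)
    conc[sphere_mask] = setup.c_spheres_kBq_per_ml
    return ActivityVolume(labels.grid, conc)
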