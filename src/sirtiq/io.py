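"""NIfTI-1 and JSON-sidecar I/O for volumes and planar images.

Volumes are written as NIfTI-1 with the voxel spacing (mm) in the header.
Internally arrays are indexed (z, y, x); on disk they are stored transposed
to (x, y, z) so the affine is a plain diagonal spacing matrix.  Acquisition
metadata travels in a JSON sidecar next to each image.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .acquisition import PlanarImage, SpectVolume
from .grid import VoxelGrid
from .phantom import ActivityVolume, LabelVolume

__all__ = [
    "save_volume",
    "load_spect_volume",
    "save_label_volume",
    "save_activity_volume",
    "save_planar_image",
    "load_planar_image",
    "write_sidecar",
    "read_sidecar",
    "file_sha256",
]


def _affine(grid: VoxelGrid) -> np.ndarray:
    dz, dy, dx = grid.voxel_size_mm
    oz, oy, ox = grid.origin_mm
    aff = np.diag([dx, dy, dz, 1.0])
    aff[:3, 3] = [ox, oy, oz]
    return aff


def _grid_from_nifti(img: nib.Nifti1Image) -> VoxelGrid:
    aff = img.affine
    shape_xyz = img.shape[:3]
    voxel = (float(aff[2, 2]), float(aff[1, 1]), float(aff[0, 0]))
    origin = (float(aff[2, 3]), float(aff[1, 3]), float(aff[0, 3]))
    return VoxelGrid((shape_xyz[2], shape_xyz[1], shape_xyz[0]), voxel, origin)


def _save_array(arr: np.ndarray, grid: VoxelGrid, path: Path) -> None:
    img = nib.Nifti1Image(np.ascontiguousarray(arr.T), _affine(grid))
    img.header.set_zooms(tuple(reversed(grid.voxel_size_mm)))
    nib.save(img, str(path))


def save_volume(volume: SpectVolume, path: str | Path) -> None:
    _save_array(volume.values.astype(np.float32), volume.grid, Path(path))


def save_label_volume(labels: LabelVolume, path: str | Path) -> None:
    _save_array(labels.labels.astype(np.uint8), labels.grid, Path(path))


def save_activity_volume(activity: ActivityVolume, path: str | Path) -> None:
    _save_array(activity.concentration_kBq_per_ml.astype(np.float32),
                activity.grid, Path(path))


def load_spect_volume(path: str | Path, *, window: str = "photopeak",
                      time_per_projection_s: float | None = None,
                      n_projections: int | None = None) -> SpectVolume:
    img = nib.load(str(path))
    grid = _grid_from_nifti(img)
    values = np.ascontiguousarray(np.asanyarray(img.dataobj).T).astype(float)
    return SpectVolume(grid, values, window, time_per_projection_s, n_projections)


def save_planar_image(image: PlanarImage, path: str | Path) -> None:
    """Planar images are stored as single-slice NIfTI volumes."""
    arr = image.counts.astype(np.float32)[None, :, :]  # (1, nz, nx) -> (x, z, 1) on disk
    dz = dx = image.pixel_size_mm
    grid = VoxelGrid((1, arr.shape[1], arr.shape[2]), (1.0, dz, dx), (0.0, 0.0, 0.0))
    _save_array(arr, grid, Path(path))


def load_planar_image(path: str | Path, *, pixel_size_mm: float, view: str,
                      window: str, duration_s: float) -> PlanarImage:
    img = nib.load(str(path))
    arr = np.ascontiguousarray(np.asanyarray(img.dataobj).T)[0]
    if np.allclose(arr, np.round(arr)):
        arr = np.round(arr).astype(np.int64)
    return PlanarImage(arr, pixel_size_mm, view, window, duration_s)


def write_sidecar(path: str | Path, metadata: dict) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True) + "\n")


def read_sidecar(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
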