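"""End-to-end pipelines: simulate an experiment to disk, analyze it back.

``run_simulate`` renders every acquisition of an experiment config to NIfTI
images with JSON sidecars and a checksum manifest (deterministic given the
config, seeds included).  ``run_analyze`` re-reads the images and produces a
report bundle: per-acquisition image-quality rows (FWHM, CV_BG, lung count
error), per-sphere CRC/CNR, planar lung-shunt estimates, and mean +/- SD
aggregation over replicate acquisitions.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .acquisition import SpectVolume, simulate_planar, simulate_spect
from .config import ExperimentConfig, dump_config
from .grid import default_grid
from .io import (file_sha256, load_planar_image, load_spect_volume, read_sidecar,
                 save_activity_volume, save_label_volume, save_planar_image,
                 save_volume, write_sidecar)
from .metrics import IQResult, apparent_lung_shunt, conjugate_view_counts, evaluate
from .phantom import ActivitySetup, PhantomGeometry, assign_activity, rasterize
from .resolution import FitError, estimate_volume_fwhm
from .scatter import DEW_DEFAULTS, dew_correct_planar
from .segmentation import build_sphere_masks, place_planar_rois, place_standard_vois

__all__ = ["run_simulate", "run_analyze", "analyze_volume", "planar_lung_shunt",
           "ReportBundle"]

#: Extra PSF blur per mm of obese shell (source-detector distance proxy).
OBESE_BLUR_PER_MM = 0.04


def analyze_volume(volume: SpectVolume, geometry: PhantomGeometry,
                   setup: ActivitySetup, **voi_kwargs) -> IQResult:
    """Segment standard VOIs + spheres on a volume and evaluate all metrics."""
    vois = place_standard_vois(geometry, volume.grid, **voi_kwargs)
    build_sphere_masks(volume, geometry, vois)
    return evaluate(volume, vois, setup)


def planar_lung_shunt(view_pairs, geometry: PhantomGeometry, *, isotope: str | None = None,
                      scatter_correct: bool = False) -> float:
    """Apparent lung shunt (%) from one or two (photopeak, scatter) view pairs.

    With ``scatter_correct`` the photopeak of each view is DEW-corrected with
    the isotope's default k-factor first.  ROI counts are combined across
    conjugate views by geometric mean before the ratio.
    """
    lung_counts, liver_counts = [], []
    for photopeak, scatter_window in view_pairs:
        img = photopeak
        if scatter_correct:
            if isotope is None:
                raise ValueError("isotope is required for scatter correction")
            img = dew_correct_planar(photopeak, scatter_window, DEW_DEFAULTS[isotope])
        rois = place_planar_rois(img, geometry)
        counts = np.asarray(img.counts, dtype=float)
        lung_counts.append(float(counts[rois.lung_roi].sum()))
        liver_counts.append(float(counts[rois.liver_roi].sum()))
    return apparent_lung_shunt(conjugate_view_counts(lung_counts),
                               conjugate_view_counts(liver_counts))


def run_simulate(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Simulate every acquisition of an experiment to ``out_dir``.

    Writes the phantom label and activity volumes, per-acquisition NIfTI
    images with JSON sidecars, the resolved config, and a manifest with
    SHA-256 checksums of every file.  Deterministic given the config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geometry = config.geometry()
    grid = default_grid(config.voxel_size_mm)
    labels = rasterize(geometry, grid)
    activity = assign_activity(labels, config.setup.to_setup())
    camera = config.camera()
    isotope = config.isotope_model()

    save_label_volume(labels, out / "labels.nii.gz")
    save_activity_volume(activity, out / "activity.nii.gz")
    dump_config(config, out / "config.yaml")

    files = ["labels.nii.gz", "activity.nii.gz", "config.yaml"]
    extra_blur = OBESE_BLUR_PER_MM * geometry.obese_shell_thickness_mm

    for i, acq in enumerate(config.acquisitions):
        stem = f"acq{i:02d}_{acq.label or acq.kind}"
        meta = {"kind": acq.kind, "seed": acq.seed, "isotope": config.isotope,
                "collimator": camera.collimator, "key": acq.key(),
                "camera": asdict(camera)}
        if acq.kind == "planar":
            meta.update(duration_s=acq.duration_s, views=list(acq.views),
                        pixel_size_mm=config.planar_fov_mm / 256)
            for v, view in enumerate(acq.views):
                pp, sw = simulate_planar(activity, camera, isotope, view,
                                         acq.duration_s, acq.seed + 1000 * v,
                                         labels=labels, fov_mm=config.planar_fov_mm)
                for img, tag in ((pp, "photopeak"), (sw, "scatter")):
                    name = f"{stem}_{view}_{tag}.nii.gz"
                    save_planar_image(img, out / name)
                    files.append(name)
        else:
            vol = simulate_spect(activity, camera, isotope, acq.time_per_projection_s,
                                 acq.n_projections, acq.seed, extra_blur_mm=extra_blur)
            meta.update(time_per_projection_s=acq.time_per_projection_s,
                        n_projections=acq.n_projections)
            name = f"{stem}.nii.gz"
            save_volume(vol, out / name)
            files.append(name)
        sidecar = f"{stem}.json"
        write_sidecar(out / sidecar, meta)
        files.append(sidecar)

    manifest = {"version": __version__, "experiment": config.name,
                "files": {f: file_sha256(out / f) for f in sorted(files)}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


@dataclass
class ReportBundle:
    """Analysis results for one simulated experiment."""

    experiment: str
    rows: list[dict] = field(default_factory=list)  # tabular IQ rows
    sphere_metrics: list[dict] = field(default_factory=list)  # per-sphere CRC/CNR
    lung_shunt: list[dict] = field(default_factory=list)
    aggregates: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.rows:
            pd.DataFrame(self.rows).to_csv(out / "report.csv", index=False)
        payload = {"experiment": self.experiment, "rows": self.rows,
                   "sphere_metrics": self.sphere_metrics, "lung_shunt": self.lung_shunt,
                   "aggregates": self.aggregates}
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _aggregate(rows: list[dict]) -> list[dict]:
    """Mean +/- SD per metric over replicate acquisitions (same key)."""
    frame = pd.DataFrame(rows)
    if frame.empty:
        return []
    out = []
    numeric = [c for c in ("FWHM_mm", "CV_BG_pct", "dN_lung_pct") if c in frame]
    for key, group in frame.groupby("key"):
        agg = {"key": key, "n_replicates": int(len(group))}
        for col in numeric:
            vals = group[col].dropna().to_numpy(dtype=float)
            if vals.size:
                agg[f"{col}_mean"] = float(vals.mean())
                agg[f"{col}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out.append(agg)
    return out


def run_analyze(image_dir: str | Path, config: ExperimentConfig | None = None) -> ReportBundle:
    """Analyze a simulated experiment directory back into a report bundle."""
    src = Path(image_dir)
    if config is None:
        from .config import load_config
        config = load_config(src / "config.yaml")
    geometry = config.geometry()
    setup = config.setup.to_setup()
    opts = config.analysis
    bundle = ReportBundle(experiment=config.name)

    sidecars = sorted(src.glob("acq*.json"))
    if not sidecars:
        raise FileNotFoundError(f"no acquisition sidecars in {src}")
    for sidecar in sidecars:
        meta = read_sidecar(sidecar)
        stem = sidecar.stem
        if meta["kind"] == "spect":
            volume = load_spect_volume(src / f"{stem}.nii.gz",
                                       time_per_projection_s=meta["time_per_projection_s"],
                                       n_projections=meta["n_projections"])
            result = analyze_volume(
                volume, geometry, setup,
                background_diameter_mm=opts.background_diameter_mm,
                background_length_mm=opts.background_length_mm,
                lung_diameter_mm=opts.lung_voi_diameter_mm,
                lung_length_mm=opts.lung_voi_length_mm)
            try:
                fwhm, _ = estimate_volume_fwhm(
                    volume, geometry, diameters_mm=tuple(opts.resolution_spheres_mm))
            except (FitError, ValueError):
                fwhm = None
            bundle.rows.append({
                "acquisition": stem, "key": meta["key"], "seed": meta["seed"],
                "FWHM_mm": fwhm, "CV_BG_pct": result.cv_bg_percent,
                "dN_lung_pct": result.lung_error_percent})
            for diam, sph in sorted(result.per_sphere.items()):
                bundle.sphere_metrics.append({
                    "acquisition": stem, "key": meta["key"], "diameter_mm": diam,
                    "evaluable": sph.evaluable, "CRC_pct": sph.crc_percent,
                    "CNR": sph.cnr, "reason": sph.reason})
        else:
            pairs = []
            for view in meta["views"]:
                pp = load_planar_image(src / f"{stem}_{view}_photopeak.nii.gz",
                                       pixel_size_mm=meta["pixel_size_mm"], view=view,
                                       window="photopeak", duration_s=meta["duration_s"])
                sw = load_planar_image(src / f"{stem}_{view}_scatter.nii.gz",
                                       pixel_size_mm=meta["pixel_size_mm"], view=view,
                                       window="scatter", duration_s=meta["duration_s"])
                pairs.append((pp, sw))
            lls_raw = planar_lung_shunt(pairs, geometry)
            entry = {"acquisition": stem, "key": meta["key"], "seed": meta["seed"],
                     "LLS_uncorrected_pct": lls_raw}
            if opts.scatter_correct:
                entry["LLS_corrected_pct"] = planar_lung_shunt(
                    pairs, geometry, isotope=meta["isotope"], scatter_correct=True)
            bundle.lung_shunt.append(entry)

    bundle.aggregates = _aggregate(bundle.rows)
    return bundle
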