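"""Experiment configuration: schema-validated structured text (YAML).

One config document describes a full experiment: phantom variant and activity
setup, isotope and camera operating point, the list of acquisitions (each
with an explicit seed), and analysis options.  Configs round-trip losslessly
through serialization.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .acquisition import ISOTOPES, CameraModel, IsotopeModel, default_camera
from .phantom import ActivitySetup, PhantomGeometry, build_geometry

__all__ = [
    "AcquisitionSpec",
    "AnalysisOptions",
    "ExperimentConfig",
    "load_config",
    "dump_config",
]


class SetupSpec(BaseModel, extra="forbid"):
    c_spheres_kBq_per_ml: float = Field(ge=0)
    c_background_kBq_per_ml: float = Field(default=0.0, ge=0)
    nominal_ratio: Optional[float] = Field(default=None, gt=0)

    def to_setup(self) -> ActivitySetup:
        return ActivitySetup(self.c_spheres_kBq_per_ml, self.c_background_kBq_per_ml,
                             self.nominal_ratio)


class AcquisitionSpec(BaseModel, extra="forbid"):
    kind: Literal["planar", "spect"]
    seed: int
    label: str = ""
    # planar
    views: list[Literal["anterior", "posterior"]] = Field(
        default_factory=lambda: ["anterior", "posterior"])
    duration_s: float = Field(default=300.0, gt=0)
    # spect
    time_per_projection_s: float = Field(default=20.0, gt=0)
    n_projections: int = Field(default=120, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionSpec":
        if self.kind == "planar" and not self.views:
            raise ValueError("planar acquisition needs at least one view")
        return self

    def key(self) -> str:
        """Grouping key: acquisition parameters without the seed (replicates
        of the same acquisition share a key)."""
        if self.kind == "planar":
            return f"planar_{self.duration_s:g}s"
        return f"spect_{self.time_per_projection_s:g}sx{self.n_projections}"


class AnalysisOptions(BaseModel, extra="forbid"):
    scatter_correct: bool = True
    resolution_spheres_mm: list[float] = Field(default_factory=lambda: [28.0, 37.0])
    background_diameter_mm: float = 45.0
    background_length_mm: float = 150.0
    lung_voi_diameter_mm: float = 30.0
    lung_voi_length_mm: float = 130.0


class ExperimentConfig(BaseModel, extra="forbid"):
    name: str
    variant: Literal["standard", "obese"] = "standard"
    geometry_overrides: dict = Field(default_factory=dict)
    setup: SetupSpec
    isotope: Literal["tc99m", "ho166"]
    collimator: Optional[Literal["LEHR", "MELP"]] = None
    camera_overrides: dict = Field(default_factory=dict)
    voxel_size_mm: float = Field(default=2.4, gt=0)
    planar_fov_mm: float = Field(default=533.3, gt=0)
    acquisitions: list[AcquisitionSpec] = Field(min_length=1)
    analysis: AnalysisOptions = Field(default_factory=AnalysisOptions)

    def geometry(self) -> PhantomGeometry:
        return build_geometry(self.variant, self.geometry_overrides or None)

    def isotope_model(self) -> IsotopeModel:
        return ISOTOPES[self.isotope]

    def camera(self) -> CameraModel:
        return default_camera(self.isotope, self.collimator, **self.camera_overrides)


def load_config(path: str | Path) -> ExperimentConfig:
    data = yaml.safe_load(Path(path).read_text())
    return ExperimentConfig.model_validate(data)


def dump_config(config: ExperimentConfig, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
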