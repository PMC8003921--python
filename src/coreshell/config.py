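"""Validated pipeline configuration, serialized into every report."""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import yaml
from pydantic import BaseModel, Field


class PipelineConfig(BaseModel):
    """All tunables of the analysis pipeline (lengths in µm).

    ``min_object_volume`` defaults to half the volume of a sphere with the
    default mean nucleus radius (4 µm), tying the small-object filter to
    the nuclear scale.
    """

    target_z_spacing: float = Field(default=0.45, gt=0)
    smooth_sigma: float = Field(default=0.5, ge=0)
    neighborhood_divisor: int = Field(default=8, ge=1)
    sensitivity: float = Field(default=0.0, ge=-1.0, le=1.0)
    min_object_volume: float = Field(
        default=0.5 * 4.0 / 3.0 * math.pi * 4.0**3, ge=0
    )
    h_minima_depth: float = Field(default=1.0, ge=0)
    refine_fraction: float = Field(default=0.70, ge=0)
    whole_closing_radius: float = Field(default=5.0, ge=0)
    shadow_closing_radius: float = Field(default=6.0, ge=0)
    layer_width: float = Field(default=5.0, gt=0)
    n_surface_points: int = Field(default=5000, ge=1)
    azimuth_bin: float = Field(default=math.pi / 10, gt=0)
    polar_bin: float = Field(default=math.pi / 20, gt=0)
    dapi_fill_holes: bool = True
    # the shell channel legitimately has a large cavity (the core); filling
    # it would destroy the compartment geometry
    farred_fill_holes: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls.model_validate(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.model_dump(), indent=2, sort_keys=True))
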