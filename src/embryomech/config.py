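"""Validated run configuration for the command-line pipeline.

One human-readable YAML file configures every stage; unknown keys are
rejected so typos fail loudly before any stage runs.  Conventions: angles
in degrees, lengths in µm, 0-based pixel coordinates, image row 0 =
dorsal.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class MovieSimConfig(_Strict):
    l_um: float = 5.0
    direction: Literal["AP", "DV"] = "AP"
    n_frames: int = 20
    frame_interval_s: float = 0.5
    snr: float = 10.0
    pixel_size_um: float = 0.1
    fov_um: float = 12.0


class TextureSimConfig(_Strict):
    mean_angle_deg: float = 90.0
    kappas: list[float] = Field(default_factory=lambda: [1.0, 4.0])
    n_patches: int = 5
    snr: float = 10.0
    pixel_size_um: float = 0.05
    size_um: float = 4.0


class CohortSimConfig(_Strict):
    n_embryos: int = 15
    noise_cv: float = 0.10


class SimulateConfig(_Strict):
    movies: MovieSimConfig = MovieSimConfig()
    textures: TextureSimConfig = TextureSimConfig()
    cohort: CohortSimConfig = CohortSimConfig()


class QuantifyConfig(_Strict):
    window_end_s: float = 10.0


class InferConfig(_Strict):
    nu0: float = 0.5
    k_max: float = 1e3


class TextureAnalysisConfig(_Strict):
    highpass_cycles_per_um: float = 1.0
    n_bins: int = 45


class RunConfig(_Strict):
    """Root configuration: paths plus per-stage tunables."""

    out_dir: Path = Path("embryomech_out")
    seed: int = 0
    simulate: SimulateConfig = SimulateConfig()
    quantify: QuantifyConfig = QuantifyConfig()
    infer: InferConfig = InferConfig()
    texture: TextureAnalysisConfig = TextureAnalysisConfig()
    input_dir: Optional[Path] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def resolved_input_dir(self) -> Path:
        return self.input_dir if self.input_dir is not None else self.out_dir
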