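"""Pipeline configuration: every preprocessing parameter in one place.

The defaults are the operating point of the pipeline — 5 px border,
127/255 threshold, 20x20 opening, (0,0,200)-(255,255,255) brightness
range, the 5x5 Gabor kernel (sigma 3, theta pi, lambda pi/4, aspect 0.5,
phase 20), 1x30 vertical opening, 5x5 dilation, gamma 2.0 and CLAHE with
clip limit 1.0 on an 8x8 tile grid.  Configurations serialize to YAML and
round-trip losslessly.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dataset_ops import SplitRule
from .line_removal import GaborParams

__all__ = ["PipelineConfig", "STAGES"]

STAGES = ("artefact", "line", "gamma", "clahe1", "clahe2", "gfb")


@dataclass
class PipelineConfig:
    # artefact removal
    border_thickness: int = 5
    threshold: int = 127
    threshold_max: int = 255
    opening_kernel: tuple[int, int] = (20, 20)  # (width, height)
    # line removal
    inrange_low: tuple[int, int, int] = (0, 0, 200)
    inrange_high: tuple[int, int, int] = (255, 255, 255)
    gabor_ksize: tuple[int, int] = (5, 5)
    gabor_sigma: float = 3.0
    gabor_theta: float = math.pi
    gabor_lambd: float = math.pi / 4
    gabor_gamma: float = 0.5
    gabor_psi: float = 20.0
    gabor_psi_in_degrees: bool = False
    vertical_kernel: tuple[int, int] = (1, 30)
    dilation_kernel: tuple[int, int] = (5, 5)
    # enhancement
    gamma_value: float = 2.0
    clahe_clip: float | None = 1.0
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_passes: int = 2
    lut_path: str | None = None
    # orchestration
    stop_stage: str = "gfb"
    augment_enabled: bool = False
    split_rule: SplitRule = field(default_factory=SplitRule)
    seed: int = 0
    noise_variance: float | None = None
    noise_seed: int = 0

    def __post_init__(self) -> None:
        if self.stop_stage not in STAGES:
            raise ValueError(f"stop_stage must be one of {STAGES}")

    def gabor_params(self) -> GaborParams:
        return GaborParams(
            ksize=tuple(self.gabor_ksize),
            sigma=self.gabor_sigma,
            theta=self.gabor_theta,
            lambd=self.gabor_lambd,
            gamma=self.gabor_gamma,
            psi=self.gabor_psi,
            psi_in_degrees=self.gabor_psi_in_degrees,
        )

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["split_rule"] = asdict(self.split_rule)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "split_rule" in data and isinstance(data["split_rule"], dict):
            data["split_rule"] = SplitRule(**data["split_rule"])
        tuple_fields = {
            f.name for f in fields(cls) if "tuple" in str(f.type)
        }
        for name in tuple_fields:
            if name in data and isinstance(data[name], list):
                data[name] = tuple(data[name])
        return cls(**data)
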