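"""Analysis configuration: defaults, presets, TOML files and flag overrides.

Precedence, lowest to highest: built-in defaults, config file, preset, CLI
flags.  Unknown keys anywhere are fatal — a typo must not silently fall back
to a default.  The effective configuration is echoed into every run log so
each number in the outputs is auditable.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from .image import DEFAULT_PIXEL_SIZE_UM
from .segment import ExclusionParams


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ExclusionConfig(_Section):
    min_area_um2: float = 200.0
    max_area_um2: float = 13_000.0
    min_circularity: float = 0.4
    min_minor_diameter_um: float = 1.5

    def to_params(self) -> ExclusionParams:
        return ExclusionParams(self.min_area_um2, self.max_area_um2,
                               self.min_circularity, self.min_minor_diameter_um)


class DespeckleConfig(_Section):
    radius: int = Field(default=1, ge=1)


class ContrastConfig(_Section):
    saturated_fraction: float = Field(default=0.0035, ge=0.0, lt=0.5)


class BackgroundConfig(_Section):
    ball_radius_px: float = Field(default=50.0, ge=1.0)


class SegmentationConfig(_Section):
    closing_radius_px: int = Field(default=4, ge=0)
    tissue_close_radius_px: int = Field(default=20, ge=0)
    exclude_border: bool = True


class TypingConfig(_Section):
    positive_fraction_cutoff: float = Field(default=0.5, gt=0.0, le=1.0)
    erosion_px: int = Field(default=2, ge=0)


class NamingConfig(_Section):
    c1_suffix: str = "_C1"
    c2_suffix: str = "_C2"


class OutputConfig(_Section):
    table_format: Literal["csv", "xlsx"] = "csv"
    include_feret: bool = False
    write_images: bool = True


class AnalysisConfig(_Section):
    """Complete, serializable analysis configuration."""

    pixel_size_um: float = Field(default=DEFAULT_PIXEL_SIZE_UM, gt=0)
    exclusion: ExclusionConfig = Field(default_factory=ExclusionConfig)
    despeckle: DespeckleConfig = Field(default_factory=DespeckleConfig)
    contrast: ContrastConfig = Field(default_factory=ContrastConfig)
    background: BackgroundConfig = Field(default_factory=BackgroundConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    typing: TypingConfig = Field(default_factory=TypingConfig)
    naming: NamingConfig = Field(default_factory=NamingConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    #: optional palette override: color name -> [r, g, b]
    palette: dict[str, tuple[int, int, int]] | None = None

    def echo_lines(self) -> list[str]:
        """Flat ``section.key = value`` lines for the run log."""
        lines = []
        for key, value in sorted(self.model_dump().items()):
            if isinstance(value, dict):
                for sub, v in sorted(value.items()):
                    lines.append(f"{key}.{sub} = {v!r}")
            else:
                lines.append(f"{key} = {value!r}")
        return lines


#: Named parameter presets: the deltoid defaults and the larger-fiber
#: pectoral settings (max CSA 20,000 um^2, min minor diameter 8 um).
PRESETS: dict[str, dict] = {
    "deltoid": {},
    "pectoral": {"exclusion": {"max_area_um2": 20_000.0,
                               "min_minor_diameter_um": 8.0}},
}


def _deep_merge(base: dict, update: dict) -> dict:
    out = dict(base)
    for key, value in update.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(
    path=None,
    preset: str | None = None,
    overrides: dict | None = None,
) -> AnalysisConfig:
    """Build the effective config from defaults, file, preset and flags.

    ``overrides`` is a nested dict in the same shape as the config (CLI flag
    values).  Unknown keys raise a validation error.
    """
    data: dict = {}
    if path is not None:
        with open(Path(path), "rb") as fh:
            data = _deep_merge(data, tomllib.load(fh))
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset '{preset}'; choose from {sorted(PRESETS)}")
        data = _deep_merge(data, PRESETS[preset])
    if overrides:
        data = _deep_merge(data, overrides)
    return AnalysisConfig(**data)
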