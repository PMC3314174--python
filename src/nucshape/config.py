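"""Pipeline configuration: defaults, YAML (de)serialization, validation.

Every numeric parameter of the pipeline is exposed here with the published
default. Unknown keys in a config file are rejected and every value is
range-checked on load, so a typo fails fast instead of silently running
with a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields

import yaml

from nucshape.snake import SnakeParams

CONFIG_VERSION = 1


@dataclass
class PreprocessParams:
    tile_grid: tuple[int, int] = (8, 8)
    clip_limit: float = 0.02
    distribution: str = "rayleigh"
    rayleigh_sigma: float = 0.4
    n_bins: int = 64
    min_area: float = 800.0
    outer_erode_r: int = 3
    outer_dilate_r: int = 6
    inner_erode_r: int = 2
    saturate_frac: float = 0.01
    low_frac: float = 0.7
    high_frac: float = 1.3
    connectivity: int = 8

    def __post_init__(self) -> None:
        self.tile_grid = tuple(self.tile_grid)
        if len(self.tile_grid) != 2 or min(self.tile_grid) < 1:
            raise ValueError("tile_grid must be two integers >= 1")
        if not (0.0 < self.clip_limit <= 1.0):
            raise ValueError("clip_limit must lie in (0, 1]")
        if self.distribution not in ("rayleigh", "uniform"):
            raise ValueError("distribution must be 'rayleigh' or 'uniform'")
        if self.rayleigh_sigma <= 0:
            raise ValueError("rayleigh_sigma must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")
        for name in ("outer_erode_r", "outer_dilate_r", "inner_erode_r"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.saturate_frac < 0.5):
            raise ValueError("saturate_frac must lie in [0, 0.5)")
        if not (0.0 < self.low_frac < self.high_frac):
            raise ValueError("need 0 < low_frac < high_frac")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class MetricParams:
    curvature_offset: int = 25
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.curvature_offset < 1:
            raise ValueError("curvature_offset must be >= 1")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class PopulationParams:
    heatmap_rows: int = 200
    curvature_cutoff: float = 0.15
    correlation: str = "pearson"
    linkage: str = "average"

    def __post_init__(self) -> None:
        if self.heatmap_rows < 2:
            raise ValueError("heatmap_rows must be >= 2")
        if self.curvature_cutoff <= 0:
            raise ValueError("curvature_cutoff must be > 0")
        if self.correlation not in ("pearson", "spearman"):
            raise ValueError("correlation must be 'pearson' or 'spearman'")


@dataclass
class PipelineConfig:
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    snake: SnakeParams = field(default_factory=SnakeParams)
    metrics: MetricParams = field(default_factory=MetricParams)
    population: PopulationParams = field(default_factory=PopulationParams)

    def to_dict(self) -> dict:
        d = {"version": CONFIG_VERSION}
        for f in fields(self):
            section = dataclasses.asdict(getattr(self, f.name))
            section = {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in section.items()}
            d[f.name] = section
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d.pop("version", None)
        sections = {f.name: f for f in fields(cls)}
        unknown = set(d) - set(sections)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, f in sections.items():
            sub = d.get(name, {})
            sub_cls = f.default_factory  # type: ignore[union-attr]
            valid = {sf.name for sf in fields(sub_cls)}
            bad = set(sub) - valid
            if bad:
                raise ValueError(f"unknown keys in config section "
                                 f"'{name}': {sorted(bad)}")
            kwargs[name] = sub_cls(**sub)
        return cls(**kwargs)


def load_config(path: str | None = None) -> PipelineConfig:
    """Load a YAML config (defaults when ``path`` is None)."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(cfg: PipelineConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
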