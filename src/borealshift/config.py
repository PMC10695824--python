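"""Pipeline configuration: a single serializable object for a full run.

The defaults define the standard desk-scale study conditions: a 256x256
synthetic landscape at 30 m, reflectance noise 0.01, 2,000 inventory
plots, epochs 2000 and 2015 with a 2010 canopy reference, and
tree-dominated threshold 0.25.  Configs round-trip losslessly through
YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .synthetic import ConfigurationError, GenerationConfig

DEFAULT_SEASON_MONTHS = {
    "spring": [3, 4, 5],
    "summer": [6, 7, 8],
    "fall": [9, 10, 11],
}

DEFAULT_COVER_GRID = {
    "n_trees": [150],
    "max_features": ["sqrt", 1.0 / 3.0],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1],
}

DEFAULT_ALBEDO_HYPERPARAMS = {
    "n_trees": 100,
    "max_features": 1.0,
    "min_samples_split": 5,
    "min_samples_leaf": 2,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    epochs: tuple[int, int] = (2000, 2015)
    reference_epoch: int = 2010
    season_months: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_SEASON_MONTHS.items()})
    generation: GenerationConfig = field(default_factory=GenerationConfig)
    # reflectance rendering
    n_dates: int = 4
    cloud_fraction: float = 0.08
    reflectance_noise_sd: float = 0.01
    # inventory
    n_plots: int = 2000
    ba_noise: float = 0.05
    bin_width: float = 0.1
    undersample_target: int | None = 80
    train_fraction: float = 0.70
    thin_distance: float = 1000.0
    # features / models
    correlation_threshold: float = 0.95
    prune_sample_size: int = 2000
    cover_grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_COVER_GRID.items()})
    cv_folds: int = 5
    cv_repeats: int = 2
    canopy_n_per_stratum: int = 250
    canopy_reference_noise_sd: float = 0.02
    # albedo / forcing
    n_albedo_days: int = 6
    albedo_coarse_factor: int = 16
    albedo_noise_sd: float = 0.01
    albedo_n_per_bin: int = 200
    albedo_hyperparams: dict = field(default_factory=lambda: dict(DEFAULT_ALBEDO_HYPERPARAMS))
    # change analysis
    tree_cover_threshold: float = 0.25
    z_critical: float = 1.96
    split_regions: bool = True  # default two-half west/east regional summary

    def validate(self) -> None:
        if len(self.epochs) < 2 or any(
            b <= a for a, b in zip(self.epochs, self.epochs[1:])
        ):
            raise ConfigurationError(f"epochs must be strictly increasing: {self.epochs}")
        if not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError(f"train_fraction must be in (0, 1): {self.train_fraction}")
        if not (0.0 < self.tree_cover_threshold < 1.0):
            raise ConfigurationError(
                f"tree_cover_threshold must be in (0, 1): {self.tree_cover_threshold}"
            )
        if not (0.0 < self.correlation_threshold <= 1.0):
            raise ConfigurationError(
                f"correlation_threshold must be in (0, 1]: {self.correlation_threshold}"
            )
        if self.z_critical <= 0:
            raise ConfigurationError(f"z_critical must be > 0: {self.z_critical}")
        self.generation.validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epochs"] = list(self.epochs)
        gen = d["generation"]
        gen["grid_shape"] = list(self.generation.grid_shape)
        gen["fire_year_range"] = list(self.generation.fire_year_range)
        gen["fire_radius_range"] = list(self.generation.fire_radius_range)
        gen["endmembers"] = np.asarray(self.generation.endmembers).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        gen = dict(d.pop("generation", {}))
        for key in ("grid_shape", "fire_year_range", "fire_radius_range"):
            if key in gen:
                gen[key] = tuple(gen[key])
        if "endmembers" in gen:
            gen["endmembers"] = np.asarray(gen["endmembers"], dtype=float)
        if "epochs" in d:
            d["epochs"] = tuple(d["epochs"])
        cfg = cls(generation=GenerationConfig(**gen), **d)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
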