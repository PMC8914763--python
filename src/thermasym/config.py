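"""Run configuration for the thermogram-asymmetry pipeline.

A single :class:`PipelineConfig` object carries every tunable parameter of the
pipeline, from the physical plausibility window applied at file-read time to
the train/test protocol of the classifier.  All values have defaults matching
the published analysis protocol; any subset can be overridden from a YAML or
JSON key-value file.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Mapping

import yaml

from .exceptions import ConfigError

__all__ = ["PipelineConfig"]


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the full pipeline.

    Parameters
    ----------
    delta_t_threshold_c:
        Left-right asymmetry threshold in °C.  Asymmetry strictly above this
        value is treated as abnormal; it is also the margin used by the
        pixel-exceedance counts ``nf``/``nm``.
    edge_threshold_frac:
        Edge pixels are those whose gradient magnitude is at least this
        fraction of the maximum gradient magnitude inside the region of
        interest.
    body_temp_floor_c:
        Pixels at or above this temperature are considered body surface; used
        as the region of interest for face-view edge detection.
    mouth_temp_floor_c:
        Pixels at or above this temperature are considered open mouth cavity;
        used as the region of interest for mouth-view edge detection.
    n_estimates:
        Number of repeated contour estimates averaged per feature vector.
    jitter_px:
        Half-width (pixels) of the uniform perturbation applied to hull
        vertices in repeat estimates, emulating manual contour adjustment.
    k_neighbors:
        Neighborhood size of the classifier.  Only ``k = 1`` is supported.
    standardize_features:
        If true, features are z-scored per dimension using training-set
        statistics before distances are computed.
    n_train_per_class:
        Training-set size per class in each random split.
    n_repeats:
        Number of random train/test splits pooled into one report.
    min_temp_c, max_temp_c:
        Physical plausibility window applied to every input temperature
        (defaults are the camera's rated range).
    rng_seed:
        Seed for every stochastic step of a pipeline run.
    """

    delta_t_threshold_c: float = 0.4
    edge_threshold_frac: float = 0.2
    body_temp_floor_c: float = 27.0
    mouth_temp_floor_c: float = 34.5
    n_estimates: int = 5
    jitter_px: float = 1.0
    k_neighbors: int = 1
    standardize_features: bool = True
    n_train_per_class: int = 12
    n_repeats: int = 12
    min_temp_c: float = -20.0
    max_temp_c: float = 250.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.delta_t_threshold_c > 0:
            raise ConfigError("delta_t_threshold_c must be > 0")
        if not 0.0 < self.edge_threshold_frac < 1.0:
            raise ConfigError("edge_threshold_frac must lie strictly in (0, 1)")
        if self.k_neighbors < 1 or self.k_neighbors % 2 == 0:
            raise ConfigError("k_neighbors must be a positive odd integer")
        if self.n_estimates < 1:
            raise ConfigError("n_estimates must be >= 1")
        if self.jitter_px < 0:
            raise ConfigError("jitter_px must be >= 0")
        if self.n_train_per_class < 1:
            raise ConfigError("n_train_per_class must be >= 1")
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if not self.min_temp_c < self.max_temp_c:
            raise ConfigError("min_temp_c must be below max_temp_c")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a YAML (or JSON) key-value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: expected a key-value mapping")
        return cls.from_mapping(data)

    def replace(self, **kwargs: Any) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
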