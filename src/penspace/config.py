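"""Run configuration: defaults, YAML loading, validation.

Precedence when assembling a run: CLI flags > YAML config file > defaults.
Every component invariant is re-validated here at parse time so a bad
combination fails before any frame is decoded.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .background_subtraction import NATIVE_ALGORITHMS
from .errors import ConfigurationError
from .motion_pipeline import CentroidParams, MorphParams
from .space_metrics import RangeParams
from .visualization import COLORMAP_NAMES


@dataclass
class RunConfig:
    """Full configuration of one analysis run."""

    input_path: str
    output_dir: str = "penspace_out"
    mask_path: Optional[str] = None
    algorithm: str = "mog2"
    algorithm_params: dict = field(default_factory=dict)
    interval_n: int = 1
    kernel_size: int = 3
    area_threshold: float = 50.0
    connectivity: int = 8
    alpha: float = 0.7
    beta: float = 0.7
    colormap: str = "hot"
    core_mass: float = 0.50
    full_mass: float = 0.95
    bandwidth_rule: str = "scott"
    fixed_bandwidth: Optional[float] = None
    fps: float = 15.0
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


_FIELDS = set(RunConfig.__dataclass_fields__)


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults and reject invalid combinations with actionable messages."""
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigurationError(
            f"unknown config keys: {', '.join(sorted(unknown))}"
        )
    if "input_path" not in raw or raw["input_path"] in (None, ""):
        raise ConfigurationError("config needs an input_path")
    cfg = RunConfig(**raw)
    if cfg.interval_n < 1:
        raise ConfigurationError(f"interval must be >= 1, got {cfg.interval_n}")
    if not (0 <= cfg.alpha <= 1) or not (0 <= cfg.beta <= 1):
        raise ConfigurationError("alpha and beta must be in [0, 1]")
    if cfg.alpha + cfg.beta <= 0:
        raise ConfigurationError("alpha + beta must be > 0")
    if cfg.colormap not in COLORMAP_NAMES:
        raise ConfigurationError(
            f"unknown colormap {cfg.colormap!r}; valid: "
            f"{', '.join(COLORMAP_NAMES)}"
        )
    if not (cfg.algorithm in NATIVE_ALGORITHMS
            or cfg.algorithm.startswith("external:")):
        raise ConfigurationError(
            f"unknown algorithm {cfg.algorithm!r}; valid: "
            f"{', '.join(NATIVE_ALGORITHMS)} or external:<id>"
        )
    MorphParams(kernel_size=cfg.kernel_size).validate()
    CentroidParams(area_threshold=cfg.area_threshold,
                   connectivity=cfg.connectivity).validate()
    RangeParams(core_mass=cfg.core_mass, full_mass=cfg.full_mass,
                bandwidth_rule=cfg.bandwidth_rule,
                fixed_bandwidth=cfg.fixed_bandwidth).validate()
    return cfg


def load_config(path=None, overrides: Optional[dict] = None) -> RunConfig:
    """YAML file + overrides -> validated RunConfig."""
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        raw.update(loaded)
    for key, value in (overrides or {}).items():
        if value is not None:
            raw[key] = value
    return validate_config(raw)
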