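"""Pipeline configuration with a strict YAML schema.

Unknown keys are rejected; defaults mirror the study protocol where it
is printed (classification threshold 0.001 %/min, alpha 5,000 ->
40,000, phase windows 30-110 / 120-160 min, 2-step TSC smoothing,
1-step trajectory smoothing). The resolved config round-trips
losslessly through YAML and is logged with every run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .solver import UromtConfig

__all__ = ["SimulateConfig", "MetricsConfig", "PipelineConfig", "load_config", "save_config"]


@dataclass
class SimulateConfig:
    shape: tuple[int, int, int] = (24, 24, 24)
    n_frames: int = 15
    frame_interval_min: float = 10.0
    first_frame_time_min: float = 30.0
    noise_sd: float = 0.0
    voxel_size_mm: tuple[float, float, float] = (0.2, 0.2, 0.2)


@dataclass
class MetricsConfig:
    flux_threshold: float = 0.001  # %/min
    influx_window_min: tuple[float, float] = (30.0, 110.0)
    clearance_window_min: tuple[float, float] = (120.0, 160.0)
    trajectory_smooth_window: int = 1
    tsc_smooth_window: int = 2


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "glymflux_out"
    series_path: str | None = None  # None -> simulate from the phantom
    mask_path: str | None = None
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    uromt: UromtConfig = field(default_factory=UromtConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)


def _build(cls, data: dict, context: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        if name in ("simulate", "uromt", "metrics") and isinstance(value, dict):
            sub = {"simulate": SimulateConfig, "uromt": UromtConfig, "metrics": MetricsConfig}[name]
            kwargs[name] = _build(sub, value, name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value) if name != "alpha_schedule" else np.asarray(value, dtype=float)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path} must contain a YAML mapping")
    return _build(PipelineConfig, data, "pipeline")


def config_to_dict(config: PipelineConfig) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return [float(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return clean(asdict(config))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=False))
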