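"""End-to-end run: simulate (or load) a series, invert it, extract metrics.

Every artifact lands in the configured output directory and is listed
with a content hash in ``manifest.json`` together with the fully
resolved configuration, so a rerun with the same config and seed is
verifiable as identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .config import PipelineConfig, config_to_dict
from .containers import DceSeries
from .metrics import (
    RoiMask,
    build_trajectory,
    phase_means,
    smooth_trajectory,
)
from .phantom import make_phantom
from .simulate import simulate_dce_series
from .solver import run_series

__all__ = ["run_pipeline"]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis chain; returns the artifact directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    rois: dict[str, np.ndarray] = {}
    with _stage("input"):
        if config.series_path is not None:
            series = gio.read_series(config.series_path, config.mask_path)
        else:
            phantom = make_phantom(
                shape=config.simulate.shape,
                seed=config.seed,
                voxel_size=config.simulate.voxel_size_mm,
            )
            series, _ = simulate_dce_series(
                phantom,
                noise_sd=config.simulate.noise_sd,
                n_frames=config.simulate.n_frames,
                frame_interval=config.simulate.frame_interval_min,
                seed=config.seed,
                first_frame_time=config.simulate.first_frame_time_min,
                n_substeps=config.uromt.n_substeps,
            )
            rois = phantom.roi_masks
            gio.write_series(series, out / "series.nii", out / "tissue_mask.nii")
            for name, mask in rois.items():
                gio.write_mask(mask, series.voxel_size, out / f"roi_{name}.nii")
        if not rois:
            rois = {"tissue": series.tissue_mask}

    with _stage("solve"):
        flux_maps = run_series(series, config.uromt)
        for m in flux_maps:
            gio.write_flux_map(
                m, series.voxel_size, out / f"rflux_{m.pair_index:02d}.nii"
            )

    with _stage("metrics"):
        rows = []
        summaries = {}
        for name, mask in rois.items():
            roi = RoiMask(name=name, mask=mask, voxel_size=series.voxel_size)
            traj = build_trajectory(
                flux_maps, roi, threshold=config.metrics.flux_threshold
            )
            traj = smooth_trajectory(traj, config.metrics.trajectory_smooth_window)
            summary = phase_means(
                traj,
                config.metrics.influx_window_min,
                config.metrics.clearance_window_min,
            )
            summaries[name] = {
                "influx_net_rate_pct_per_min": summary.influx_net_rate,
                "clearance_net_rate_pct_per_min": summary.clearance_net_rate,
                "influx_window_min": list(summary.influx_window),
                "clearance_window_min": list(summary.clearance_window),
            }
            for i in range(len(traj)):
                rows.append(
                    {
                        "roi": name,
                        "time_min": traj.times[i],
                        "influx_mm3": traj.influx_volume[i],
                        "clearance_mm3": traj.clearance_volume[i],
                        "influx_frac": traj.influx_fraction[i],
                        "clearance_frac": traj.clearance_fraction[i],
                        "net_rate_pct_per_min": traj.net_rate[i],
                    }
                )
        pd.DataFrame(rows).to_csv(out / "trajectories.csv", index=False)
        (out / "phase_summaries.json").write_text(json.dumps(summaries, indent=1))

    with _stage("manifest"):
        files = sorted(
            p for p in out.iterdir() if p.is_file() and p.name != "manifest.json"
        )
        manifest = {
            "seed": config.seed,
            "config": config_to_dict(config),
            "n_flux_maps": len(flux_maps),
            "files": {p.name: gio.file_sha256(p) for p in files},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return out
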