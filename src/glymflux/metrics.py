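"""Regional influx/clearance readouts from r-flux map series.

Voxels with r-flux strictly above +threshold (0.001 %/min by default)
are influx voxels and strictly below -threshold clearance voxels;
voxels at or inside the band belong to neither. Per-ROI volumes,
volume fractions, and net rates (the spatial mean of r-flux over ALL
ROI voxels) are stacked into 14-point time trajectories, optionally
smoothed by a centered 1-step moving average, and summarized over the
influx- (30-110 min) and clearance-dominated (120-160 min) phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import FluxMap

__all__ = [
    "RoiMask",
    "RegionTrajectory",
    "PhaseSummary",
    "classify_voxels",
    "regional_volumes",
    "net_rate",
    "build_trajectory",
    "smooth_trajectory",
    "phase_means",
]

INFLUX_WINDOW = (30.0, 110.0)
CLEARANCE_WINDOW = (120.0, 160.0)


@dataclass
class RoiMask:
    name: str
    mask: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def volume_mm3(self) -> float:
        return int(self.mask.sum()) * self.voxel_volume_mm3


@dataclass
class RegionTrajectory:
    roi: str
    times: np.ndarray  # minutes, interval midpoints
    influx_volume: np.ndarray  # mm^3
    clearance_volume: np.ndarray  # mm^3
    influx_fraction: np.ndarray
    clearance_fraction: np.ndarray
    net_rate: np.ndarray  # %/min
    smoothed: bool = False

    def __post_init__(self) -> None:
        arrays = (
            self.times,
            self.influx_volume,
            self.clearance_volume,
            self.influx_fraction,
            self.clearance_fraction,
            self.net_rate,
        )
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValueError("trajectory arrays must share one length")
        fsum = self.influx_fraction + self.clearance_fraction
        if np.any(self.influx_fraction < 0) or np.any(self.clearance_fraction < 0):
            raise ValueError("fractions must be non-negative")
        if np.any(fsum > 1 + 1e-12):
            raise ValueError("influx_fraction + clearance_fraction exceeds 1")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PhaseSummary:
    roi: str
    influx_net_rate: float  # mean net rate over the influx window, %/min
    clearance_net_rate: float  # mean over the clearance window, %/min
    influx_window: tuple[float, float] = INFLUX_WINDOW
    clearance_window: tuple[float, float] = CLEARANCE_WINDOW


def classify_voxels(
    flux: FluxMap, threshold: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split a map into influx (> threshold) and clearance (< -threshold) masks."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    influx = flux.values > threshold
    clearance = flux.values < -threshold
    return influx, clearance


def regional_volumes(
    influx_mask: np.ndarray, clearance_mask: np.ndarray, roi: RoiMask
) -> tuple[tuple[float, float], tuple[float, float]]:
    """ROI influx/clearance volumes (mm^3) and volume fractions.

    Volume is the voxel count inside the ROI times the voxel volume;
    the fraction divides by the total ROI volume.
    """
    if influx_mask.shape != roi.mask.shape or clearance_mask.shape != roi.mask.shape:
        raise ValueError(
            f"mask grids {influx_mask.shape}/{clearance_mask.shape} do not match "
            f"ROI grid {roi.mask.shape}"
        )
    vv = roi.voxel_volume_mm3
    n_roi = int(roi.mask.sum())
    n_in = int((influx_mask & roi.mask).sum())
    n_cl = int((clearance_mask & roi.mask).sum())
    volumes = (n_in * vv, n_cl * vv)
    fractions = (n_in / n_roi, n_cl / n_roi)
    return volumes, fractions


def net_rate(flux: FluxMap, roi: RoiMask) -> float:
    """Spatial mean of r-flux over all ROI voxels (%/min), sub-threshold included."""
    if flux.values.shape != roi.mask.shape:
        raise ValueError(
            f"flux grid {flux.values.shape} does not match ROI grid {roi.mask.shape}"
        )
    return float(flux.values[roi.mask].mean())


def build_trajectory(
    maps: list[FluxMap], roi: RoiMask, threshold: float = 0.001
) -> RegionTrajectory:
    """Stack per-map regional metrics into a time trajectory.

    Times are the midpoints of each map's interval.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 flux maps")
    shapes = {m.values.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"flux maps disagree on grid shape: {sorted(shapes)}")
    if maps[0].values.shape != roi.mask.shape:
        raise ValueError(
            f"flux grid {maps[0].values.shape} does not match ROI grid {roi.mask.shape}"
        )
    times, iv, cv, if_, cf, nr = [], [], [], [], [], []
    for m in maps:
        infl, clear = classify_voxels(m, threshold)
        (vol_i, vol_c), (fr_i, fr_c) = regional_volumes(infl, clear, roi)
        times.append(m.midpoint)
        iv.append(vol_i)
        cv.append(vol_c)
        if_.append(fr_i)
        cf.append(fr_c)
        nr.append(net_rate(m, roi))
    return RegionTrajectory(
        roi=roi.name,
        times=np.asarray(times),
        influx_volume=np.asarray(iv),
        clearance_volume=np.asarray(cv),
        influx_fraction=np.asarray(if_),
        clearance_fraction=np.asarray(cf),
        net_rate=np.asarray(nr),
    )


def _centered_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average over 2*window+1 points, truncated at the ends."""
    n = len(x)
    out = np.empty_like(np.asarray(x, dtype=float))
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n, i + window + 1)
        out[i] = np.mean(x[lo:hi])
    return out


def smooth_trajectory(traj: RegionTrajectory, window: int = 1) -> RegionTrajectory:
    """Noise-cancelling moving average over trajectory series.

    A centered average over ``2*window + 1`` neighborhoods with
    shrinking windows at the ends, so length is preserved and a
    constant series is unchanged. ``window=0`` is the identity.
    """
    if window < 0:
        raise ValueError("window must be non-negative")
    if window == 0:
        return replace(traj, smoothed=traj.smoothed)
    return RegionTrajectory(
        roi=traj.roi,
        times=traj.times.copy(),
        influx_volume=_centered_moving_average(traj.influx_volume, window),
        clearance_volume=_centered_moving_average(traj.clearance_volume, window),
        influx_fraction=_centered_moving_average(traj.influx_fraction, window),
        clearance_fraction=_centered_moving_average(traj.clearance_fraction, window),
        net_rate=_centered_moving_average(traj.net_rate, window),
        smoothed=True,
    )


def phase_means(
    traj: RegionTrajectory,
    influx_window: tuple[float, float] = INFLUX_WINDOW,
    clearance_window: tuple[float, float] = CLEARANCE_WINDOW,
) -> PhaseSummary:
    """Mean net rate over the influx- and clearance-dominated windows.

    A map belongs to a window when its interval midpoint falls inside
    the closed window. A window containing no points is rejected.
    """
    means = []
    for window in (influx_window, clearance_window):
        inside = (traj.times >= window[0]) & (traj.times <= window[1])
        if not inside.any():
            raise ValueError(
                f"window {window} contains no trajectory time points "
                f"(times span {traj.times[0]}..{traj.times[-1]} min)"
            )
        means.append(float(traj.net_rate[inside].mean()))
    return PhaseSummary(
        roi=traj.roi,
        influx_net_rate=means[0],
        clearance_net_rate=means[1],
        influx_window=tuple(influx_window),
        clearance_window=tuple(clearance_window),
    )
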