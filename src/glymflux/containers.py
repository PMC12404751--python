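"""Shared in-memory containers for the imaging pipeline.

Densities are percent-signal-change images (directly proportional to
tracer concentration), times are minutes from infusion start, and
spatial units are voxels unless a ``voxel_size`` converts to mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class DceSeries:
    """4D tracer series: ordered 3D percent-signal-change frames.

    Attributes
    ----------
    frames
        Array of shape ``(n_frames, nx, ny, nz)``, percent signal change
        from baseline (%).
    frame_times
        Minutes from tracer-infusion start, strictly increasing,
        length ``n_frames``.
    voxel_size
        Isotropic or per-axis voxel edge length in mm, length 3.
    tissue_mask
        Boolean 3D volume on the frame grid.
    """

    frames: np.ndarray
    frame_times: np.ndarray
    voxel_size: tuple[float, float, float]
    tissue_mask: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
        if self.frames.ndim != 4:
            raise ValueError(
                f"frames must be 4D (n_frames, nx, ny, nz); got shape {self.frames.shape}"
            )
        if len(self.frame_times) != self.frames.shape[0]:
            raise ValueError(
                f"{len(self.frame_times)} frame times for {self.frames.shape[0]} frames"
            )
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.tissue_mask.shape != self.frames.shape[1:]:
            raise ValueError(
                f"tissue_mask shape {self.tissue_mask.shape} does not match "
                f"frame grid {self.frames.shape[1:]}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frames.shape[1:]

    @property
    def n_pairs(self) -> int:
        return self.n_frames - 1


@dataclass
class VelocityField:
    """Per-pair velocity field, ``components`` of shape (3, nx, ny, nz), voxel/min."""

    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 4 or self.components.shape[0] != 3:
            raise ValueError(
                f"velocity components must have shape (3, nx, ny, nz); got {self.components.shape}"
            )

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt(np.sum(self.components**2, axis=0))


@dataclass
class SourceField:
    """Relative source r (1/min): shape (nx, ny, nz), or (n_substeps, nx, ny, nz)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (3, 4):
            raise ValueError(
                f"source values must be 3D or (n_substeps, nx, ny, nz); got {self.values.shape}"
            )


@dataclass
class FluxMap:
    """Time-averaged relative source over one frame pair (r-flux, % per minute)."""

    values: np.ndarray
    interval: tuple[float, float]
    pair_index: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"flux map must be 3D; got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("flux map contains non-finite values")
        if not self.interval[1] > self.interval[0]:
            raise ValueError(f"degenerate interval {self.interval}")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.interval[0] + self.interval[1])


@dataclass
class Tsc:
    """Time signal curve of one structure (dcLN, eCA, iCA, pFV, CSF...)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    normalization: str = "baseline"  # "baseline" (% of baseline) or "peak_csf"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be matching 1D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.normalization not in ("baseline", "peak_csf", "raw"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


@dataclass
class IcpRecording:
    """Sampled intracranial pressure waveform (mmHg) at fixed rate fs (Hz)."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1D")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs
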