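"""Synthetic DCE series, drainage curves, and ICP waveforms.

The default influx-clearance scenario emulates the measured timeline:
tracer entering from a CSF inlet dominates for roughly the first 120
minutes of a 15-frame, 10-minute-interval series, after which a
spatially broad negative source (clearance) takes over. Every frame is
generated by the same forward transport model the solver inverts, so a
noiseless series is exactly regenerable from its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import DceSeries, IcpRecording, Tsc
from .phantom import Phantom, make_phantom
from .transport import GroundTruth, forward_transport, required_substeps

__all__ = [
    "InfluxClearanceScenario",
    "simulate_dce_series",
    "simulate_icp",
    "simulate_tsc",
]


@dataclass(frozen=True)
class InfluxClearanceScenario:
    """Schedule of ground-truth transport fields over the frame pairs.

    The influx source is a Gaussian bump (length scale ``influx_scale``
    as a fraction of min(shape)) anchored at the CSF inlet whose
    amplitude decays geometrically across pairs; the clearance source is
    a broader Gaussian at the tissue center whose amplitude ramps in
    through a sigmoid centered at ``clearance_onset_frac`` of the pair
    sequence. Velocity is a small radial outflow from the inlet.

    Amplitudes are relative rates (1/min); see docs/methods.md for how
    the defaults were chosen.
    """

    influx_amplitude: float = 0.045
    influx_decay_frac: float = 0.36  # e-folding of the amplitude, fraction of n_pairs
    influx_scale: float = 0.17
    clearance_amplitude: float = 0.02
    clearance_onset_frac: float = 0.65
    clearance_width_frac: float = 0.07
    clearance_scale: float = 0.34
    velocity_amplitude: float = 0.08  # voxel/min
    velocity_scale: float = 0.21
    sigma: float = 0.002  # voxel^2/min
    baseline_background: float = 0.5  # percent signal change far from the inlet
    baseline_amplitude: float = 20.0  # percent signal change at the inlet core
    baseline_scale: float = 0.21


def _distance_from(shape: tuple[int, int, int], center: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    return np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    return np.array(np.nonzero(mask), dtype=float).mean(axis=1)


def build_ground_truth(
    phantom: Phantom,
    scenario: InfluxClearanceScenario,
    n_pairs: int,
) -> GroundTruth:
    """Materialize per-pair velocity and source fields for a phantom."""
    shape = phantom.shape
    scale = min(shape)
    tissue = phantom.tissue_mask
    inlet_c = _mask_centroid(phantom.csf_inlet_mask)
    tissue_c = _mask_centroid(tissue)

    d_in = _distance_from(shape, inlet_c)
    d_ct = _distance_from(shape, tissue_c)
    ell_in = scenario.influx_scale * scale
    ell_cl = scenario.clearance_scale * scale
    influx_shape = np.exp(-(d_in**2) / (2 * ell_in**2)) * tissue
    clearance_shape = np.exp(-(d_ct**2) / (2 * ell_cl**2)) * tissue

    # radial outflow from the inlet, tapered by a Gaussian envelope
    ell_v = scenario.velocity_scale * scale
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    envelope = scenario.velocity_amplitude * np.exp(-(d_in**2) / (2 * ell_v**2)) * tissue
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = [np.where(d_in > 0, (g - c) / np.maximum(d_in, 1e-12), 0.0)
                for g, c in zip(grids, inlet_c)]
    velocity_pair = np.stack([envelope * u for u in unit])

    tau = max(scenario.influx_decay_frac * n_pairs, 1e-6)
    onset = scenario.clearance_onset_frac * n_pairs
    width = max(scenario.clearance_width_frac * n_pairs, 1e-6)

    velocity = np.empty((n_pairs, 3, *shape))
    source = np.empty((n_pairs, *shape))
    for k in range(n_pairs):
        a_in = scenario.influx_amplitude * np.exp(-k / tau)
        a_cl = scenario.clearance_amplitude / (1.0 + np.exp(-(k - onset) / width))
        source[k] = a_in * influx_shape - a_cl * clearance_shape
        velocity[k] = velocity_pair * np.exp(-k / tau)
    return GroundTruth(velocity=velocity, source=source, sigma=scenario.sigma)


def initial_frame(phantom: Phantom, scenario: InfluxClearanceScenario) -> np.ndarray:
    """Percent-signal-change image at the first frame time."""
    shape = phantom.shape
    inlet_c = _mask_centroid(phantom.csf_inlet_mask)
    d_in = _distance_from(shape, inlet_c)
    ell = scenario.baseline_scale * min(shape)
    rho0 = (
        scenario.baseline_background
        + scenario.baseline_amplitude * np.exp(-(d_in**2) / (2 * ell**2))
    ) * phantom.tissue_mask
    return rho0


def simulate_dce_series(
    phantom: Phantom,
    scenario: InfluxClearanceScenario | None = None,
    noise_sd: float = 0.0,
    n_frames: int = 15,
    frame_interval: float = 10.0,
    seed: int = 0,
    first_frame_time: float = 30.0,
    n_substeps: int = 10,
) -> tuple[DceSeries, GroundTruth]:
    """Generate a DCE-like series and the ground truth that produced it.

    With ``noise_sd == 0`` each frame equals ``forward_transport`` of
    the previous one under the per-pair ground truth; noise is additive
    Gaussian on the percent-change values, truncated at zero. The
    default 15 frames at 10-minute intervals yield 14 inter-frame pairs.
    """
    if n_frames < 3:
        raise ValueError("n_frames must be at least 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if scenario is None:
        scenario = InfluxClearanceScenario()
    n_pairs = n_frames - 1
    gt = build_ground_truth(phantom, scenario, n_pairs)

    n_min = max(
        required_substeps(gt.velocity[k], gt.sigma, frame_interval)
        for k in range(n_pairs)
    )
    n_sub = max(n_substeps, n_min)

    frames = np.empty((n_frames, *phantom.shape))
    frames[0] = initial_frame(phantom, scenario)
    for k in range(n_pairs):
        frames[k + 1] = forward_transport(
            frames[k], gt, frame_interval, n_sub, pair=k
        )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        frames = np.maximum(frames + rng.normal(0.0, noise_sd, frames.shape), 0.0)

    times = first_frame_time + frame_interval * np.arange(n_frames)
    series = DceSeries(
        frames=frames,
        frame_times=times,
        voxel_size=phantom.voxel_size,
        tissue_mask=phantom.tissue_mask,
    )
    return series, gt


def simulate_icp(
    mean_mmHg: float = 3.79,
    cardiac_hz: float = 6.0,
    resp_hz: float = 1.0,
    fs: float = 10_000.0,
    duration: float = 300.0,
    seed: int = 0,
    cardiac_amp: float = 0.5,
    resp_amp: float = 0.3,
    noise_sd: float = 0.05,
    settle_s: float = 0.0,
    settle_offset: float = 0.0,
) -> IcpRecording:
    """Pulsatile ICP waveform: mean + cardiac and respiratory sines.

    ``settle_s``/``settle_offset`` optionally prepend an exponentially
    decaying offset emulating the period before the pressure reading
    stabilizes after catheter connection.
    """
    if fs <= 2 * cardiac_hz:
        raise ValueError("fs must exceed twice the cardiac frequency")
    if duration <= 60:
        raise ValueError("duration must exceed 60 s")
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    samples = (
        mean_mmHg
        + cardiac_amp * np.sin(2 * np.pi * cardiac_hz * t)
        + resp_amp * np.sin(2 * np.pi * resp_hz * t)
    )
    if settle_s > 0 and settle_offset != 0.0:
        samples = samples + settle_offset * np.exp(-t / (settle_s / 3.0)) * (t < settle_s)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, n)
    return IcpRecording(samples=samples, fs=fs)


def simulate_tsc(
    plateau_fraction: float = 0.35,
    rise_time: float = 40.0,
    n_points: int = 30,
    noise_sd: float = 0.0,
    seed: int = 0,
    total_span: float = 160.0,
    label: str = "stream",
) -> Tsc:
    """Monotone saturating drainage-stream curve in peak-CSF units.

    value(t) = plateau_fraction * (1 - exp(-t / rise_time)), plus
    optional Gaussian noise (fraction-of-peak units). Defaults mimic
    external-carotid streams plateauing at 30%-40% of the peak CSF
    signal by the end of a 160-minute acquisition.
    """
    if not 0.0 <= plateau_fraction <= 1.0:
        raise ValueError("plateau_fraction must be in [0, 1]")
    times = np.linspace(0.0, total_span, n_points)
    values = plateau_fraction * (1.0 - np.exp(-times / rise_time))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, n_points)
    return Tsc(times=times, values=values, label=label, normalization="peak_csf")
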