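"""Advection-diffusion-source forward model on a voxel grid.

This is the constraint PDE of the transport inversion,

    drho/dt + div(rho v) = sigma * laplace(rho) + rho * r,

integrated by operator splitting per sub-step: conservative first-order
upwind advection, explicit diffusion, then a multiplicative source
update ``rho *= exp(r * dt)``. All three stages preserve positivity
under the stability limits enforced by :func:`required_substeps`, and
advection/diffusion conserve total mass exactly under the zero-flux
(reflecting) boundary, so the discrete mass budget

    mass_out - mass_in = sum(rho_pre_source * (exp(r*dt) - 1))

holds to round-off and is assertable.

Spatial unit is the voxel (h = 1); velocity is voxel/min, sigma is
voxel^2/min, r is 1/min, time is minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GroundTruth",
    "advect",
    "diffuse",
    "laplacian",
    "forward_transport",
    "required_substeps",
]


@dataclass
class GroundTruth:
    """Per-pair transport fields driving (or recovered from) a series.

    velocity: (n_pairs, 3, nx, ny, nz) voxel/min
    source:   (n_pairs, nx, ny, nz) 1/min
    sigma:    scalar diffusivity, voxel^2/min
    """

    velocity: np.ndarray
    source: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.source = np.asarray(self.source, dtype=float)
        if self.velocity.ndim == 4:  # single pair convenience
            self.velocity = self.velocity[None]
        if self.source.ndim == 3:
            self.source = self.source[None]
        if self.velocity.ndim != 5 or self.velocity.shape[1] != 3:
            raise ValueError(
                f"velocity must have shape (n_pairs, 3, nx, ny, nz); got {self.velocity.shape}"
            )
        if self.source.shape != (
            self.velocity.shape[0],
            *self.velocity.shape[2:],
        ):
            raise ValueError(
                f"source shape {self.source.shape} inconsistent with velocity {self.velocity.shape}"
            )
        if not (np.all(np.isfinite(self.velocity)) and np.all(np.isfinite(self.source))):
            raise ValueError("ground-truth fields contain non-finite values")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.velocity.shape[0]


def _axis_slices(ndim: int, axis: int) -> tuple[tuple[slice, ...], tuple[slice, ...]]:
    lo = [slice(None)] * ndim
    hi = [slice(None)] * ndim
    lo[axis] = slice(None, -1)
    hi[axis] = slice(1, None)
    return tuple(lo), tuple(hi)


def advect(rho: np.ndarray, velocity: np.ndarray, dt: float) -> np.ndarray:
    """One conservative upwind advection step with zero boundary flux.

    Face velocities are the mean of the two adjacent cell velocities;
    the flux takes the upwind cell value. Total mass is conserved
    exactly because every interior face flux appears once with each
    sign and boundary faces carry no flux.
    """
    out = rho - dt * advection_divergence(rho, velocity)
    return out


def advection_divergence(rho: np.ndarray, velocity: np.ndarray) -> np.ndarray:
    div = np.zeros_like(rho)
    for d in range(3):
        lo, hi = _axis_slices(3, d)
        u = 0.5 * (velocity[d][lo] + velocity[d][hi])  # interior faces
        flux = np.maximum(u, 0.0) * rho[lo] + np.minimum(u, 0.0) * rho[hi]
        div[lo] += flux
        div[hi] -= flux
    return div


def laplacian(rho: np.ndarray) -> np.ndarray:
    """Discrete Neumann (zero-flux) Laplacian; symmetric, h = 1."""
    out = np.zeros_like(rho)
    for d in range(3):
        lo, hi = _axis_slices(3, d)
        g = np.diff(rho, axis=d)  # gradient on interior faces
        out[lo] += g
        out[hi] -= g
    return out


def diffuse(rho: np.ndarray, sigma: float, dt: float) -> np.ndarray:
    if sigma == 0.0:
        return rho
    return rho + sigma * dt * laplacian(rho)


def required_substeps(
    velocity: np.ndarray, sigma: float, duration: float
) -> int:
    """Minimum sub-step count for positivity/stability over ``duration``.

    Advection: dt * sum_d max|v_d| <= 1 (upwind CFL, h = 1).
    Diffusion: sigma * dt <= 1/6 (explicit 3D limit, h = 1).
    """
    speed_sum = sum(float(np.max(np.abs(velocity[d]))) for d in range(3))
    n_adv = int(np.ceil(duration * speed_sum)) if speed_sum > 0 else 1
    n_dif = int(np.ceil(6.0 * sigma * duration)) if sigma > 0 else 1
    return max(1, n_adv, n_dif)


def transport_step(
    rho: np.ndarray, velocity: np.ndarray, source: np.ndarray, sigma: float, dt: float
) -> np.ndarray:
    """One split sub-step: advect, diffuse, apply source."""
    rho = advect(rho, velocity, dt)
    rho = diffuse(rho, sigma, dt)
    return rho * np.exp(source * dt)


def forward_transport(
    rho0: np.ndarray,
    gt: GroundTruth,
    duration: float,
    n_substeps: int,
    pair: int = 0,
) -> np.ndarray:
    """Evolve a density under one pair's transport fields.

    Parameters
    ----------
    rho0
        Non-negative 3D density at the start of the interval.
    gt
        Ground-truth fields; ``pair`` selects which pair's velocity and
        source to apply.
    duration
        Interval length in minutes.
    n_substeps
        Temporal subdivisions; must satisfy the stability limit or the
        call is refused with the required minimum.
    """
    rho0 = np.asarray(rho0, dtype=float)
    if rho0.ndim != 3:
        raise ValueError(f"rho0 must be 3D; got shape {rho0.shape}")
    if np.any(rho0 < 0):
        raise ValueError("rho0 must be non-negative")
    if not 0 <= pair < gt.n_pairs:
        raise IndexError(f"pair {pair} out of range for {gt.n_pairs} pairs")
    velocity = gt.velocity[pair]
    source = gt.source[pair]
    if velocity.shape[1:] != rho0.shape:
        raise ValueError(
            f"field grid {velocity.shape[1:]} does not match rho0 grid {rho0.shape}"
        )
    n_min = required_substeps(velocity, gt.sigma, duration)
    if n_substeps < n_min:
        raise ValueError(
            f"n_substeps={n_substeps} violates the stability limit; "
            f"need at least {n_min} sub-steps for this field and duration"
        )
    dt = duration / n_substeps
    rho = rho0.copy()
    for _ in range(n_substeps):
        rho = transport_step(rho, velocity, source, gt.sigma, dt)
    return rho
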