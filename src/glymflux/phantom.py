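"""Digital phantoms standing in for segmented rat-brain masks.

A phantom is a voxel grid with a tissue (parenchyma) mask, named ROI
masks (brainstem/cerebellum analogs), and a CSF inlet region through
which tracer enters, mimicking infusion at the cisterna magna.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phantom", "RoiSpec", "make_phantom", "default_roi_spec"]


@dataclass(frozen=True)
class RoiSpec:
    """A spherical region given in fractions of the grid extent.

    center and radius are fractions of ``min(shape)`` so one spec scales
    across grid sizes.
    """

    name: str
    center: tuple[float, float, float]
    radius: float


@dataclass
class Phantom:
    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    tissue_mask: np.ndarray
    roi_masks: dict[str, np.ndarray]
    csf_inlet_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.tissue_mask.shape != tuple(self.shape):
            raise ValueError("tissue_mask shape does not match phantom shape")
        if not self.tissue_mask.any():
            raise ValueError("tissue_mask is empty")
        if not self.csf_inlet_mask.any():
            raise ValueError("csf_inlet_mask is empty")
        for name, mask in self.roi_masks.items():
            if mask.shape != tuple(self.shape):
                raise ValueError(f"ROI {name!r} shape does not match phantom shape")
            if not mask.any():
                raise ValueError(f"ROI {name!r} is empty")
            if np.any(mask & ~self.tissue_mask):
                raise ValueError(f"ROI {name!r} is not a subset of tissue_mask")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))


def _sphere_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


# Geometry in fractions of min(shape): tissue sphere at the grid center,
# inlet near the lower pole (cisterna-magna side), ROIs between inlet
# and center the way brainstem and cerebellum sit near the skull base.
_TISSUE = RoiSpec("tissue", (0.5, 0.5, 0.5), 0.38)
_INLET = RoiSpec("csf_inlet", (0.5, 0.5, 0.22), 0.10)


def default_roi_spec() -> list[RoiSpec]:
    return [
        RoiSpec("brainstem", (0.5, 0.5, 0.375), 0.13),
        RoiSpec("cerebellum", (0.5, 0.5, 0.5), 0.17),
    ]


def make_phantom(
    shape: tuple[int, int, int] = (24, 24, 24),
    roi_spec: list[RoiSpec] | None = None,
    seed: int = 0,
    voxel_size: tuple[float, float, float] = (0.2, 0.2, 0.2),
) -> Phantom:
    """Build a deterministic spherical phantom with named ROI masks.

    Parameters
    ----------
    shape
        Grid dimensions, at least 8 per axis.
    roi_spec
        Spherical ROIs in fractional coordinates; ``None`` selects the
        default brainstem/cerebellum analogs. Every ROI must fit inside
        the grid and is clipped to the tissue mask.
    seed
        Kept for interface uniformity with the stochastic generators;
        the phantom itself is purely geometric.
    voxel_size
        mm per axis; the 0.2 mm default matches the DCE acquisition
        resolution the masks stand in for.
    """
    shape = tuple(int(n) for n in shape)
    if len(shape) != 3 or any(n < 8 for n in shape):
        raise ValueError(f"shape must be 3 axes of at least 8 voxels; got {shape}")
    if roi_spec is None:
        roi_spec = default_roi_spec()

    scale = min(shape)
    ext = np.asarray(shape, dtype=float)

    def resolve(spec: RoiSpec) -> tuple[np.ndarray, float]:
        center = np.asarray(spec.center) * (ext - 1)
        radius = spec.radius * scale
        if np.any(center - radius < -0.5) or np.any(center + radius > ext - 0.5):
            raise ValueError(f"region {spec.name!r} does not fit inside grid {shape}")
        return center, radius

    tc, tr = resolve(_TISSUE)
    tissue = _sphere_mask(shape, tc, tr)
    ic, ir = resolve(_INLET)
    inlet = _sphere_mask(shape, ic, ir)

    rois: dict[str, np.ndarray] = {}
    for spec in roi_spec:
        c, r = resolve(spec)
        mask = _sphere_mask(shape, c, r) & tissue
        if not mask.any():
            raise ValueError(f"region {spec.name!r} has no voxels inside the tissue mask")
        rois[spec.name] = mask

    return Phantom(
        shape=shape,
        voxel_size=tuple(float(v) for v in voxel_size),
        tissue_mask=tissue,
        roi_masks=rois,
        csf_inlet_mask=inlet,
    )
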