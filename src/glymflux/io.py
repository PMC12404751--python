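"""On-disk formats: NIfTI-1 images, CSV curves, JSON sidecars/manifests.

NIfTI stores no acquisition times, so a 4D series travels with a JSON
sidecar (``<name>.times.json``, field ``frame_times_min``). Masks are
3D uint8 volumes; flux maps are 3D float volumes with the interval in
a sidecar-free filename convention plus a JSON diagnostics log written
by the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import DceSeries, FluxMap, IcpRecording, Tsc

__all__ = [
    "write_series",
    "read_series",
    "write_mask",
    "read_mask",
    "write_flux_map",
    "read_flux_map",
    "write_tsc_csv",
    "read_tsc_csv",
    "write_icp_csv",
    "read_icp_csv",
    "file_sha256",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def _times_sidecar(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".times.json")
    return path.with_suffix(".times.json")


def write_series(series: DceSeries, path: str | Path, mask_path: str | Path | None = None) -> None:
    """Write a 4D series as NIfTI-1 plus its frame-times sidecar."""
    path = Path(path)
    data = np.moveaxis(series.frames, 0, -1)  # NIfTI wants time last
    img = nib.Nifti1Image(data.astype(np.float64), _affine(series.voxel_size))
    nib.save(img, path)
    sidecar = {"frame_times_min": [float(t) for t in series.frame_times]}
    _times_sidecar(path).write_text(json.dumps(sidecar, indent=1))
    if mask_path is not None:
        write_mask(series.tissue_mask, series.voxel_size, mask_path)


def read_series(
    path: str | Path,
    mask_path: str | Path | None = None,
    frame_times: np.ndarray | None = None,
) -> DceSeries:
    """Read a 4D NIfTI series; frame times come from the sidecar or argument."""
    path = Path(path)
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(
            f"{path} is {data.ndim}D; a 4D series (x, y, z, time) is expected"
        )
    if frame_times is None:
        sidecar = _times_sidecar(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"frame times not given and sidecar {sidecar} is missing; "
                "expected a JSON file with field 'frame_times_min'"
            )
        frame_times = np.asarray(
            json.loads(sidecar.read_text())["frame_times_min"], dtype=float
        )
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    frames = np.moveaxis(data, -1, 0)
    if mask_path is not None:
        mask = read_mask(mask_path)
        if mask.shape != frames.shape[1:]:
            raise ValueError(
                f"mask grid {mask.shape} does not match series grid {frames.shape[1:]}"
            )
    else:
        mask = np.ones(frames.shape[1:], dtype=bool)
    return DceSeries(
        frames=frames,
        frame_times=frame_times,
        voxel_size=voxel_size,
        tissue_mask=mask,
    )


def write_mask(mask: np.ndarray, voxel_size, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(voxel_size))
    nib.save(img, Path(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(Path(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is {data.ndim}D; a 3D mask is expected")
    return data.astype(bool)


def write_flux_map(flux: FluxMap, voxel_size, path: str | Path) -> None:
    img = nib.Nifti1Image(flux.values.astype(np.float64), _affine(voxel_size))
    img.header["descrip"] = (
        f"r-flux pair {flux.pair_index} {flux.interval[0]:g}-{flux.interval[1]:g} min".encode()
    )
    nib.save(img, Path(path))


def read_flux_map(
    path: str | Path, interval: tuple[float, float], pair_index: int
) -> FluxMap:
    img = nib.load(Path(path))
    return FluxMap(
        values=np.asarray(img.dataobj, dtype=float),
        interval=interval,
        pair_index=pair_index,
    )


def write_tsc_csv(curves: list[Tsc], path: str | Path) -> None:
    rows = []
    for tsc in curves:
        for t, v in zip(tsc.times, tsc.values):
            rows.append(
                {
                    "time_min": t,
                    "value": v,
                    "label": tsc.label,
                    "normalization": tsc.normalization,
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_tsc_csv(path: str | Path) -> list[Tsc]:
    df = pd.read_csv(Path(path))
    required = {"time_min", "value", "label", "normalization"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns: {sorted(missing)}")
    curves = []
    for label, sub in df.groupby("label", sort=False):
        sub = sub.sort_values("time_min")
        curves.append(
            Tsc(
                times=sub["time_min"].to_numpy(dtype=float),
                values=sub["value"].to_numpy(dtype=float),
                label=str(label),
                normalization=str(sub["normalization"].iloc[0]),
            )
        )
    return curves


def write_icp_csv(rec: IcpRecording, path: str | Path) -> None:
    pd.DataFrame({"time_s": rec.times, "mmHg": rec.samples}).to_csv(
        Path(path), index=False
    )


def read_icp_csv(path: str | Path) -> IcpRecording:
    df = pd.read_csv(Path(path))
    missing = {"time_s", "mmHg"} - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("ICP recording needs at least 2 samples")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("ICP samples must be uniformly spaced")
    return IcpRecording(samples=df["mmHg"].to_numpy(dtype=float), fs=1.0 / steps[0])


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
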