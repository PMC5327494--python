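"""Image-series I/O: NIfTI volumes with a plain-text timing sidecar.

Frame timing cannot live in a NIfTI header, so every series is written as
``<name>.nii.gz`` plus ``<name>_timing.csv`` with columns
``frame,time_ms,kind``.  Round trips preserve voxel data bit-exactly
(float64) and timing metadata exactly.
"""
from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ImageSeries


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + "_timing.csv")
    return path.with_name(path.stem + "_timing.csv")


def write_series(series: ImageSeries, path) -> Path:
    """Write volume + timing sidecar; returns the volume path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dy, dx = series.voxel_size
    affine = np.diag([dx, dy, series.slice_thickness, 1.0])
    img = nib.Nifti1Image(series.data.astype(np.float64), affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    pd.DataFrame(
        {
            "frame": np.arange(series.n_frames),
            "time_ms": series.times,
            "kind": series.kind,
        }
    ).to_csv(sidecar, index=False)
    return path


def read_series(path) -> ImageSeries:
    """Read volume + sidecar back into an :class:`ImageSeries`."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"timing sidecar not found: expected {sidecar} next to {path.name}"
        )
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[2] == 1:  # (nx, ny, 1, t) written by other tools
        data = data[:, :, 0, :]
    if data.ndim != 3:
        raise ValueError(f"expected a 3D frame stack, got shape {data.shape}")
    table = pd.read_csv(sidecar)
    for col in ("frame", "time_ms", "kind"):
        if col not in table.columns:
            raise ValueError(f"sidecar {sidecar} missing column {col!r}")
    if len(table) != data.shape[2]:
        raise ValueError(
            f"frame count mismatch: volume has {data.shape[2]} frames, "
            f"sidecar {sidecar.name} lists {len(table)}"
        )
    kinds = table["kind"].unique()
    if len(kinds) != 1:
        raise ValueError("sidecar mixes frame kinds")
    affine = img.affine
    voxel_size = (abs(float(affine[1, 1])), abs(float(affine[0, 0])))
    thickness = abs(float(affine[2, 2])) or 1.0
    return ImageSeries(
        data,
        table["time_ms"].to_numpy(dtype=float),
        str(kinds[0]),
        voxel_size=voxel_size,
        slice_thickness=thickness,
    )


def write_mask(mask: np.ndarray, path, voxel_size=(0.25, 0.25), slice_thickness=1.5) -> Path:
    """Write an integer-labelled (or boolean) mask volume."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(mask)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    dy, dx = voxel_size
    img = nib.Nifti1Image(arr.astype(np.int16), np.diag([dx, dy, slice_thickness, 1.0]))
    nib.save(img, str(path))
    return path


def read_mask(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj)
    return np.squeeze(arr)
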