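"""File formats: TSV time series, whitespace motion tables, NIfTI-1
volumes, JSON configs/results.

All writes are atomic (write to a temporary sibling, then rename), so a
failed run never leaves a partial output behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import InvalidConfigError, MotionTrace, TimeSeries

__all__ = [
    "atomic_write_text",
    "write_timeseries_tsv",
    "read_timeseries_tsv",
    "read_motion_table",
    "write_json",
    "read_json",
    "write_nifti",
    "read_nifti4d",
]


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_timeseries_tsv(path: str | os.PathLike, ts: TimeSeries) -> None:
    """Two-column TSV: time_s, value."""
    df = pd.DataFrame({"time_s": ts.times, "value": ts.values})
    atomic_write_text(path, df.to_csv(sep="\t", index=False, float_format="%.10g"))


def read_timeseries_tsv(path: str | os.PathLike) -> TimeSeries:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise InvalidConfigError(f"{path}: expected a two-column TSV with >= 2 rows")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dts = np.diff(t)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-12):
        raise InvalidConfigError(f"{path}: time column is not uniformly sampled")
    return TimeSeries(df.iloc[:, 1].to_numpy(dtype=float), dt=float(dts[0]), t0=float(t[0]))


def read_motion_table(path: str | os.PathLike) -> MotionTrace:
    """Six-column whitespace/TSV table: x, y, z (mm), pitch, roll, yaw (rad)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise InvalidConfigError(f"{path}: expected 6 motion-parameter columns")
    return MotionTrace(translations=arr[:, :3], rotations=arr[:, 3:])


def write_json(path: str | os.PathLike, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path: str | os.PathLike):
    with open(path) as fh:
        return json.load(fh)


def write_nifti(
    path: str | os.PathLike,
    data: np.ndarray,
    voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0),
    tr: float | None = None,
) -> None:
    """Write a 3-D/4-D array as NIfTI-1 with TR stored in the header.

    Voxel indices are 0-based; world coordinates follow the (diagonal)
    affine built from ``voxel_size``.
    """
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = list(voxel_size[:3])
    if data.ndim == 4:
        zooms.append(tr if tr is not None else 1.0)
    img.header.set_zooms(tuple(zooms))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(f".{path.name}.tmp.nii")
    nib.save(img, tmp)
    os.replace(tmp, path)


def read_nifti4d(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Return (data, TR seconds) from a 4-D NIfTI-1 file."""
    img = nib.load(path)
    data = np.asarray(img.get_fdata())
    if data.ndim != 4:
        raise InvalidConfigError(f"{path}: expected a 4-D volume")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 1.0
    if tr <= 0:
        raise InvalidConfigError(f"{path}: TR in header must be > 0")
    return data, tr
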