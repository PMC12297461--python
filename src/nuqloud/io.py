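"""Reading and writing point-cloud tables and volumetric images.

The canonical tabular dialect is comma-separated with a header row and
columns ``sample_id,nucleus_id,x_um,y_um,z_um[,channel_<name>...]``; extra
columns are carried through as per-nucleus labels.  Volumes are plain 3D
TIFF or HDF5 arrays (single channel), 1 µm isotropic voxels unless the file
declares otherwise.
"""
from __future__ import annotations

import logging
import os

import numpy as np
import pandas as pd

from .datatypes import COORD_COLUMNS, SampleCloud

logger = logging.getLogger(__name__)

_DIALECTS = {"csv": ",", "tsv": "\t"}


class FormatError(ValueError):
    """Input file does not follow the canonical table layout."""


def read_point_table(path, format_dialect: str = "csv") -> list:
    """Read a point-cloud table into one :class:`SampleCloud` per sample.

    Row order is preserved within each sample; missing intensity columns
    yield empty intensity maps.  Raises :class:`FormatError` for missing
    coordinate columns and ``ValueError`` for non-finite coordinates or
    duplicate ``(sample_id, nucleus_id)`` pairs.
    """
    if format_dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {format_dialect!r}")
    df = pd.read_csv(path, sep=_DIALECTS[format_dialect])
    missing = [c for c in ("sample_id", "nucleus_id") + tuple(COORD_COLUMNS)
               if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    coords = df[list(COORD_COLUMNS)]
    bad = ~np.isfinite(coords.to_numpy(dtype=float)).all(axis=1)
    if bad.any():
        rows = np.nonzero(bad)[0]
        raise ValueError(f"{path}: non-finite coordinates at data rows "
                         f"{rows.tolist()[:10]}")
    dup = df.duplicated(subset=["sample_id", "nucleus_id"])
    if dup.any():
        rows = np.nonzero(dup.to_numpy())[0]
        raise ValueError(f"{path}: duplicate (sample_id, nucleus_id) at data "
                         f"rows {rows.tolist()[:10]}")
    clouds = []
    for sid in df["sample_id"].unique():  # preserves first-appearance order
        clouds.append(SampleCloud.from_frame(df[df["sample_id"] == sid],
                                             sample_id=sid))
    logger.info("read %d samples / %d nuclei from %s",
                len(clouds), len(df), path)
    return clouds


def write_results(tables, path) -> None:
    """Write one or more row-aligned result tables as a single CSV.

    ``tables`` is a DataFrame or a list of DataFrames sharing the
    ``(sample_id, nucleus_id)`` key; multiple tables are joined on that key.
    Floats are written at full round-trip precision.
    """
    if isinstance(tables, pd.DataFrame):
        df = tables
    else:
        tables = list(tables)
        df = tables[0]
        for other in tables[1:]:
            df = df.merge(other, on=["sample_id", "nucleus_id"], how="left")
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
    logger.info("wrote %d rows x %d columns to %s", len(df), df.shape[1], path)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _looks_like_channel_axis(shape) -> bool:
    # a 2D RGB(A) image parades as 3D: one axis of length <= 4 while the
    # spatial axes are much longer
    return min(shape) <= 4 and max(shape) >= 16


def read_volume(path):
    """Read a 3D single-channel volume; returns ``(array, voxel_size_um)``.

    Supports TIFF and HDF5.  Voxel size defaults to 1 µm isotropic when the
    file carries no metadata (HDF5 datasets may declare a ``voxel_size_um``
    attribute).  Raises ``ValueError`` for non-3D data, including 2D
    multichannel (RGB) images.
    """
    ext = os.path.splitext(str(path))[1].lower()
    voxel = (1.0, 1.0, 1.0)
    if ext in (".h5", ".hdf5", ".hdf"):
        import h5py

        with h5py.File(path, "r") as fh:
            keys = list(fh.keys())
            if not keys:
                raise ValueError(f"{path}: empty HDF5 file")
            ds = fh[keys[0]]
            arr = np.asarray(ds)
            if "voxel_size_um" in ds.attrs:
                voxel = tuple(float(v) for v in ds.attrs["voxel_size_um"])
    else:
        import tifffile

        arr = tifffile.imread(path)
    if arr.ndim != 3 or _looks_like_channel_axis(arr.shape):
        raise ValueError(
            f"{path}: expected a 3D single-channel volume, got shape "
            f"{arr.shape}")
    return arr, voxel


def write_volume(path, array, voxel_size_um=(1.0, 1.0, 1.0)) -> None:
    """Write a 3D volume (TIFF or HDF5, chosen by extension)."""
    arr = np.asarray(array)
    if arr.ndim != 3:
        raise ValueError(f"expected 3D array, got shape {arr.shape}")
    ext = os.path.splitext(str(path))[1].lower()
    if ext in (".h5", ".hdf5", ".hdf"):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("volume", data=arr)
            ds.attrs["voxel_size_um"] = list(voxel_size_um)
    else:
        import tifffile

        tifffile.imwrite(path, arr)
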