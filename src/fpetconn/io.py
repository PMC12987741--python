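"""Readers and writers for the external formats the pipeline touches.

NIfTI-1 for 4D dynamic series, tissue probability maps and parcellation
volumes (via nibabel); whitespace-delimited text for T x 6 rigid-body motion
traces (the realignment-output dialect: three translations in mm, then three
rotations in radians); TSV for region tables and connectivity matrices.

NIfTI headers do not reliably carry per-frame timing, so the frame duration
is explicit: pass it as an argument or place a JSON sidecar next to the image
(``{"frame_duration": 1.0}`` with the same stem and ``.json`` extension).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .types import ConnectivityMatrix, DynamicSeries, MotionTrace, ParcelMap, \
    TissueProbabilityMap, make_connectivity

log = logging.getLogger(__name__)

__all__ = [
    "read_dynamic_series",
    "write_dynamic_series",
    "read_tissue_map",
    "write_tissue_map",
    "read_motion_trace",
    "write_motion_trace",
    "read_parcellation",
    "write_parcellation",
    "read_connectivity",
    "write_connectivity",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for ext in (".nii.gz", ".nii"):
        if name.endswith(ext):
            return path.with_name(name[: -len(ext)] + ".json")
    return path.with_suffix(".json")


def read_dynamic_series(path, frame_duration: Optional[float] = None) -> DynamicSeries:
    """Load a 4D NIfTI dynamic series.

    ``frame_duration`` (seconds) is taken from the argument if given,
    otherwise from a JSON sidecar next to the image.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dynamic series not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"expected 4D dynamic series, got {data.ndim}D image: {path}")
    if frame_duration is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            frame_duration = meta.get("frame_duration")
        if frame_duration is None:
            raise ValueError(
                f"frame_duration not supplied and no sidecar found for {path}; "
                "pass frame_duration explicitly or write a JSON sidecar"
            )
    frame_duration = float(frame_duration)
    if frame_duration <= 0:
        raise ValueError(f"frame_duration must be > 0, got {frame_duration}")
    zooms = img.header.get_zooms()[:3]
    return DynamicSeries(
        data=np.asarray(data, dtype=float),
        frame_duration=frame_duration,
        voxel_size=tuple(float(z) for z in zooms),
        affine=img.affine,
    )


def write_dynamic_series(series: DynamicSeries, path, sidecar: bool = True) -> None:
    """Write a DynamicSeries to 4D NIfTI (plus a frame-timing JSON sidecar)."""
    path = Path(path)
    img = nib.Nifti1Image(series.data, series.affine)
    img.header.set_zooms(tuple(series.voxel_size) + (series.frame_duration,))
    nib.save(img, str(path))
    if sidecar:
        with open(_sidecar_path(path), "w") as fh:
            json.dump({"frame_duration": series.frame_duration}, fh)


def read_tissue_map(path, tissue_class: str) -> TissueProbabilityMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"tissue map not found: {path}")
    img = nib.load(str(path))
    data = np.asarray(np.asanyarray(img.dataobj), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected 3D tissue map, got {data.ndim}D: {path}")
    return TissueProbabilityMap(
        prob=data,
        tissue_class=tissue_class,
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=img.affine,
    )


def write_tissue_map(tmap: TissueProbabilityMap, path) -> None:
    img = nib.Nifti1Image(tmap.prob, tmap.affine)
    img.header.set_zooms(tuple(tmap.voxel_size))
    nib.save(img, str(path))


def read_motion_trace(path, frame_duration: float = 1.0,
                      degrees: bool = False) -> MotionTrace:
    """Read a T x 6 whitespace-delimited motion parameter file.

    Column order: translation x, y, z (mm), then rotation x, y, z (radians by
    default; set ``degrees=True`` for tools that write degrees).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"motion trace not found: {path}")
    try:
        arr = np.loadtxt(str(path), ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in motion file {path}: {exc}") from exc
    if arr.shape[1] != 6:
        raise ValueError(
            f"motion file must have 6 columns, found {arr.shape[1]}: {path}"
        )
    if degrees:
        arr = arr.copy()
        arr[:, 3:] = np.deg2rad(arr[:, 3:])
    return MotionTrace(params=arr, frame_duration=frame_duration)


def write_motion_trace(motion: MotionTrace, path) -> None:
    np.savetxt(str(path), motion.params, fmt="%.17g")


def read_parcellation(label_path, table_path) -> ParcelMap:
    """Load an integer NIfTI label volume and its TSV region table."""
    label_path, table_path = Path(label_path), Path(table_path)
    if not label_path.exists():
        raise FileNotFoundError(f"parcellation volume not found: {label_path}")
    if not table_path.exists():
        raise FileNotFoundError(f"region table not found: {table_path}")
    img = nib.load(str(label_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D label volume, got {data.ndim}D")
    rounded = np.rint(data).astype(np.int64)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError("label volume contains non-integer values")
    table = pd.read_csv(table_path, sep="\t")
    return ParcelMap(
        labels=rounded,
        region_table=table,
        voxel_size=tuple(float(z) for z in img.header.get_zooms()[:3]),
        affine=img.affine,
    )


def write_parcellation(parcels: ParcelMap, label_path, table_path) -> None:
    img = nib.Nifti1Image(parcels.labels.astype(np.int32), parcels.affine)
    nib.save(img, str(label_path))
    parcels.region_table.to_csv(table_path, sep="\t", index=False)


def write_connectivity(matrix: ConnectivityMatrix, path) -> None:
    """Write a connectivity matrix as TSV with region ids as header row/column.

    The full matrix is stored (not just a triangle) for human readability;
    values round-trip to better than 1e-12.
    """
    if not isinstance(matrix, ConnectivityMatrix):
        # constructing the type enforces symmetry/diagonal invariants
        raise TypeError("write_connectivity expects a ConnectivityMatrix")
    df = pd.DataFrame(matrix.values,
                      index=matrix.region_ids, columns=matrix.region_ids)
    df.index.name = "region"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_connectivity(path, method: str = "pearson", band=None) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = np.asarray(df.columns)
    try:
        ids = ids.astype(int)
    except (TypeError, ValueError):
        pass
    return make_connectivity(df.to_numpy(dtype=float), ids, method=method, band=band)
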