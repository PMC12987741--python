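"""Shared domain types for dynamic PET connectivity analysis.

Every object validates its own invariants at construction time, so that
downstream code can assume well-formed inputs: a 4D dynamic series has at
least two finite frames on a regular time grid; tissue probability maps live
in [0, 1]; a connectivity matrix is symmetric with a unit diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FrequencyBand",
    "DynamicSeries",
    "TissueProbabilityMap",
    "MotionTrace",
    "ParcelMap",
    "RegionTimeSeries",
    "ConnectivityMatrix",
    "nyquist_frequency",
]

#: tolerance for the symmetry check of connectivity matrices
_SYMMETRY_TOL = 1e-12


def nyquist_frequency(frame_duration: float) -> float:
    """Highest representable frequency for a given frame duration.

    For frames of ``frame_duration`` seconds the sampling rate is
    ``fs = 1/frame_duration`` and the Nyquist frequency is ``fs/2``;
    e.g. 3 s frames give ~0.167 Hz, 1 s frames give 0.5 Hz.
    """
    if not np.isfinite(frame_duration) or frame_duration <= 0:
        raise ValueError(
            f"frame_duration must be positive and finite, got {frame_duration!r}"
        )
    return 1.0 / (2.0 * float(frame_duration))


@dataclass(frozen=True)
class FrequencyBand:
    """Closed frequency interval [low, high] in Hz with 0 <= low < high."""

    low: float
    high: float

    def __post_init__(self) -> None:
        low, high = float(self.low), float(self.high)
        if not (np.isfinite(low) and np.isfinite(high)):
            raise ValueError("band edges must be finite")
        if not 0.0 <= low < high:
            raise ValueError(f"require 0 <= low < high, got low={low}, high={high}")
        object.__setattr__(self, "low", low)
        object.__setattr__(self, "high", high)

    def validate_for(self, frame_duration: float) -> "FrequencyBand":
        """Check the band against the Nyquist frequency of a sampling grid."""
        fn = nyquist_frequency(frame_duration)
        if self.high > fn + 1e-12:
            raise ValueError(
                f"band upper edge {self.high} Hz exceeds Nyquist {fn:.6g} Hz "
                f"for frame duration {frame_duration} s"
            )
        return self

    def contains(self, f) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return (f >= self.low) & (f <= self.high)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.low:g}-{self.high:g} Hz"


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class DynamicSeries:
    """A 4D dynamic PET acquisition: (x, y, z, frame) activity values.

    Parameters
    ----------
    data:
        4D array, one volume per frame, arbitrary activity units.
    frame_duration:
        Frame length in seconds (the effective TR of the series).
    frame_onsets:
        Frame start times in seconds; defaults to ``i * frame_duration``.
        Must be strictly increasing with spacing equal to ``frame_duration``.
    voxel_size:
        mm per voxel along each spatial axis.
    affine:
        Opaque 4x4 orientation matrix, passed through unchanged by all filters.
    """

    data: np.ndarray
    frame_duration: float
    frame_onsets: Optional[np.ndarray] = None
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data (x, y, z, frame), got {self.data.ndim}D")
        if self.data.shape[3] < 2:
            raise ValueError("a dynamic series needs at least 2 frames")
        _check_finite("data", self.data)
        self.frame_duration = float(self.frame_duration)
        if self.frame_duration <= 0:
            raise ValueError(f"frame_duration must be > 0, got {self.frame_duration}")
        if self.frame_onsets is None:
            self.frame_onsets = np.arange(self.n_frames) * self.frame_duration
        self.frame_onsets = np.asarray(self.frame_onsets, dtype=float)
        if self.frame_onsets.shape != (self.n_frames,):
            raise ValueError("frame_onsets length must equal the number of frames")
        spacing = np.diff(self.frame_onsets)
        if not np.allclose(spacing, self.frame_duration, rtol=1e-9, atol=1e-9):
            raise ValueError("frame_onsets must increase in steps of frame_duration")
        self.voxel_size = tuple(float(z) for z in self.voxel_size)
        if len(self.voxel_size) != 3 or any(z <= 0 for z in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple:
        return self.data.shape[:3]

    def with_data(self, data: np.ndarray, **changes) -> "DynamicSeries":
        """Copy of this series with new voxel data (metadata preserved)."""
        return replace(self, data=data, **changes)


@dataclass
class TissueProbabilityMap:
    """3D tissue probability volume for one of GM, WM, CSF."""

    prob: np.ndarray
    tissue_class: str
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.ndim != 3:
            raise ValueError(f"tissue probability map must be 3D, got {self.prob.ndim}D")
        _check_finite("prob", self.prob)
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("tissue probabilities must lie in [0, 1]")
        if self.tissue_class not in ("GM", "WM", "CSF"):
            raise ValueError(f"tissue_class must be GM, WM or CSF, got {self.tissue_class!r}")
        self.voxel_size = tuple(float(z) for z in self.voxel_size)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    def check_grid(self, series: DynamicSeries) -> None:
        if self.prob.shape != series.spatial_shape:
            raise ValueError(
                f"tissue map grid {self.prob.shape} does not match "
                f"series grid {series.spatial_shape}"
            )


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters: T x 6 (3 translations mm, 3 rotations rad)."""

    params: np.ndarray
    frame_duration: float = 1.0

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion trace must be T x 6 "
                f"(got shape {self.params.shape})"
            )
        _check_finite("params", self.params)
        self.frame_duration = float(self.frame_duration)
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    def check_series(self, series: DynamicSeries) -> None:
        if self.n_frames != series.n_frames:
            raise ValueError(
                f"motion trace has {self.n_frames} rows but series has "
                f"{series.n_frames} frames"
            )


@dataclass
class ParcelMap:
    """Integer-labelled parcellation volume plus its region table.

    ``region_table`` has columns ``label`` (positive int), ``name`` and
    ``network``; every nonzero label in the volume appears exactly once.
    """

    labels: np.ndarray
    region_table: pd.DataFrame
    voxel_size: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("parcellation volume must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("parcellation labels must be integers")
            self.labels = as_int
        if self.labels.min() < 0:
            raise ValueError("parcellation labels must be non-negative (0 = background)")
        present = np.unique(self.labels)
        present = present[present > 0]
        if present.size == 0:
            raise ValueError("no parcels: the label volume contains only background")
        table = pd.DataFrame(self.region_table)
        required = {"label", "name", "network"}
        if not required.issubset(table.columns):
            raise ValueError(f"region table needs columns {sorted(required)}")
        table = table.copy()
        table["label"] = table["label"].astype(int)
        dup = table["label"][table["label"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate labels in region table: {sorted(set(dup))}")
        missing = sorted(set(present.tolist()) - set(table["label"].tolist()))
        if missing:
            raise ValueError(f"labels present in volume but missing from table: {missing}")
        self.region_table = table.reset_index(drop=True)
        self.voxel_size = tuple(float(z) for z in self.voxel_size)
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def present_labels(self) -> np.ndarray:
        """Labels that actually occur in the volume, ascending."""
        u = np.unique(self.labels)
        return u[u > 0]

    @property
    def n_regions(self) -> int:
        return len(self.present_labels)


@dataclass
class RegionTimeSeries:
    """Parcel-mean signals: R regions x T frames."""

    values: np.ndarray
    region_ids: np.ndarray
    frame_duration: float
    frame_onsets: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be R x T")
        r, t = self.values.shape
        if r < 2 or t < 2:
            raise ValueError(f"need at least 2 regions and 2 frames, got {r} x {t}")
        _check_finite("values", self.values)
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.shape != (r,):
            raise ValueError("region_ids length must equal the number of rows")
        self.frame_duration = float(self.frame_duration)
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        if self.frame_onsets is None:
            self.frame_onsets = np.arange(t) * self.frame_duration
        self.frame_onsets = np.asarray(self.frame_onsets, dtype=float)
        if self.frame_onsets.shape != (t,):
            raise ValueError("frame_onsets length must equal the number of frames")
        if np.any(np.diff(self.frame_onsets) <= 0):
            raise ValueError("frame_onsets must be strictly increasing")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray, **changes) -> "RegionTimeSeries":
        return replace(self, values=values, **changes)


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R correlation matrix with unit diagonal.

    ``method`` records the estimator ("pearson" or "partial"); ``band`` the
    frequency band the underlying signals were restricted to, if any.
    """

    values: np.ndarray
    region_ids: np.ndarray
    method: str = "pearson"
    band: Optional[FrequencyBand] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("connectivity matrix must be square")
        _check_finite("values", self.values)
        if np.max(np.abs(self.values - self.values.T)) > _SYMMETRY_TOL:
            raise ValueError("connectivity matrix must be symmetric (tolerance 1e-12)")
        if not np.array_equal(np.diag(self.values), np.ones(len(self.values))):
            raise ValueError("connectivity matrix diagonal must be exactly 1")
        off = self.values[~np.eye(len(self.values), dtype=bool)]
        if off.size and (off.min() < -1.0 or off.max() > 1.0):
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")
        self.region_ids = np.asarray(self.region_ids)
        if self.region_ids.shape != (len(self.values),):
            raise ValueError("region_ids length must match the matrix size")
        if self.method not in ("pearson", "partial"):
            raise ValueError(f"method must be 'pearson' or 'partial', got {self.method!r}")

    @property
    def n_regions(self) -> int:
        return len(self.values)

    def lower_triangle(self) -> np.ndarray:
        """Canonical vectorization: lower triangle excluding the diagonal."""
        i, j = np.tril_indices(self.n_regions, k=-1)
        return self.values[i, j]


def make_connectivity(
    values: np.ndarray,
    region_ids: Sequence,
    method: str = "pearson",
    band: Optional[FrequencyBand] = None,
) -> ConnectivityMatrix:
    """Build a valid ConnectivityMatrix from a raw near-correlation array.

    Symmetrizes, clips to [-1, 1] and resets the diagonal, absorbing the
    floating-point jitter every correlation estimator produces.
    """
    values = np.asarray(values, dtype=float)
    values = 0.5 * (values + values.T)
    values = np.clip(values, -1.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values=values, region_ids=np.asarray(region_ids),
                              method=method, band=band)
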