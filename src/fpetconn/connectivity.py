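"""Regional extraction and metabolic-connectivity estimation.

Connectivity between parcellated regions is the Pearson correlation of the
denoised regional time courses (the component-regression path) or the
partial correlation controlling for motion parameters (the band-pass path,
where motion is not otherwise removed). Matrices are compared over their
lower triangles, the canonical vectorization everywhere in this package.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.stats

from .types import ConnectivityMatrix, DynamicSeries, ParcelMap, RegionTimeSeries, \
    make_connectivity

log = logging.getLogger(__name__)

__all__ = [
    "extract_regional_timeseries",
    "pearson_connectivity",
    "partial_corr_connectivity",
    "top_edges",
    "compare_matrices",
    "group_mean_matrix",
]


def extract_regional_timeseries(series: DynamicSeries,
                                parcels: ParcelMap) -> RegionTimeSeries:
    """Mean time course per parcel label, one row per region.

    Regions listed in the table but absent from the volume are dropped with
    a warning.
    """
    if parcels.labels.shape != series.spatial_shape:
        raise ValueError(
            f"parcellation grid {parcels.labels.shape} does not match the "
            f"series grid {series.spatial_shape}"
        )
    flat_labels = parcels.labels.reshape(-1)
    present = parcels.present_labels
    table_labels = parcels.region_table["label"].to_numpy()
    missing = sorted(set(table_labels.tolist()) - set(present.tolist()))
    if missing:
        log.warning("regions with zero voxels dropped: %s", missing)
    data = series.data.reshape(-1, series.n_frames)
    max_label = int(flat_labels.max())
    counts = np.bincount(flat_labels, minlength=max_label + 1)
    sums = np.zeros((max_label + 1, series.n_frames))
    for f in range(series.n_frames):
        sums[:, f] = np.bincount(flat_labels, weights=data[:, f],
                                 minlength=max_label + 1)
    means = sums[present] / counts[present, None]
    return RegionTimeSeries(values=means, region_ids=present,
                            frame_duration=series.frame_duration,
                            frame_onsets=series.frame_onsets)


def _check_constant_rows(values: np.ndarray, region_ids) -> None:
    sd = values.std(axis=1, ddof=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = np.asarray(region_ids)[bad]
        raise ValueError(
            f"correlation undefined: constant time series in region(s) {names.tolist()}"
        )


def pearson_connectivity(regions: RegionTimeSeries,
                         band=None) -> ConnectivityMatrix:
    """Pearson correlation matrix of the regional time courses."""
    if regions.n_frames < 3:
        raise ValueError("need at least 3 frames to estimate correlations")
    _check_constant_rows(regions.values, regions.region_ids)
    corr = np.corrcoef(regions.values)
    return make_connectivity(corr, regions.region_ids, method="pearson", band=band)


def partial_corr_connectivity(
    regions: RegionTimeSeries,
    confounds: np.ndarray,
    band=None,
) -> ConnectivityMatrix:
    """Partial correlation of regions controlling for confound time courses.

    Entry (i, j) is the Pearson correlation of the residuals of rows i and j
    after least-squares regression on the confounds (an intercept is always
    added). With constant-only confounds this reduces exactly to the plain
    Pearson matrix.
    """
    if regions.n_frames < 3:
        raise ValueError("need at least 3 frames to estimate correlations")
    c = np.asarray(confounds, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != regions.n_frames:
        raise ValueError(
            f"confounds have {c.shape[0]} rows but the series has "
            f"{regions.n_frames} frames"
        )
    x = np.column_stack([np.ones(regions.n_frames), c])
    # drop exact duplicate columns, then insist on full column rank
    x = np.unique(x, axis=1)
    s = np.linalg.svd(x, compute_uv=False)
    if x.shape[1] > x.shape[0] or s[-1] / s[0] <= 1e-10:
        raise ValueError("confound matrix is rank-deficient after deduplication")
    y = regions.values.T
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ beta).T
    _check_constant_rows(resid, regions.region_ids)
    corr = np.corrcoef(resid)
    return make_connectivity(corr, regions.region_ids, method="partial", band=band)


def top_edges(matrix: ConnectivityMatrix, fraction: float = 0.05) -> pd.DataFrame:
    """Strongest ``fraction`` of connections (upper-triangle entries).

    Edges are ranked by value descending; ``ceil(fraction * R(R-1)/2)`` are
    kept, plus any edges tied with the cutoff value. Columns:
    region_i, region_j, value.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    r = matrix.n_regions
    iu, ju = np.triu_indices(r, k=1)
    values = matrix.values[iu, ju]
    n_edges = values.size
    k = int(np.ceil(fraction * n_edges))
    order = np.argsort(-values, kind="stable")
    cutoff = values[order[k - 1]]
    keep = order[values[order] >= cutoff]
    ids = np.asarray(matrix.region_ids)
    return pd.DataFrame({
        "region_i": ids[iu[keep]],
        "region_j": ids[ju[keep]],
        "value": values[keep],
    })


def compare_matrices(
    a: ConnectivityMatrix,
    b: ConnectivityMatrix,
    method: str = "spearman",
) -> Tuple[float, int]:
    """Correlation of two matrices over lower-triangle entries.

    Returns ``(correlation, n_pairs)`` with ``n_pairs = R(R-1)/2``.
    """
    if a.n_regions != b.n_regions or not np.array_equal(a.region_ids, b.region_ids):
        raise ValueError("matrices must share the same region set and order")
    va, vb = a.lower_triangle(), b.lower_triangle()
    if method == "spearman":
        rho = scipy.stats.spearmanr(va, vb).statistic
    elif method == "pearson":
        rho = scipy.stats.pearsonr(va, vb).statistic
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return float(rho), va.size


def group_mean_matrix(matrices: Sequence[ConnectivityMatrix],
                      fisher_z: bool = False) -> ConnectivityMatrix:
    """Element-wise mean connectivity across subjects (diagonal reset to 1).

    Averaging is on raw correlation values by default for comparability with
    reported connectivity magnitudes; ``fisher_z=True`` averages in
    z-space and transforms back.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty matrix list")
    ref = matrices[0]
    for m in matrices[1:]:
        if not np.array_equal(m.region_ids, ref.region_ids):
            raise ValueError("all matrices must share the same region set and order")
    stack = np.stack([m.values for m in matrices])
    if fisher_z:
        z = np.arctanh(np.clip(stack, -1 + 1e-15, 1 - 1e-15))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    return make_connectivity(mean, ref.region_ids, method=ref.method, band=ref.band)
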