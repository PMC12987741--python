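"""Construction of the unified nuisance design matrix.

One multiple-regression design combines, per subject and analysis window:

* principal components of standardized voxel time courses from the top
  fraction of the white-matter and CSF probability maps (component-based
  noise correction: these capture tracer delivery, the cumulative uptake
  trend, and physiological/scanner noise shared across non-neuronal tissue);
* a 24-parameter motion expansion (6 rigid-body parameters, their backward
  differences, and the squares of both), compressed by PCA;
* sine/cosine regressors at every Fourier-grid frequency *outside* a chosen
  pass-band, so that removing them in the same regression acts as a
  band-pass filter.

All columns are assembled with an intercept into a single full-rank design
that is regressed out of the data in one step (see ``filters``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import scipy.linalg

from .types import DynamicSeries, FrequencyBand, MotionTrace, TissueProbabilityMap

log = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "threshold_tissue_mask",
    "extract_tissue_components",
    "expand_motion_friston24",
    "motion_pca",
    "build_band_regressors",
    "assemble_design",
    "build_compcor_design",
]


@dataclass
class DesignMatrix:
    """T x K nuisance regressor block with per-column provenance labels."""

    values: np.ndarray
    column_labels: List[str]
    band: Optional[FrequencyBand] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("design must be a T x K matrix with K >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("design contains non-finite values")
        if len(self.column_labels) != self.values.shape[1]:
            raise ValueError("one label per column required")
        if sum(1 for lab in self.column_labels if lab == "intercept") != 1:
            raise ValueError("design must contain exactly one intercept column")
        s = scipy.linalg.svdvals(self.values)
        if s[-1] / s[0] <= 1e-10:
            raise ValueError("design is numerically rank-deficient")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def threshold_tissue_mask(tmap: TissueProbabilityMap, fraction: float = 0.05) -> np.ndarray:
    """Binary mask of the upper ``fraction`` of nonzero-probability voxels.

    Retains ``ceil(fraction * n_nonzero)`` voxels plus any voxels tied with
    the cutoff probability (inclusive ties keep the rule deterministic and
    independent of voxel ordering). Default fraction 0.05: the top 5 %.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    prob = tmap.prob
    nonzero = prob[prob > 0]
    if nonzero.size == 0:
        raise ValueError("all-zero probability map: nothing to threshold")
    k = int(np.ceil(fraction * nonzero.size))
    cutoff = np.sort(nonzero)[::-1][k - 1]
    return prob >= cutoff


def _svd_components(x: np.ndarray, variance_target: float, cap: int) -> Tuple[np.ndarray, np.ndarray]:
    """Left singular vectors of ``x`` (T x N) with a cumulative-variance cut.

    Returns (components T x C, explained variance ratios). The sign of each
    component is fixed so its largest-magnitude loading is positive.
    """
    u, s, vt = scipy.linalg.svd(x, full_matrices=False)
    var = s ** 2
    total = var.sum()
    if total == 0:
        raise ValueError("decomposition input has zero variance")
    ratios = var / total
    cum = np.cumsum(ratios)
    n_keep = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    n_keep = max(1, min(n_keep, cap, int((s > s[0] * 1e-12).sum())))
    u = u[:, :n_keep].copy()
    for c in range(n_keep):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            u[:, c] = -u[:, c]
    return u, ratios[:n_keep]


def extract_tissue_components(
    series: DynamicSeries,
    mask: np.ndarray,
    variance_target: float = 0.5,
    max_components: int = 6,
) -> np.ndarray:
    """Temporal principal components of standardized voxel signals in a mask.

    Each voxel time course is mean-centered and variance-normalized
    (correlation PCA) before the decomposition, so high-activity voxels do
    not dominate. The smallest number of components whose cumulative
    explained variance reaches ``variance_target`` is kept, capped at
    ``max_components``. Components are orthogonal, unit-norm and zero-mean.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError("mask shape does not match the series grid")
    if not mask.any():
        raise ValueError("empty tissue mask")
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames for component extraction")
    x = series.data[mask].T.astype(float)  # T x V
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all voxels inside the mask are constant in time")
    x = x[:, keep] / sd[keep]
    comps, _ = _svd_components(x, variance_target, max_components)
    return comps


def expand_motion_friston24(motion: MotionTrace) -> np.ndarray:
    """24-parameter motion expansion.

    Column blocks, in order: the 6 rigid-body parameters, their backward
    differences (first row zero), the squared parameters, and the squared
    differences.
    """
    p = motion.params
    if p.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute motion derivatives")
    d = np.zeros_like(p)
    d[1:] = np.diff(p, axis=0)
    return np.hstack([p, d, p ** 2, d ** 2])


def motion_pca(expanded: np.ndarray, variance_target: float = 0.99) -> np.ndarray:
    """PCA compression of the (standardized) 24-column motion expansion.

    Zero-variance columns are dropped before standardization; at least one
    component is always kept. Returns T x M orthogonal unit-norm columns.
    """
    x = np.asarray(expanded, dtype=float)
    if x.ndim != 2:
        raise ValueError("expanded motion block must be 2D")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all motion columns are constant")
    x = x[:, keep] / sd[keep]
    comps, _ = _svd_components(x, variance_target, cap=x.shape[1])
    return comps


def build_band_regressors(
    n_frames: int,
    frame_duration: float,
    band: FrequencyBand,
) -> np.ndarray:
    """Sine/cosine regressors at every Fourier-grid frequency outside ``band``.

    Grid frequencies are f_k = k / (T * dt) for k = 1 .. floor(T/2); a pair
    (cos, sin) is emitted for every f_k strictly below the band's low edge or
    strictly above its high edge. The identically-zero sine at the exact
    Nyquist frequency (even T) is dropped. Columns are mean-centered. An
    empty result (band covering the whole spectrum) is returned as a T x 0
    matrix and logged, not raised.
    """
    band.validate_for(frame_duration)
    t = np.arange(n_frames) * frame_duration
    total = n_frames * frame_duration
    cols = []
    for k in range(1, n_frames // 2 + 1):
        f = k / total
        if band.low < f < band.high or np.isclose(f, band.low) or np.isclose(f, band.high):
            continue
        cols.append(np.cos(2 * np.pi * f * t))
        if not (n_frames % 2 == 0 and k == n_frames // 2):
            cols.append(np.sin(2 * np.pi * f * t))
    if not cols:
        log.info("band %s leaves no out-of-band grid frequency; empty regressor block",
                 band)
        return np.empty((n_frames, 0))
    out = np.column_stack(cols)
    return out - out.mean(axis=0)


def _drop_dependent_columns(x: np.ndarray, labels: List[str],
                            tol: float = 1e-8) -> Tuple[np.ndarray, List[str]]:
    """Greedy left-to-right sweep keeping only linearly independent columns."""
    t = x.shape[0]
    q = np.empty((t, 0))
    kept_cols, kept_labels = [], []
    for j in range(x.shape[1]):
        c = x[:, j]
        r = c - q @ (q.T @ c)
        norm_c = np.linalg.norm(c)
        if norm_c == 0 or np.linalg.norm(r) < tol * max(norm_c, 1.0):
            log.warning("dropping linearly dependent design column %r", labels[j])
            continue
        q = np.column_stack([q, r / np.linalg.norm(r)])
        kept_cols.append(j)
        kept_labels.append(labels[j])
    return x[:, kept_cols], kept_labels


def assemble_design(
    wm_components: Optional[np.ndarray] = None,
    csf_components: Optional[np.ndarray] = None,
    motion_components: Optional[np.ndarray] = None,
    band_regressors: Optional[np.ndarray] = None,
    n_frames: Optional[int] = None,
    band: Optional[FrequencyBand] = None,
) -> DesignMatrix:
    """Stack all nuisance blocks behind an intercept into one design.

    Rank-deficient assemblies are repaired by dropping later duplicate
    columns (logged), preserving the provenance label of every survivor.
    """
    blocks: List[Tuple[str, np.ndarray]] = []
    for prefix, block in (("wm_pc", wm_components), ("csf_pc", csf_components),
                          ("motion_pc", motion_components)):
        if block is not None and np.asarray(block).shape[1] > 0:
            blocks.append((prefix, np.asarray(block, dtype=float)))
    if band_regressors is not None and np.asarray(band_regressors).shape[1] > 0:
        blocks.append(("freq", np.asarray(band_regressors, dtype=float)))

    if n_frames is None:
        if not blocks:
            raise ValueError("n_frames required when all blocks are empty")
        n_frames = blocks[0][1].shape[0]
    for prefix, block in blocks:
        if block.shape[0] != n_frames:
            raise ValueError(
                f"block {prefix!r} has {block.shape[0]} rows, expected {n_frames}"
            )

    columns = [np.ones((n_frames, 1))]
    labels = ["intercept"]
    for prefix, block in blocks:
        columns.append(block)
        if prefix == "freq":
            # alternating cos/sin labels over the out-of-band grid
            labels.extend(
                f"freq_{'cos' if i % 2 == 0 else 'sin'}_{i // 2}"
                for i in range(block.shape[1])
            )
        else:
            labels.extend(f"{prefix}_{i}" for i in range(block.shape[1]))
    x = np.hstack(columns)

    s = scipy.linalg.svdvals(x)
    if s[-1] / s[0] <= 1e-10:
        x, labels = _drop_dependent_columns(x, labels)
    return DesignMatrix(values=x, column_labels=labels, band=band)


def build_compcor_design(
    series: DynamicSeries,
    wm: TissueProbabilityMap,
    csf: TissueProbabilityMap,
    motion: Optional[MotionTrace] = None,
    band: Optional[FrequencyBand] = None,
    mask_fraction: float = 0.05,
    variance_target: float = 0.5,
    max_components: int = 6,
    motion_variance_target: float = 0.99,
) -> DesignMatrix:
    """Convenience wrapper: full unified design for one subject/window."""
    wm.check_grid(series)
    csf.check_grid(series)
    wm_pcs = extract_tissue_components(
        series, threshold_tissue_mask(wm, mask_fraction),
        variance_target, max_components)
    csf_pcs = extract_tissue_components(
        series, threshold_tissue_mask(csf, mask_fraction),
        variance_target, max_components)
    motion_pcs = None
    if motion is not None:
        motion.check_series(series)
        motion_pcs = motion_pca(expand_motion_friston24(motion),
                                motion_variance_target)
    band_block = None
    if band is not None:
        band_block = build_band_regressors(series.n_frames, series.frame_duration, band)
    return assemble_design(wm_pcs, csf_pcs, motion_pcs, band_block,
                           n_frames=series.n_frames, band=band)
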