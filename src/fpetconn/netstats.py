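"""Network-level statistics on connectivity matrices.

Hierarchical agglomeration (Ward linkage on Euclidean distances between
connectivity profiles), cophenetic evaluation of the resulting tree,
fixed-k cluster cuts, cluster-overlap contingency tables, and permutation
split-half reliability of connectivity estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .connectivity import group_mean_matrix, pearson_connectivity
from .types import ConnectivityMatrix, RegionTimeSeries

__all__ = [
    "LinkageTree",
    "ReliabilityResult",
    "ward_linkage",
    "cophenetic_coefficient",
    "cut_clusters",
    "cluster_overlap",
    "split_half_reliability",
]


@dataclass
class LinkageTree:
    """Agglomerative merge sequence over region connectivity profiles.

    ``merges`` is the standard (R-1) x 4 linkage encoding: left id, right id,
    merge height, merged cluster size. Leaves are indexed 0..R-1 in the order
    of ``region_ids``.
    """

    merges: np.ndarray
    region_ids: np.ndarray

    def __post_init__(self) -> None:
        self.merges = np.asarray(self.merges, dtype=float)
        self.region_ids = np.asarray(self.region_ids)
        r = len(self.region_ids)
        if self.merges.shape != (r - 1, 4):
            raise ValueError("linkage must have R-1 merges of 4 fields")
        heights = self.merges[:, 2]
        if np.any(np.diff(heights) < -1e-10):
            raise ValueError("merge heights must be non-decreasing")
        if int(self.merges[-1, 3]) != r:
            raise ValueError("final merged cluster must contain all regions")

    @property
    def n_leaves(self) -> int:
        return len(self.region_ids)


def ward_linkage(matrix: ConnectivityMatrix) -> LinkageTree:
    """Ward-linkage agglomeration of regions by their connectivity profiles.

    The feature vector of region r is row r of the matrix; the dissimilarity
    is the Euclidean distance between profiles. Ward's criterion merges the
    pair with the smallest increase in within-cluster variance, yielding a
    monotone merge-height sequence.
    """
    if matrix.n_regions < 2:
        raise ValueError("need at least 2 regions to cluster")
    z = sch.linkage(matrix.values, method="ward", metric="euclidean")
    return LinkageTree(merges=z, region_ids=matrix.region_ids)


def cophenetic_coefficient(tree: LinkageTree, matrix: ConnectivityMatrix) -> float:
    """Correlation between profile distances and cophenetic (merge) distances.

    A value of 1 means the tree reproduces the pairwise Euclidean distances
    exactly (the distances are ultrametric).
    """
    if matrix.n_regions < 3:
        raise ValueError("cophenetic correlation requires at least 3 regions")
    if tree.n_leaves != matrix.n_regions or not np.array_equal(
            tree.region_ids, matrix.region_ids):
        raise ValueError("tree and matrix must describe the same regions")
    dist = ssd.pdist(matrix.values, metric="euclidean")
    c, _ = sch.cophenet(tree.merges, dist)
    return float(c)


def cut_clusters(tree: LinkageTree, k: int = 8) -> np.ndarray:
    """Labels for exactly ``k`` clusters, obtained by undoing the last k-1 merges.

    The default of 8 follows the convention of seven canonical cortical
    networks plus one subcortical cluster. Labels are 1..k in order of first
    appearance.
    """
    r = tree.n_leaves
    if not 1 <= k <= r:
        raise ValueError(f"k must lie in [1, {r}], got {k}")
    labels = sch.cut_tree(tree.merges, n_clusters=k).ravel()
    return labels + 1


def cluster_overlap(labels_a: Sequence, labels_b: Sequence) -> pd.DataFrame:
    """Contingency table n(a, b) of regions shared by cluster a of A and b of B."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    return pd.crosstab(pd.Series(a, name="cluster_a"), pd.Series(b, name="cluster_b"))


@dataclass
class ReliabilityResult:
    """Distribution of split-half reliability correlations."""

    correlations: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    n_perm: int
    seed: Optional[int]

    def __post_init__(self) -> None:
        self.correlations = np.asarray(self.correlations, dtype=float)
        if self.n_perm < 1 or self.correlations.shape != (self.n_perm,):
            raise ValueError("need n_perm >= 1 recorded correlations")
        if not (-1 - 1e-12 <= self.ci_low <= self.ci_high <= 1 + 1e-12):
            raise ValueError("CI bounds must lie within [-1, 1]")


def _pearson_lower(a: ConnectivityMatrix, b: ConnectivityMatrix) -> float:
    va, vb = a.lower_triangle(), b.lower_triangle()
    va = va - va.mean()
    vb = vb - vb.mean()
    denom = np.sqrt((va @ va) * (vb @ vb))
    if denom == 0:
        # degenerate spread: identical constant vectors count as r = 1
        return 1.0 if np.allclose(a.lower_triangle(), b.lower_triangle()) else np.nan
    return float((va @ vb) / denom)


def split_half_reliability(
    subject_series: Sequence[RegionTimeSeries],
    estimator: Optional[Callable[[RegionTimeSeries], ConnectivityMatrix]] = None,
    n_perm: int = 5000,
    seed: Optional[int] = None,
    contiguous: bool = False,
) -> ReliabilityResult:
    """Permutation split-half reliability of group-mean connectivity.

    Per permutation, each subject's frames are randomly partitioned into two
    disjoint equal-size halves (odd T: the extra frame goes to half 1; with
    ``contiguous=True`` the halves are the first and second temporal
    blocks, identical across permutations). The estimator (default: Pearson
    connectivity) is run on each half, subject matrices are averaged per
    half, and the Pearson correlation of the two lower-triangle vectors is
    recorded. Returns the full distribution with its mean and 2.5/97.5
    percentile interval.
    """
    subjects = list(subject_series)
    if not subjects:
        raise ValueError("empty subject list")
    for s, sub in enumerate(subjects):
        if sub.n_frames < 6:
            raise ValueError(f"subject {s} has only {sub.n_frames} frames (need >= 6)")
        if sub.n_regions < 3:
            raise ValueError("reliability needs at least 3 regions")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    estimator = estimator or pearson_connectivity
    rng = np.random.default_rng(seed)
    rs = np.empty(n_perm)
    for p in range(n_perm):
        halves: List[List[ConnectivityMatrix]] = [[], []]
        for s, sub in enumerate(subjects):
            t = sub.n_frames
            n1 = (t + 1) // 2
            if contiguous:
                idx1, idx2 = np.arange(n1), np.arange(n1, t)
            else:
                perm = rng.permutation(t)
                idx1, idx2 = np.sort(perm[:n1]), np.sort(perm[n1:])
            for half, idx in ((0, idx1), (1, idx2)):
                sel = RegionTimeSeries(
                    values=sub.values[:, idx],
                    region_ids=sub.region_ids,
                    frame_duration=sub.frame_duration,
                    frame_onsets=sub.frame_onsets[idx],
                )
                try:
                    halves[half].append(estimator(sel))
                except Exception as exc:
                    raise RuntimeError(
                        f"estimator failed for subject {s}, permutation {p}: {exc}"
                    ) from exc
        mean1 = group_mean_matrix(halves[0])
        mean2 = group_mean_matrix(halves[1])
        rs[p] = _pearson_lower(mean1, mean2)
    lo, hi = np.percentile(rs, [2.5, 97.5])
    return ReliabilityResult(
        correlations=rs, mean=float(rs.mean()),
        ci_low=float(min(lo, 1.0)), ci_high=float(min(hi, 1.0)),
        n_perm=n_perm, seed=seed,
    )
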