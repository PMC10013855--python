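"""Ligand binding-pose clustering.

Pipeline: superpose the trajectory on the receptor (frame 0 reference),
compute the pairwise ligand RMSD matrix with no further fitting (poses are
compared in the receptor frame), build a Ward minimum-variance hierarchy on
that matrix, pick the cluster count at the elbow of within-cluster variance
vs k, and report populations plus a medoid representative per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core import ResidueGroup, Trajectory, superpose

__all__ = ["RMSDMatrix", "ClusterResult", "ligand_rmsd_matrix", "ward_cluster",
           "select_k_elbow", "summarize_clusters", "kmeans_cluster"]


@dataclass(frozen=True)
class RMSDMatrix:
    """Symmetric pairwise pose RMSD matrix (Angstrom), zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.values, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RMSD matrix must be square")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("RMSD matrix must be symmetric")
        if np.any(m < 0):
            raise ValueError("RMSD matrix must be non-negative")
        if not np.allclose(np.diag(m), 0, atol=1e-8):
            raise ValueError("RMSD matrix must have zero diagonal")
        object.__setattr__(self, "values", m)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ClusterResult:
    """Partition of frames into pose clusters.

    populations are percentages summing to 100; each cluster's medoid is the
    member frame with the lowest mean RMSD to the other members.
    """

    k: int
    labels: np.ndarray  # per-frame cluster id, 0..k-1
    populations: np.ndarray  # per-cluster %
    medoid_frame: np.ndarray  # per-cluster frame index

    def __post_init__(self) -> None:
        if not np.isclose(self.populations.sum(), 100.0, atol=1e-9):
            raise ValueError("populations must sum to 100%")
        for c, m in enumerate(self.medoid_frame):
            if self.labels[m] != c:
                raise ValueError("medoid must belong to its cluster")


def ligand_rmsd_matrix(trajectory: Trajectory, ligand: ResidueGroup,
                       fit_group: Optional[ResidueGroup] = None,
                       presuperposed: bool = False) -> RMSDMatrix:
    """All-pairs ligand RMSD after receptor superposition.

    When ``presuperposed`` is False the trajectory is first aligned to frame
    0 on ``fit_group`` (typically the receptor without its flexible
    intracellular loop 3). Entry (i, j) is then the plain coordinate RMSD of
    the ligand atoms between frames i and j, with no per-pair refitting.
    """
    if not presuperposed:
        if fit_group is None:
            raise ValueError("fit_group required unless trajectory is presuperposed")
        trajectory = superpose(trajectory, reference_frame=0, fit_group=fit_group)
    atoms = ligand.atom_indices(trajectory.topology)
    X = trajectory.coordinates[:, atoms]  # (n, L, 3)
    n = X.shape[0]
    flat = X.reshape(n, -1)
    # ||xi - xj||^2 summed over atoms, via the Gram trick
    sq = np.sum(flat**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * flat @ flat.T
    np.maximum(d2, 0.0, out=d2)
    m = np.sqrt(d2 / X.shape[1])
    np.fill_diagonal(m, 0.0)
    return RMSDMatrix(values=(m + m.T) / 2.0)


def _ward_linkage(matrix: RMSDMatrix) -> np.ndarray:
    return linkage(squareform(matrix.values, checks=False), method="ward")


def ward_cluster(matrix: RMSDMatrix, k: int) -> np.ndarray:
    """Ward minimum-variance hierarchical clustering cut at ``k`` clusters.

    Returns 0-based labels, numbered by first appearance in frame order.
    """
    if not 1 <= k <= matrix.n:
        raise ValueError(f"k={k} out of range [1, {matrix.n}]")
    if matrix.n == 1:
        return np.zeros(1, dtype=int)
    raw = fcluster(_ward_linkage(matrix), t=k, criterion="maxclust")
    return _renumber(raw)


def _renumber(raw: np.ndarray) -> np.ndarray:
    seen: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in seen:
            seen[r] = len(seen)
        out[i] = seen[r]
    return out


def _wss(matrix: np.ndarray, labels: np.ndarray) -> float:
    """Within-cluster sum of squares on a distance matrix.

    For points in Euclidean space, sum_c (1/(2 n_c)) sum_{i,j in c} d_ij^2
    equals the sum of squared distances to cluster centroids.
    """
    total = 0.0
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        sub = matrix[np.ix_(idx, idx)]
        total += float(np.sum(sub**2)) / (2.0 * len(idx))
    return total


def select_k_elbow(matrix: RMSDMatrix, k_max: int = 10) -> int:
    """Elbow selection of the cluster count.

    Computes within-cluster variance for Ward partitions at k = 1..k_max and
    returns the k with maximal perpendicular distance to the chord joining
    (1, WSS_1) and (k_max, WSS_kmax), after normalising both axes. Returns 1
    when the frames are (near-)identical.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    k_max = min(k_max, matrix.n)
    wss = np.array([_wss(matrix.values, ward_cluster(matrix, k))
                    for k in range(1, k_max + 1)])
    if wss[0] <= 1e-12:  # all frames essentially identical
        return 1
    ks = np.arange(1, k_max + 1, dtype=float)
    # normalise to [0,1] on both axes so the chord criterion is scale-free
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    y = (wss - wss[-1]) / (wss[0] - wss[-1]) if wss[0] > wss[-1] else np.zeros_like(wss)
    # distance from (x, y) to the line through (0, 1) and (1, 0)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    k = int(ks[np.argmax(dist)])
    # demand a demarcated elbow: a single diffuse blob has a smooth
    # power-law WSS decay (ratio near 1 at every step), not a kink
    if k > 1 and wss[k - 1] > 0.5 * wss[k - 2]:
        return 1
    return k


def summarize_clusters(matrix: RMSDMatrix, labels: np.ndarray) -> ClusterResult:
    """Populations (%) and medoid frames for a given partition."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (matrix.n,):
        raise ValueError("labels must assign every frame")
    uniq = np.unique(labels)
    if not np.array_equal(uniq, np.arange(len(uniq))):
        labels = _renumber(labels)
        uniq = np.unique(labels)
    pops = np.empty(len(uniq))
    medoids = np.empty(len(uniq), dtype=int)
    for c in uniq:
        idx = np.nonzero(labels == c)[0]
        if idx.size == 0:
            raise ValueError(f"cluster {c} is empty")
        pops[c] = 100.0 * idx.size / matrix.n
        sub = matrix.values[np.ix_(idx, idx)]
        # mean RMSD to the other members; ties broken by lowest frame index
        mean_r = sub.sum(axis=1) / max(idx.size - 1, 1)
        medoids[c] = idx[int(np.argmin(mean_r))]
    return ClusterResult(k=len(uniq), labels=labels, populations=pops,
                         medoid_frame=medoids)


def kmeans_cluster(trajectory: Trajectory, ligand: ResidueGroup, k: int,
                   fit_group: Optional[ResidueGroup] = None,
                   presuperposed: bool = False, seed: int = 0) -> np.ndarray:
    """K-means sensitivity check on flattened ligand coordinates."""
    from sklearn.cluster import KMeans

    if not presuperposed:
        if fit_group is None:
            raise ValueError("fit_group required unless trajectory is presuperposed")
        trajectory = superpose(trajectory, reference_frame=0, fit_group=fit_group)
    atoms = ligand.atom_indices(trajectory.topology)
    flat = trajectory.coordinates[:, atoms].reshape(trajectory.n_frames, -1)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(flat)
    return _renumber(km.labels_)
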