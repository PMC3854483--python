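"""Optimal-superposition RMSD and single-linkage conformational clustering.

Frames whose pairwise best-fit RMSD falls (strictly) below the cutoff —
2 angstrom by default, over the entire peptide — are linked; clusters are
the connected components of that graph (single linkage). Up to three
representative structures are returned: the medoid (frame minimizing the
summed intra-cluster RMSD, ties to the lowest frame index) of each of the
three largest clusters. In the full pipeline clustering is run separately
within each pi-stacking arrangement category.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Union

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import AtomSet, EmptyInputError, ShapeError

__all__ = ["ClusterResult", "kabsch_rotation", "kabsch_rmsd",
           "rmsd_matrix", "single_linkage_cluster"]


def _coords(x: Union[AtomSet, np.ndarray]) -> np.ndarray:
    if isinstance(x, AtomSet):
        return x.coords
    return np.asarray(x, dtype=float).reshape(-1, 3)


def kabsch_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix R minimizing ||a - b R^T|| (i.e. rotating the
    already-centered b onto a), reflections excluded."""
    h = b.T @ a  # correlation matrix sum_i outer(b_i, a_i)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def kabsch_rmsd(a: Union[AtomSet, np.ndarray],
                b: Union[AtomSet, np.ndarray]) -> float:
    """Minimal RMSD between two equal-size structures over all rigid
    superpositions (rotation + translation, no reflection)."""
    xa, xb = _coords(a), _coords(b)
    if xa.shape != xb.shape:
        raise ShapeError(f"atom counts differ: {xa.shape[0]} vs {xb.shape[0]}")
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)
    r = kabsch_rotation(xa, xb)
    diff = xa - xb @ r.T
    return float(np.sqrt((diff ** 2).sum() / len(xa)))


def rmsd_matrix(frames: Sequence[Union[AtomSet, np.ndarray]]) -> np.ndarray:
    """Symmetric matrix of pairwise best-fit RMSDs."""
    xs = [_coords(f) for f in frames]
    n = len(xs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_rmsd(xs[i], xs[j])
    return m


@dataclass(frozen=True)
class ClusterResult:
    """Clusters ordered by decreasing size; up to three medoid frames."""

    clusters: "list[list[int]]"
    representatives: "list[int]"

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, dtype=int)
        for k, members in enumerate(self.clusters):
            lab[members] = k
        return lab


def single_linkage_cluster(frames: Sequence[Union[AtomSet, np.ndarray]],
                           cutoff: float = 2.0) -> ClusterResult:
    """Single-linkage clustering of frames at an RMSD cutoff (strict <).

    Returns clusters sorted by decreasing size (ties: lowest contained
    frame index first) and the medoids of the up-to-3 largest clusters.
    """
    if len(frames) == 0:
        raise EmptyInputError("clustering requires at least one frame")
    dm = rmsd_matrix(frames)
    n = len(dm)
    adj = csr_matrix((dm < cutoff) & ~np.eye(n, dtype=bool))
    _, labels = connected_components(adj, directed=False)
    groups: "dict[int, list[int]]" = {}
    for i, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(i)
    clusters = sorted(groups.values(), key=lambda g: (-len(g), min(g)))

    reps: List[int] = []
    for members in clusters[:3]:
        sub = dm[np.ix_(members, members)]
        reps.append(members[int(np.argmin(sub.sum(axis=1)))])
    return ClusterResult(clusters=clusters, representatives=reps)
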