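"""Ligand conformer clustering with an NMRclust-style penalty cut.

Poses are first superposed on a conformationally homogeneous central moiety,
so the pairwise RMSD matrix reflects genuine internal rearrangements of the
terminal groups rather than rigid-body drift.  Clustering follows the
Kelley-Gardner-Sutcliffe recipe: average-linkage agglomeration, then at each
cut level a penalty equal to the normalized average intra-cluster spread
(rescaled onto [1, N−1] across levels) plus the number of clusters; the
partition minimizing the penalty is returned.  The penalty is invariant
under uniform scaling of the distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import apply_transform, kabsch_superpose

__all__ = ["pose_rmsd_matrix", "nmrclust", "cluster_report", "ClusterResult"]


def pose_rmsd_matrix(poses: np.ndarray, central_moiety) -> np.ndarray:
    """All-pair ligand RMSD after aligning each pose on the central moiety.

    ``poses`` has shape (P, n_atoms, 3); ``central_moiety`` indexes the
    atoms used for superposition (≥ 3).  Every pose is fit onto the first
    pose's moiety, then plain all-atom RMSDs are computed between every pair
    (no further fitting), so motions that leave the moiety fixed score zero.
    """
    poses = np.asarray(poses, dtype=float)
    if poses.ndim != 3 or poses.shape[0] < 2:
        raise ValueError("need at least 2 poses of shape (P, n_atoms, 3)")
    moiety = np.asarray(
        central_moiety.indices if hasattr(central_moiety, "indices") else central_moiety,
        dtype=int,
    )
    if len(moiety) < 3:
        raise ValueError("central moiety must contain at least 3 atoms")
    ref = poses[0][moiety]
    fitted = np.empty_like(poses)
    for i, pose in enumerate(poses):
        rot, tr, _ = kabsch_superpose(pose[moiety], ref)
        fitted[i] = apply_transform(pose, rot, tr)
    p = poses.shape[0]
    dist = np.zeros((p, p))
    for i in range(p):
        d = np.sqrt(((fitted[i + 1:] - fitted[i]) ** 2).sum(axis=2).mean(axis=1))
        dist[i, i + 1:] = d
        dist[i + 1:, i] = d
    return dist


@dataclass
class ClusterResult:
    """A conformer partition chosen by the penalty cut."""

    assignment: np.ndarray        # cluster id per conformer, 0-based contiguous
    representatives: np.ndarray   # one conformer index per cluster (medoid)
    penalty_trace: pd.DataFrame   # per cut level: n_clusters, spread, penalty
    populations: np.ndarray       # fraction of conformers per cluster

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def _partition_spread(dist: np.ndarray, labels: np.ndarray) -> float:
    """Average over multi-member clusters of mean intra-cluster distance."""
    spreads = []
    for lab in np.unique(labels):
        members = np.where(labels == lab)[0]
        if len(members) > 1:
            sub = dist[np.ix_(members, members)]
            spreads.append(sub[np.triu_indices(len(members), k=1)].mean())
    return float(np.mean(spreads)) if spreads else 0.0


def _medoid(dist: np.ndarray, members: np.ndarray) -> int:
    if len(members) == 1:
        return int(members[0])
    sub = dist[np.ix_(members, members)]
    return int(members[int(np.argmin(sub.mean(axis=1)))])


def nmrclust(dist: np.ndarray) -> ClusterResult:
    """Average-linkage clustering with the penalty-minimizing cut level.

    ``dist`` is a symmetric, non-negative, zero-diagonal matrix.  Penalty at
    a level with spread s and c clusters: norm(s) + c, where norm rescales
    the spreads observed across levels onto [1, N−1] (all-equal spreads map
    to 1).  Ties go to the first (fewest-merges) level.  With fewer than two
    items a trivial single cluster is returned with a warning.
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if n < 2:
        warnings.warn("fewer than 2 conformers: trivial single cluster", stacklevel=2)
        return ClusterResult(
            assignment=np.zeros(max(n, 1), dtype=int),
            representatives=np.array([0]),
            penalty_trace=pd.DataFrame(
                {"n_clusters": [1], "spread": [0.0], "penalty": [1.0]}
            ),
            populations=np.array([1.0]),
        )
    if not np.allclose(dist, dist.T, atol=1e-9) or np.any(dist < 0):
        raise ValueError("distance matrix must be symmetric and non-negative")
    z = linkage(squareform(dist, checks=False), method="average")
    # level k = after k merges -> n-k clusters, for k = 1 .. n-1
    labels_per_level = []
    spreads = np.empty(n - 1)
    for k in range(1, n):
        labels = fcluster(z, t=n - k, criterion="maxclust")
        labels_per_level.append(labels)
        spreads[k - 1] = _partition_spread(dist, labels)
    lo, hi = spreads.min(), spreads.max()
    if hi - lo < 1e-15:
        norm = np.ones(n - 1)
    else:
        norm = 1.0 + (spreads - lo) * (n - 2) / (hi - lo)
    n_clusters = n - np.arange(1, n)
    penalty = norm + n_clusters
    best = int(np.argmin(penalty))
    labels = labels_per_level[best]
    # relabel 0-based, ordered by first occurrence
    uniq, assignment = np.unique(labels, return_inverse=True)
    order = {}
    remap = np.empty(len(uniq), dtype=int)
    next_id = 0
    for lab in assignment:
        if lab not in order:
            order[lab] = next_id
            next_id += 1
    for old, new in order.items():
        remap[old] = new
    assignment = remap[assignment]
    n_c = assignment.max() + 1
    reps = np.array(
        [_medoid(dist, np.where(assignment == c)[0]) for c in range(n_c)]
    )
    pops = np.array([(assignment == c).mean() for c in range(n_c)])
    trace = pd.DataFrame(
        {"n_clusters": n_clusters, "spread": spreads, "penalty": penalty}
    )
    return ClusterResult(
        assignment=assignment, representatives=reps, penalty_trace=trace,
        populations=pops,
    )


def cluster_report(result: ClusterResult, top_k: int = 4) -> pd.DataFrame:
    """Clusters ranked by population with the cumulative share of the top k.

    ``top_k`` larger than the number of clusters is clamped with a warning.
    The table's ``cumulative`` column is the running population fraction in
    rank order; row ``rank == top_k`` therefore reports the share of the top
    k clusters.
    """
    k = top_k
    if k > result.n_clusters:
        warnings.warn(
            f"top_k={top_k} exceeds {result.n_clusters} clusters; clamping",
            stacklevel=2,
        )
        k = result.n_clusters
    order = np.argsort(-result.populations, kind="stable")
    table = pd.DataFrame(
        {
            "rank": np.arange(1, len(order) + 1),
            "cluster": order,
            "population": result.populations[order],
            "representative": result.representatives[order],
        }
    )
    table["cumulative"] = table["population"].cumsum()
    table.attrs["top_k"] = k
    table.attrs["top_k_share"] = float(table["cumulative"].iloc[k - 1])
    return table
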