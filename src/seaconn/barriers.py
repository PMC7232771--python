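"""Dispersal-barrier detection by connectivity clustering.

Habitat nodes are partitioned into clusters with high internal connectivity
separated by barriers whose *mean crossing probability* falls below a
tunable threshold θ.  The algorithm is a deterministic greedy agglomeration:
starting from singletons, repeatedly merge the cluster pair with the largest
mean inter-cluster crossing probability while that maximum exceeds θ.
Raising θ declares weaker links to be barriers and therefore yields more
(or equally many) clusters.

The input must be symmetrized first (mean mode by default upstream); the
mean crossing probability between clusters A and B is the mean of the
symmetrized matrix over the A×B block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

DEFAULT_THETA_GRID = (0.001, 0.002, 0.003)


@dataclass
class ClusterAssignment:
    """Partition of nodes into connectivity clusters at threshold θ.

    ``labels`` maps each node (by position) to a cluster id in 0..K-1;
    cluster ids are ordered by each cluster's smallest node index, so the
    labeling is stable under re-runs.
    """

    labels: np.ndarray
    node_ids: list
    theta: float
    n_clusters: int
    meta: dict = field(default_factory=dict)

    def members(self, cluster: int) -> list:
        return [self.node_ids[i] for i in np.flatnonzero(self.labels == cluster)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node_id": self.node_ids, "cluster_id": self.labels})


def _as_symmetric_array(M: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    arr = M.values if isinstance(M, ConnectivityMatrix) else np.asarray(M, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("matrix must be square")
    if not np.allclose(arr, arr.T, rtol=0, atol=1e-12):
        raise ValueError("matrix must be symmetrized before clustering "
                         "(apply connectivity.symmetrize first)")
    return arr


def cluster_connectivity(M: ConnectivityMatrix | np.ndarray, theta: float) -> ClusterAssignment:
    """Greedy agglomerative barrier clustering at crossing threshold θ.

    Merging continues while the largest mean inter-cluster crossing
    probability exceeds θ; ties are broken by the smallest (minimum node
    index of the first cluster, then of the second).  Every remaining
    inter-cluster mean is therefore ≤ θ on return.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    arr = _as_symmetric_array(M)
    n = arr.shape[0]
    node_ids = list(M.node_ids) if isinstance(M, ConnectivityMatrix) else list(range(n))

    # Clusters are indexed by the minimum node index of their members.
    # cross[a, b] = sum of arr over the a×b block; sizes[a] = |cluster a|.
    cross = arr.copy()
    sizes = np.ones(n)
    alive = np.ones(n, dtype=bool)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}

    while alive.sum() > 1:
        mean = cross / np.outer(sizes, sizes)
        mean[~alive, :] = -np.inf
        mean[:, ~alive] = -np.inf
        np.fill_diagonal(mean, -np.inf)
        iu = np.triu_indices(n, k=1)
        flat = mean[iu]
        k = int(np.argmax(flat))  # row-major order = smallest (a, b) on ties
        best = flat[k]
        if not (best > theta):
            break
        a, b = int(iu[0][k]), int(iu[1][k])
        # merge b into a (a < b, keeping the smaller index as cluster key)
        cross[a, :] += cross[b, :]
        cross[:, a] += cross[:, b]
        sizes[a] += sizes[b]
        alive[b] = False
        members[a].extend(members[b])
        del members[b]

    # stable labeling: order clusters by smallest member node index
    labels = np.empty(n, dtype=int)
    for k, key in enumerate(sorted(members)):
        labels[members[key]] = k
    assert len(members) == alive.sum()
    return ClusterAssignment(
        labels=labels,
        node_ids=node_ids,
        theta=float(theta),
        n_clusters=len(members),
        meta={"algorithm": "greedy agglomeration on mean crossing probability"},
    )


def barrier_strengths(
    M: ConnectivityMatrix | np.ndarray, assignment: ClusterAssignment
) -> pd.DataFrame:
    """Mean crossing probability for every unordered cluster pair.

    Returns a DataFrame (cluster_a, cluster_b, mean_crossing); for a
    partition returned by :func:`cluster_connectivity` all values are ≤ θ.
    """
    arr = _as_symmetric_array(M)
    labels = assignment.labels
    if len(labels) != arr.shape[0]:
        raise ValueError("assignment does not match matrix size")
    rows = []
    for a in range(assignment.n_clusters):
        ia = np.flatnonzero(labels == a)
        for b in range(a + 1, assignment.n_clusters):
            ib = np.flatnonzero(labels == b)
            rows.append({
                "cluster_a": a,
                "cluster_b": b,
                "mean_crossing": float(arr[np.ix_(ia, ib)].mean()),
            })
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "mean_crossing"])


def cluster_sweep(
    M: ConnectivityMatrix | np.ndarray,
    thetas: tuple[float, ...] = DEFAULT_THETA_GRID,
) -> dict[float, ClusterAssignment]:
    """Cluster at each θ of a grid (default the 0.001/0.002/0.003 sweep)."""
    return {float(t): cluster_connectivity(M, t) for t in thetas}
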