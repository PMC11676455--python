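"""Spatial clustering of docked poses for one drug-target pair.

Two methods, both cut at a 4 Å default:

* **COM-based** — single-linkage agglomerative clustering on pairwise
  ligand center-of-mass distances, tree cut at the cutoff.  With single
  linkage this equals the connected components of the "COMs within cutoff"
  graph, matching the plain "within 4 Å" reading of the cutoff.
* **Adjacency-based** — connected components of the graph with an edge
  wherever two poses' minimum heavy-atom-to-heavy-atom distance is within
  the cutoff.  Elongated poses whose COMs are far apart can still touch, so
  the two partitions genuinely differ.

Cluster ids are canonical: numbered 1..k in order of each cluster's smallest
member pose_index, so partitions are invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist, pdist

from .features import center_of_mass
from .io import Pose

__all__ = ["ClusterLabeling", "com_cluster", "adjacency_cluster", "cluster_oracle",
           "min_heavy_atom_distance"]

Linkage = Literal["single", "complete", "average"]


@dataclass
class ClusterLabeling:
    """A partition of one drug's poses: ``labels`` maps pose_index to cluster
    id, ``sizes`` maps cluster id to member count."""

    method: str
    cutoff: float
    labels: dict[int, int]
    sizes: dict[int, int]

    def __post_init__(self) -> None:
        counted: dict[int, int] = {}
        for cid in self.labels.values():
            counted[cid] = counted.get(cid, 0) + 1
        if counted != self.sizes:
            raise ValueError("cluster sizes inconsistent with labels")

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _canonicalize(pose_indices: Sequence[int], raw: np.ndarray, method: str, cutoff: float) -> ClusterLabeling:
    """Renumber raw cluster assignments to canonical ids ordered by smallest
    member pose_index."""
    first_member: dict[int, int] = {}
    for pidx, cid in zip(pose_indices, raw):
        cid = int(cid)
        if cid not in first_member or pidx < first_member[cid]:
            first_member[cid] = pidx
    order = sorted(first_member, key=first_member.get)
    remap = {old: new for new, old in enumerate(order, start=1)}
    labels = {pidx: remap[int(cid)] for pidx, cid in zip(pose_indices, raw)}
    sizes: dict[int, int] = {}
    for cid in labels.values():
        sizes[cid] = sizes.get(cid, 0) + 1
    return ClusterLabeling(method=method, cutoff=cutoff, labels=labels, sizes=sizes)


def _check_same_pair(poses: Sequence[Pose]) -> None:
    if not poses:
        raise ValueError("cannot cluster an empty pose list")
    pair = {(p.drug_id, p.target_id) for p in poses}
    if len(pair) > 1:
        raise ValueError(f"poses span multiple drug-target pairs: {sorted(pair)}")


def com_cluster(poses: Sequence[Pose], cutoff: float = 4.0,
                linkage_method: Linkage = "single") -> ClusterLabeling:
    """Cluster poses by ligand center-of-mass distance.

    Single linkage (default) cut at ``cutoff`` Å; complete/average linkage are
    available for sensitivity checks but change the meaning of the cutoff.
    """
    _check_same_pair(poses)
    idx = [p.pose_index for p in poses]
    if len(poses) == 1:
        return _canonicalize(idx, np.array([1]), f"com/{linkage_method}", cutoff)
    coms = np.array([center_of_mass(p.atoms) for p in poses])
    d = pdist(coms)
    if np.all(d == 0):  # identical COMs: scipy linkage is happy, but be explicit
        raw = np.ones(len(poses), dtype=int)
    else:
        raw = fcluster(linkage(d, method=linkage_method), t=cutoff, criterion="distance")
    return _canonicalize(idx, raw, f"com/{linkage_method}", cutoff)


def min_heavy_atom_distance(a: Pose, b: Pose) -> float:
    """Minimum distance (Å) between the heavy atoms of two poses."""
    ca = np.array([at.coords for at in a.heavy_atoms() or a.atoms])
    cb = np.array([at.coords for at in b.heavy_atoms() or b.atoms])
    return float(cdist(ca, cb).min())


def adjacency_cluster(poses: Sequence[Pose], cutoff: float = 4.0) -> ClusterLabeling:
    """Cluster poses as connected components of the contact graph: an edge
    joins two poses whose closest heavy atoms are within ``cutoff`` Å."""
    _check_same_pair(poses)
    n = len(poses)
    idx = [p.pose_index for p in poses]
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if min_heavy_atom_distance(poses[i], poses[j]) <= cutoff:
                adj[i, j] = adj[j, i] = True
    _, comp = connected_components(csr_matrix(adj), directed=False)
    return _canonicalize(idx, comp, "adjacency", cutoff)


def cluster_oracle(
    poses: Sequence[Pose],
    cutoff: float,
    predicate: Callable[[Pose, Pose, float], bool],
) -> ClusterLabeling:
    """Brute-force reference clustering: transitive closure of a pairwise
    predicate.  Test oracle only; refuses more than 50 poses."""
    _check_same_pair(poses)
    n = len(poses)
    if n > 50:
        raise ValueError(f"cluster_oracle is a test oracle; refusing n={n} > 50")
    # union-find by repeated sweeps (O(n^3) worst case; fine at n <= 50)
    comp = list(range(n))

    def find(i: int) -> int:
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if predicate(poses[i], poses[j], cutoff):
                ri, rj = find(i), find(j)
                if ri != rj:
                    comp[max(ri, rj)] = min(ri, rj)
    raw = np.array([find(i) for i in range(n)])
    return _canonicalize([p.pose_index for p in poses], raw, "oracle", cutoff)


def com_predicate(a: Pose, b: Pose, cutoff: float) -> bool:
    """Pairwise predicate matching :func:`com_cluster` with single linkage."""
    return float(np.linalg.norm(center_of_mass(a.atoms) - center_of_mass(b.atoms))) <= cutoff


def adjacency_predicate(a: Pose, b: Pose, cutoff: float) -> bool:
    """Pairwise predicate matching :func:`adjacency_cluster`."""
    return min_heavy_atom_distance(a, b) <= cutoff
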