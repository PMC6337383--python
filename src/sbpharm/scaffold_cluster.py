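"""Common-binding-mode elucidation from docked pose ensembles.

Scaffold RMSD matrix -> agglomerative complete-linkage clustering at a fixed
height -> partition into common-scaffold clusters (clusters covering poses of
at least ``min_distinct`` different ligands) and residual clusters -> medoid
representative selection.

No superposition is performed before the RMSD: poses share the receptor frame,
so scaffold RMSD measures binding-mode difference directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .chem_core import LigandPose

DEFAULT_HEIGHT = 2.0  # Angstrom clustering height
DEFAULT_MIN_DISTINCT = 4  # ligands required for a common scaffold cluster


def scaffold_rmsd(pose_a: LigandPose, pose_b: LigandPose) -> float:
    """RMSD over corresponding scaffold heavy atoms, no superposition.

    If either pose carries scaffold automorphisms, the minimum RMSD over all
    supplied equivalent atom orderings is returned.
    """
    if len(pose_a.scaffold_map) != len(pose_b.scaffold_map):
        raise ValueError(
            f"scaffold length mismatch: {pose_a.pose_id} has {len(pose_a.scaffold_map)}, "
            f"{pose_b.pose_id} has {len(pose_b.scaffold_map)}"
        )
    if not pose_a.scaffold_map:
        raise ValueError("empty scaffold map")
    a = pose_a.scaffold_coords()
    orders_b = [pose_b.scaffold_map] + list(pose_b.automorphisms)
    best = np.inf
    for order in orders_b:
        b = pose_b.scaffold_coords(order)
        rmsd = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
        best = min(best, rmsd)
    return best


def rmsd_matrix(poses: Sequence[LigandPose]) -> np.ndarray:
    """Symmetric scaffold RMSD matrix over a pose ensemble."""
    n = len(poses)
    if any(p.automorphisms for p in poses):
        dmat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                dmat[i, j] = dmat[j, i] = scaffold_rmsd(poses[i], poses[j])
        return dmat
    coords = np.stack([p.scaffold_coords() for p in poses])  # (n, k, 3)
    dmat = np.zeros((n, n))
    for i in range(n):
        diff = coords[i + 1 :] - coords[i]  # (n-i-1, k, 3)
        d = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
        dmat[i, i + 1 :] = d
        dmat[i + 1 :, i] = d
    return dmat


@dataclass
class PoseClustering:
    """Result of cutting a complete-linkage dendrogram at a fixed height.

    ``clusters`` holds member-index lists ordered by size descending (ties by
    lowest member index); ``merge_heights`` records the applied merges.
    """

    clusters: list[list[int]]
    merge_heights: list[float]
    height_cutoff: float
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if self.labels.size == 0:
            n = sum(len(c) for c in self.clusters)
            self.labels = np.empty(n, dtype=int)
            for cid, members in enumerate(self.clusters):
                self.labels[members] = cid


def _agglomerate(dmat: np.ndarray, linkage: str) -> list[tuple[float, int, int, list[int]]]:
    """Full agglomeration schedule with deterministic tie-breaking.

    Clusters carry stable integer ids (leaves 0..n-1, merged clusters get the
    next free ids); a merge tie is resolved in favour of the lowest (i, j) id
    pair.  Returns (height, id_i, id_j, merged member list) per merge.
    """
    n = dmat.shape[0]
    if np.isnan(dmat).any():
        raise ValueError("distance matrix contains NaN")
    if not np.allclose(dmat, dmat.T):
        raise ValueError("distance matrix must be symmetric")
    members: list[list[int]] = [[i] for i in range(n)]
    ids = list(range(n))
    sizes = np.ones(n)
    M = dmat.astype(float).copy()
    np.fill_diagonal(M, np.inf)
    merges = []
    next_id = n
    while M.shape[0] > 1:
        flat = np.argmin(M)
        i, j = np.unravel_index(flat, M.shape)  # row-major argmin => lowest (i, j)
        if i > j:
            i, j = j, i
        h = M[i, j]
        merged = sorted(members[i] + members[j])
        merges.append((float(h), ids[i], ids[j], merged))
        # Lance-Williams update of row i, then drop row j
        row_i, row_j = M[i], M[j]
        if linkage == "complete":
            new_row = np.maximum(row_i, row_j)
        elif linkage == "average":
            new_row = (sizes[i] * row_i + sizes[j] * row_j) / (sizes[i] + sizes[j])
        else:
            raise ValueError(f"unknown linkage {linkage!r}")
        M[i, :] = new_row
        M[:, i] = new_row
        M[i, i] = np.inf
        keep = np.arange(M.shape[0]) != j
        M = M[np.ix_(keep, keep)]
        members[i] = merged
        sizes[i] = sizes[i] + sizes[j]
        ids[i] = next_id
        next_id += 1
        del members[j]
        ids = [cid for k, cid in enumerate(ids) if k != j]
        sizes = sizes[keep]
    return merges


def _order_clusters(clusters: list[list[int]]) -> list[list[int]]:
    return sorted((sorted(c) for c in clusters), key=lambda c: (-len(c), c[0]))


def agglomerative_cut(dmat: np.ndarray, height: float, linkage: str) -> tuple[list[list[int]], list[float]]:
    """Apply all merges with height strictly below the cutoff.

    Complete and average linkage are monotone, so applying the merge schedule
    until the first merge at >= height equals cutting the dendrogram there.
    Merges at exactly the cutoff are not applied.
    """
    n = dmat.shape[0]
    merges = _agglomerate(dmat, linkage)
    clusters = {i: [i] for i in range(n)}
    heights = []
    next_id = n
    for h, ida, idb, merged in merges:
        if h >= height:
            break
        del clusters[ida]
        del clusters[idb]
        clusters[next_id] = merged
        heights.append(h)
        next_id += 1
    return _order_clusters(list(clusters.values())), heights


def complete_linkage(dmat: np.ndarray, height: float = DEFAULT_HEIGHT) -> PoseClustering:
    """Complete-linkage clustering of a symmetric RMSD matrix cut at ``height``."""
    clusters, heights = agglomerative_cut(np.asarray(dmat, dtype=float), height, "complete")
    return PoseClustering(clusters=clusters, merge_heights=heights, height_cutoff=height)


def partition_csc(
    clustering: PoseClustering,
    ligand_of: Callable[[int], str] | Sequence[str] | dict,
    min_distinct: int = DEFAULT_MIN_DISTINCT,
) -> tuple[list[list[int]], list[list[int]]]:
    """Split clusters into common-scaffold clusters and residual clusters.

    A cluster is a CSC iff it contains poses of at least ``min_distinct``
    distinct ligands.  Together the two lists contain every pose exactly once.
    """
    if callable(ligand_of):
        lookup = ligand_of
    else:
        lookup = lambda i: ligand_of[i]  # noqa: E731
    csc, residual = [], []
    for cluster in clustering.clusters:
        ligands = {lookup(i) for i in cluster}
        (csc if len(ligands) >= min_distinct else residual).append(cluster)
    return csc, residual


def representative_pose(cluster: Sequence[int], dmat: np.ndarray) -> int:
    """Medoid: member with minimal mean distance to the rest (ties -> lowest index)."""
    members = sorted(cluster)
    if not members:
        raise ValueError("empty cluster")
    if len(members) == 1:
        return members[0]
    sub = np.asarray(dmat)[np.ix_(members, members)]
    mean_d = sub.sum(axis=1) / (len(members) - 1)
    return members[int(np.argmin(mean_d))]


def cluster_poses(
    poses: Sequence[LigandPose],
    height: float = DEFAULT_HEIGHT,
    min_distinct: int = DEFAULT_MIN_DISTINCT,
) -> pd.DataFrame:
    """End-to-end convenience: RMSD matrix -> clustering -> CSC flags -> medoids.

    Returns a table with columns pose_id, ligand_id, cluster_id, is_csc,
    is_medoid (cluster ids ordered by population).
    """
    dmat = rmsd_matrix(poses)
    clustering = complete_linkage(dmat, height)
    csc, _ = partition_csc(clustering, [p.ligand_id for p in poses], min_distinct)
    csc_ids = {id(c) for c in csc}
    rows = []
    for cid, members in enumerate(clustering.clusters):
        medoid = representative_pose(members, dmat)
        for i in members:
            rows.append(
                {
                    "pose_id": poses[i].pose_id,
                    "ligand_id": poses[i].ligand_id,
                    "cluster_id": cid,
                    "is_csc": id(members) in csc_ids,
                    "is_medoid": i == medoid,
                }
            )
    return pd.DataFrame(rows)
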