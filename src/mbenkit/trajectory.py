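"""Lineage inference and pseudotime over malignant cells.

Cluster centroids in PC space are joined by a minimum spanning tree rooted
at the proliferating cluster; each root-to-leaf path is a lineage.  Cells
are projected orthogonally onto the piecewise-linear path of their nearest
lineage, and pseudotime is the arc length from the root to the projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class LineageSet:
    """Ordered cluster paths sharing one root, in a common PC space."""

    root: str
    lineages: list[list[str]]
    centroids: pd.DataFrame          # clusters x PC coordinates
    params: dict = field(default_factory=dict)


def lineage_graph(cluster_centroids: pd.DataFrame, root_cluster: str) -> LineageSet:
    """Minimum spanning tree over centroid distances; lineages = root-to-leaf paths.

    Ties between equal-length edges are broken by lexicographic cluster id
    (centroids are processed in sorted-id order).
    """
    ids = sorted(cluster_centroids.index)
    if len(ids) < 2:
        raise ValueError("need at least 2 clusters")
    if root_cluster not in ids:
        raise ValueError(f"root cluster {root_cluster!r} not present")
    C = cluster_centroids.loc[ids].to_numpy(dtype=float)
    D = np.sqrt(((C[:, None, :] - C[None, :, :]) ** 2).sum(-1))
    mst = sparse.csgraph.minimum_spanning_tree(D)
    mst = mst + mst.T

    adj = {i: set() for i in range(len(ids))}
    for i, j in zip(*mst.nonzero()):
        adj[i].add(j)
        adj[j].add(i)

    root = ids.index(root_cluster)
    leaves = [i for i in range(len(ids)) if len(adj[i]) == 1 and i != root]

    def _path(to: int) -> list[int]:
        # DFS from root; the tree guarantees a unique path
        stack = [(root, [root])]
        while stack:
            node, path = stack.pop()
            if node == to:
                return path
            for nxt in sorted(adj[node]):
                if nxt not in path:
                    stack.append((nxt, path + [nxt]))
        raise RuntimeError("disconnected spanning tree")

    lineages = [[ids[i] for i in _path(leaf)] for leaf in sorted(leaves)]
    return LineageSet(
        root=root_cluster,
        lineages=lineages,
        centroids=cluster_centroids.loc[ids],
        params={"n_clusters": len(ids)},
    )


def _project_onto_path(points: np.ndarray, path: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal projection of points onto a piecewise-linear path.

    Returns (arc_length, distance) per point; projections are clamped to the
    segments so arc length lies in [0, total path length].
    """
    seg_start = path[:-1]
    seg_vec = path[1:] - path[:-1]
    seg_len = np.sqrt((seg_vec**2).sum(axis=1))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])

    best_t = np.full(len(points), np.inf)
    best_d = np.full(len(points), np.inf)
    for s in range(len(seg_vec)):
        v = seg_vec[s]
        L2 = seg_len[s] ** 2
        if L2 == 0:
            proj = np.zeros(len(points))
        else:
            proj = np.clip(((points - seg_start[s]) @ v) / L2, 0.0, 1.0)
        foot = seg_start[s] + proj[:, None] * v
        d = np.sqrt(((points - foot) ** 2).sum(axis=1))
        better = d < best_d - 1e-12
        best_d[better] = d[better]
        best_t[better] = cum[s] + proj[better] * seg_len[s]
    return best_t, best_d


def pseudotime(
    cells_in_pc_space: pd.DataFrame, lineages: LineageSet
) -> pd.DataFrame:
    """Per-cell lineage assignment and arc-length pseudotime.

    Each cell joins the lineage whose piecewise-linear centroid path it is
    closest to (ties go to the lower-index lineage); its pseudotime is the
    arc length from the root to its orthogonal projection on that path.
    """
    pcs = cells_in_pc_space.to_numpy(dtype=float)
    n = len(pcs)
    assign = np.zeros(n, dtype=int)
    t = np.full(n, np.nan)
    dist = np.full(n, np.inf)
    for li, lineage in enumerate(lineages.lineages):
        path = lineages.centroids.loc[lineage].to_numpy(dtype=float)
        lt, ld = _project_onto_path(pcs, path)
        better = ld < dist - 1e-12  # strict: ties keep the lower lineage index
        assign[better] = li
        t[better] = lt[better]
        dist[better] = ld[better]
    return pd.DataFrame(
        {"lineage": assign, "pseudotime": t, "distance": dist},
        index=cells_in_pc_space.index,
    )


def select_root(cluster_scores: pd.Series) -> str:
    """Default root: the cluster with the highest mean proliferation score."""
    return str(cluster_scores.idxmax())
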