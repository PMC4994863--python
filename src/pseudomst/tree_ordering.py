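"""Cluster-level MST and cell-level ordering.

A minimum spanning tree over the cluster centers (Euclidean edge lengths)
gives the backbone.  The *main path* is the leaf-to-leaf path with the most
clusters (ties: most member cells, then a canonical lexicographic rule); all
other origin-to-leaf paths are branch paths.  Cells are projected onto the
tree edge nearest their cluster's position in the path and ordered by the
scalar projection; the pseudotime of the k-th ordered cell is the integer k.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cell_clustering import CellClusterModel
from .io import ExpressionMatrix
from .preprocess import ReducedMatrix


@dataclass
class ClusterTree:
    """Spanning tree over cluster centers with Euclidean edge lengths."""

    nodes: dict[int, np.ndarray]  # cluster id -> center (K,)
    cell_counts: dict[int, int]
    edges: list[tuple[int, int, float]]  # (a, b, length), a < b
    total_length: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g

    def leaves(self) -> list[int]:
        g = self.graph()
        return sorted(n for n in g.nodes if g.degree(n) == 1)


def build_mst(model: CellClusterModel) -> ClusterTree:
    """Minimum spanning tree over cluster centers.

    Prim's algorithm started from the lowest cluster id; equal-length frontier
    edges are broken by the smallest ``(min id, max id)`` pair, so the tree is
    deterministic even with duplicate centers.
    """
    ids = list(range(1, model.n_clusters + 1))
    if len(ids) < 2:
        raise ValueError(
            "single cluster: no tree to build — use the single-cluster fallback "
            "(order cells along PC 1)"
        )
    centers = {c: np.asarray(model.centers[c - 1], dtype=float) for c in ids}
    counts = {c: int(n) for c, n in zip(ids, model.cells_per_cluster)}
    in_tree = {ids[0]}
    edges: list[tuple[int, int, float]] = []
    while len(in_tree) < len(ids):
        best: tuple[float, int, int] | None = None
        for u in sorted(in_tree):
            for v in ids:
                if v in in_tree:
                    continue
                d = float(np.linalg.norm(centers[u] - centers[v]))
                cand = (d, min(u, v), max(u, v))
                if best is None or cand < best:
                    best = cand
        assert best is not None
        d, a, b = best
        edges.append((a, b, d))
        in_tree.add(a if a not in in_tree else b)
    edges.sort(key=lambda e: (e[1], e[2]))
    return ClusterTree(
        nodes=centers,
        cell_counts=counts,
        edges=edges,
        total_length=float(sum(e[2] for e in edges)),
    )


def _canonical(path: list[int]) -> list[int]:
    """Orient a path so its id sequence is the lexicographically smaller one."""
    return path if path <= path[::-1] else path[::-1]


def find_main_path(tree: ClusterTree) -> list[int]:
    """Leaf-to-leaf path with the most clusters; ties by most cells, then
    lexicographically smallest canonical id sequence."""
    g = tree.graph()
    leaves = tree.leaves()
    best_key = None
    best_path: list[int] | None = None
    for i, a in enumerate(leaves):
        for b in leaves[i + 1 :]:
            path = nx.shortest_path(g, a, b)
            cells = sum(tree.cell_counts[c] for c in path)
            cand = _canonical(list(path))
            key = (-len(path), -cells, cand)
            if best_key is None or key < best_key:
                best_key = key
                best_path = cand
    assert best_path is not None
    return best_path


def enumerate_paths(tree: ClusterTree, origin: int) -> list[list[int]]:
    """All simple paths from the origin cluster to every leaf."""
    if origin not in tree.nodes:
        raise ValueError(f"unknown origin cluster: {origin}")
    g = tree.graph()
    paths = []
    for leaf in tree.leaves():
        if leaf == origin:
            continue
        paths.append(list(nx.shortest_path(g, origin, leaf)))
    if not paths:  # origin is the sole node of a 1-edge tree's leaf set? n>=2 always
        paths = [[origin]]
    return paths


def validate_manual_path(tree: ClusterTree, path: list[int]) -> list[int]:
    """Accept a user-specified cluster sequence if it is a path in the tree."""
    g = tree.graph()
    if len(path) < 2 or len(set(path)) != len(path):
        raise ValueError("manual path must list >= 2 distinct clusters")
    for a, b in zip(path, path[1:]):
        if not g.has_edge(a, b):
            raise ValueError(f"({a}, {b}) is not an edge of the tree")
    return list(path)


def orient_path(
    path: list[int],
    marker_means: dict[int, float],
    direction: str = "increasing",
) -> list[int]:
    """Orient a cluster path so a marker gene trends the requested way.

    The slope of a least-squares line through the per-cluster marker means
    (in path order) decides; an exactly zero slope keeps the input orientation
    with a warning.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"direction must be increasing/decreasing, got {direction!r}")
    means = np.asarray([marker_means[c] for c in path], dtype=float)
    x = np.arange(len(path), dtype=float)
    slope = float(np.polyfit(x, means, 1)[0]) if len(path) > 1 else 0.0
    if abs(slope) <= 1e-12 * max(1.0, float(np.abs(means).max())):
        warnings.warn("marker trend is flat along the path; orientation unchanged")
        return list(path)
    want_up = direction == "increasing"
    return list(path) if (slope > 0) == want_up else list(path)[::-1]


def marker_means_per_cluster(
    m: ExpressionMatrix, model: CellClusterModel, gene: str
) -> dict[int, float]:
    """Mean expression of one gene within each cell cluster."""
    row = m.values[m.gene_index(gene)]
    return {
        c: float(row[model.labels == c].mean())
        for c in range(1, model.n_clusters + 1)
    }


@dataclass
class OrderedPath:
    """Cell-level ordering along one cluster path.

    ``pseudotime[k]`` is the integer rank (1-based) of ``cell_order[k]`` —
    always exactly the permutation 1..N of positions.
    """

    cluster_sequence: list[int]
    cell_order: list[str]
    pseudotime: np.ndarray
    edge_assignment: list[tuple[int, int] | None] = field(default_factory=list)
    projection_value: np.ndarray | None = None
    is_main: bool = False

    @property
    def n_cells(self) -> int:
        return len(self.cell_order)


def order_cells_along_path(
    path: list[int],
    model: CellClusterModel,
    r: ReducedMatrix,
    is_main: bool = False,
) -> OrderedPath:
    """Project the path clusters' cells onto tree edges and rank them.

    Edge assignment: first-cluster cells go to the first edge, last-cluster
    cells to the last edge, and an interior cluster's cells to the edge toward
    whichever neighboring center is nearer (ties: the earlier edge).  The
    projection of cell k on edge (C_i, C_j) is ``v_ij . E_k / ||v_ij||`` with
    ``v_ij = center_j - center_i``.  The global order is by (cluster position,
    edge index, projection value, stable input index).
    """
    if len(path) < 2:
        raise ValueError("path must contain at least 2 clusters")
    coords = np.asarray(r.coords, dtype=float)
    centers = {c: np.asarray(model.centers[c - 1], dtype=float) for c in path}
    pos = {c: i for i, c in enumerate(path)}
    m_len = len(path)
    records = []  # (cluster_pos, edge_idx, projection, input_idx)
    for idx in range(coords.shape[0]):
        c = int(model.labels[idx])
        if c not in pos:
            continue
        p = pos[c]
        if p == 0:
            edge_idx = 0
        elif p == m_len - 1:
            edge_idx = m_len - 2
        else:
            d_prev = float(np.linalg.norm(coords[idx] - centers[path[p - 1]]))
            d_next = float(np.linalg.norm(coords[idx] - centers[path[p + 1]]))
            edge_idx = p - 1 if d_prev <= d_next else p
        a, b = path[edge_idx], path[edge_idx + 1]
        v = centers[b] - centers[a]
        nv = float(np.linalg.norm(v))
        proj = float(v @ coords[idx]) / nv if nv > 0 else 0.0
        records.append((p, edge_idx, proj, idx, (a, b)))
    if not records:
        raise ValueError("no cells in the path's clusters (clustering bug upstream)")
    counts = {c: 0 for c in path}
    for rec in records:
        counts[path[rec[0]]] += 1
    if any(v == 0 for v in counts.values()):
        empty = [c for c, v in counts.items() if v == 0]
        raise ValueError(f"empty cluster(s) on path: {empty} (clustering bug upstream)")
    records.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    cell_order = [r.cell_ids[t[3]] for t in records]
    return OrderedPath(
        cluster_sequence=list(path),
        cell_order=cell_order,
        pseudotime=np.arange(1, len(records) + 1),
        edge_assignment=[t[4] for t in records],
        projection_value=np.asarray([t[2] for t in records]),
        is_main=is_main,
    )


def order_cells_by_pc1(r: ReducedMatrix) -> OrderedPath:
    """Single-cluster fallback: rank all cells by their first PC coordinate."""
    warnings.warn(
        "single cluster: ordering all cells by PC 1 instead of a tree path"
    )
    order = np.argsort(r.coords[:, 0], kind="stable")
    return OrderedPath(
        cluster_sequence=[1],
        cell_order=[r.cell_ids[i] for i in order],
        pseudotime=np.arange(1, len(order) + 1),
        edge_assignment=[None] * len(order),
        projection_value=r.coords[order, 0].copy(),
        is_main=True,
    )


def marker_only_ordering(
    m: ExpressionMatrix, gene: str, direction: str = "increasing"
) -> OrderedPath:
    """Baseline: order cells directly by one marker gene's expression.

    Ascending for ``increasing``; ties keep input order (stable sort).
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError(f"direction must be increasing/decreasing, got {direction!r}")
    row = m.values[m.gene_index(gene)]
    key = row if direction == "increasing" else -row
    order = np.argsort(key, kind="stable")
    return OrderedPath(
        cluster_sequence=[],
        cell_order=[m.cell_ids[i] for i in order],
        pseudotime=np.arange(1, len(order) + 1),
        edge_assignment=[None] * len(order),
        projection_value=row[order].copy(),
        is_main=True,
    )
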