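"""MST pseudotime over NK death states.

Cluster (or state) centroids in PC space are joined by a minimum spanning
tree; the tree is rooted at the healthy NK node, every cell is projected onto
the nearest point of the MST edges incident to its own cluster, and its
pseudotime is the tree-geodesic distance from the root centroid to that
projection.  Nodes of degree >= 3 are the trajectory's decision points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import networkx as nx


class TrajectoryError(ValueError):
    pass


@dataclass
class TrajectoryModel:
    nodes: list[str]
    centroids: np.ndarray               # nodes x dims
    edges: list[tuple[str, str, float]]
    root: str | None = None
    pseudotime: np.ndarray | None = None
    cell_labels: np.ndarray | None = None
    _graph: nx.Graph = field(default=None, repr=False)

    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(self.nodes)
            for a, b, w in self.edges:
                g.add_edge(a, b, weight=w)
            self._graph = g
        return self._graph

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "nodes": self.nodes,
            "root": self.root,
            "edges": [[a, b, w] for a, b, w in self.edges],
            "decision_points": decision_points(self),
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def fit_mst(coords: np.ndarray, labels: np.ndarray) -> TrajectoryModel:
    """Centroid MST: mean coordinates per label, complete graph with
    Euclidean edge weights, exact minimum spanning tree (Kruskal; distance
    ties broken by lexicographic node pair).  ``coords`` may be a raw
    cells x dims array or an Embedding."""
    coords = getattr(coords, "coords", coords)
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq = sorted(str(u) for u in np.unique(labels))
    if len(uniq) < 2:
        raise TrajectoryError("need at least 2 labeled groups")
    cents = []
    for u in uniq:
        mask = labels.astype(str) == u
        if mask.sum() == 0:
            raise TrajectoryError(f"group {u!r} has no cells")
        cents.append(coords[mask].mean(axis=0))
    cents = np.asarray(cents)
    # Kruskal over lexicographically sorted edges makes tie-breaking explicit
    cand = []
    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            d = float(np.linalg.norm(cents[i] - cents[j]))
            cand.append((d, uniq[i], uniq[j]))
    cand.sort(key=lambda e: (e[0], e[1], e[2]))
    g = nx.Graph()
    g.add_nodes_from(uniq)
    uf = {u: u for u in uniq}

    def find(u):
        while uf[u] != u:
            uf[u] = uf[uf[u]]
            u = uf[u]
        return u

    edges = []
    for d, a, b in cand:
        ra, rb = find(a), find(b)
        if ra != rb:
            uf[ra] = rb
            edges.append((a, b, d))
            g.add_edge(a, b, weight=d)
        if len(edges) == len(uniq) - 1:
            break
    model = TrajectoryModel(
        nodes=uniq, centroids=cents, edges=edges, cell_labels=labels.astype(str)
    )
    model._graph = g
    return model


def pseudotime(
    model: TrajectoryModel,
    coords: np.ndarray,
    labels: np.ndarray,
    root: str,
) -> np.ndarray:
    """Tree-geodesic pseudotime from the root centroid.

    Each cell is orthogonally projected onto the segment of every MST edge
    incident to its own cluster's node, the nearest projection is kept, and
    pseudotime is the geodesic distance from the root centroid to that point
    (entering the edge through whichever endpoint is shorter).
    """
    g = model.graph()
    root = str(root)
    if root not in model.nodes:
        raise TrajectoryError(f"root {root!r} is not a node")
    if not nx.is_connected(g):
        raise TrajectoryError("MST is disconnected")
    node_dist = nx.single_source_dijkstra_path_length(g, root, weight="weight")
    coords = getattr(coords, "coords", coords)
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels).astype(str)
    pos = {n: model.centroids[model.nodes.index(n)] for n in model.nodes}
    pt = np.empty(len(coords))
    for idx in range(len(coords)):
        node = labels[idx]
        if node not in g:
            raise TrajectoryError(f"cell {idx} has unknown label {node!r}")
        best = np.inf
        best_time = node_dist[node]
        incident = list(g.edges(node)) or []
        if not incident:
            pt[idx] = node_dist[node]
            continue
        c = coords[idx]
        for a, b in incident:
            pa, pb = pos[a], pos[b]
            seg = pb - pa
            ln2 = float(seg @ seg)
            t = 0.0 if ln2 == 0 else float(np.clip((c - pa) @ seg / ln2, 0.0, 1.0))
            proj = pa + t * seg
            d = float(np.linalg.norm(c - proj))
            if d < best:
                best = d
                ln = np.sqrt(ln2)
                best_time = min(
                    node_dist[a] + t * ln,
                    node_dist[b] + (1.0 - t) * ln,
                )
        pt[idx] = best_time
    model.root = root
    model.pseudotime = pt
    return pt


def decision_points(model: TrajectoryModel) -> list[str]:
    """MST nodes of degree >= 3, ordered by pseudotime of their centroid
    when a root is set (else by node name)."""
    g = model.graph()
    hubs = [n for n in model.nodes if g.degree(n) >= 3]
    if model.root is not None:
        dist = nx.single_source_dijkstra_path_length(g, model.root, weight="weight")
        hubs.sort(key=lambda n: (dist[n], n))
    else:
        hubs.sort()
    return hubs
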