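"""Node-level network topology metrics and topology-based network comparison.

Implements the ten node metrics reported by the Cytoscape
NetworkAnalyzer plugin for simple undirected graphs — degree, average
shortest path length, betweenness centrality, closeness centrality,
clustering coefficient, eccentricity, neighborhood connectivity,
radiality, stress, and topological coefficient — with NetworkAnalyzer's
conventions pinned: all path-based quantities are unweighted and
computed within connected components; betweenness is normalized by
(n_c - 1)(n_c - 2)/2 per component; an isolated node has degree 0,
clustering 0, eccentricity 0 and closeness 0.

Networks are compared by PCA on the stacked (network, node) x metric
table, with per-network centroid distances as a scalar separation
summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["METRIC_COLUMNS", "node_topology", "topology_pca", "TopologyPcaResult"]

METRIC_COLUMNS = [
    "degree",
    "average_shortest_path_length",
    "betweenness_centrality",
    "closeness_centrality",
    "clustering_coefficient",
    "eccentricity",
    "neighborhood_connectivity",
    "radiality",
    "stress",
    "topological_coefficient",
]


def _as_graph(net) -> nx.Graph:
    g = net if isinstance(net, nx.Graph) else net.graph
    if g.is_directed():
        raise ValueError("topology metrics are defined for undirected graphs")
    if any(u == v for u, v in g.edges):
        raise ValueError("self-loops are not allowed")
    return g


def _stress_and_paths(g: nx.Graph, nodes: list) -> tuple[dict, dict, dict]:
    """Distances, shortest-path counts and stress via per-source BFS DAGs.

    ``sigma[s][v]`` counts shortest s->v paths; stress(v) sums, over
    unordered pairs {s, t} with v interior, the number of shortest s-t
    paths through v: sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t).
    """
    dist: dict = {}
    sigma: dict = {}
    for s in nodes:
        d = {s: 0}
        sig = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in g.neighbors(u):
                    if w not in d:
                        d[w] = d[u] + 1
                        sig[w] = 0
                        nxt.append(w)
                    if d[w] == d[u] + 1:
                        sig[w] += sig[u]
            frontier = nxt
        dist[s] = d
        sigma[s] = sig
    stress = {v: 0 for v in nodes}
    for si, s in enumerate(nodes):
        for t in nodes[si + 1 :]:
            if t not in dist[s]:
                continue
            dst = dist[s][t]
            for v in dist[s]:
                if v == s or v == t:
                    continue
                if v in dist[t] and dist[s][v] + dist[t][v] == dst:
                    stress[v] += sigma[s][v] * sigma[t][v]
    return dist, sigma, stress


def _topological_coefficient(g: nx.Graph, v) -> float:
    kv = g.degree(v)
    if kv <= 1:
        return 0.0
    nv = set(g.neighbors(v))
    # nodes at distance <= 2 sharing at least one neighbor with v
    candidates = {m for u in nv for m in g.neighbors(u)} | nv
    candidates.discard(v)
    js = []
    for m in candidates:
        shared = len(nv & set(g.neighbors(m)))
        if shared == 0:
            continue
        js.append(shared + (1 if g.has_edge(v, m) else 0))
    if not js:
        return 0.0
    return float(np.mean(js)) / kv


def node_topology(net) -> pd.DataFrame:
    """The ten NetworkAnalyzer node metrics as a DataFrame indexed by node."""
    g = _as_graph(net)
    nodes = list(g.nodes)
    out = pd.DataFrame(index=pd.Index(nodes, name="node"), columns=METRIC_COLUMNS,
                       dtype=float)
    out["degree"] = [g.degree(v) for v in nodes]
    out["clustering_coefficient"] = pd.Series(nx.clustering(g))
    out["neighborhood_connectivity"] = [
        float(np.mean([g.degree(u) for u in g.neighbors(v)])) if g.degree(v) else 0.0
        for v in nodes
    ]
    out["topological_coefficient"] = [_topological_coefficient(g, v) for v in nodes]

    dist, _, stress = _stress_and_paths(g, nodes)
    out["stress"] = pd.Series(stress)

    for comp in nx.connected_components(g):
        comp = list(comp)
        nc = len(comp)
        sub_ecc = {}
        sub_aspl = {}
        for v in comp:
            dv = dist[v]
            others = [dv[u] for u in comp if u != v]
            sub_ecc[v] = max(others) if others else 0
            sub_aspl[v] = float(np.mean(others)) if others else 0.0
        diameter = max(sub_ecc.values()) if nc > 1 else 0
        sub = g.subgraph(comp)
        btw = (
            nx.betweenness_centrality(sub, normalized=True)
            if nc > 2
            else {v: 0.0 for v in comp}
        )
        for v in comp:
            out.at[v, "eccentricity"] = sub_ecc[v]
            out.at[v, "average_shortest_path_length"] = sub_aspl[v]
            out.at[v, "closeness_centrality"] = (
                1.0 / sub_aspl[v] if sub_aspl[v] > 0 else 0.0
            )
            out.at[v, "betweenness_centrality"] = btw[v]
            out.at[v, "radiality"] = (
                (diameter + 1.0 - sub_aspl[v]) / diameter if diameter > 0 else 0.0
            )
    return out


@dataclass
class TopologyPcaResult:
    scores: pd.DataFrame  # columns PC1, PC2 (+ 'network' label)
    loadings: pd.DataFrame  # metric x PC
    explained_variance_ratio: np.ndarray
    centroids: pd.DataFrame  # network x (PC1, PC2)
    centroid_distances: dict[tuple[str, str], float]


def topology_pca(tables: dict[str, pd.DataFrame], mode: str = "nodes") -> TopologyPcaResult:
    """PCA on topology metrics across networks.

    ``mode="nodes"`` stacks (network, node) rows; ``mode="means"``
    aggregates each network to its per-metric mean first.  Columns are
    unit-variance scaled; zero-variance columns are dropped with a
    warning.  Per-network centroid distances in the PC1-2 plane summarize
    network separation.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 networks to compare")
    frames = []
    for label, tab in tables.items():
        t = tab[METRIC_COLUMNS].copy()
        if mode == "means":
            t = t.mean(axis=0).to_frame().T
        elif mode != "nodes":
            raise ValueError("mode must be 'nodes' or 'means'")
        t.insert(0, "network", label)
        frames.append(t)
    stacked = pd.concat(frames, ignore_index=True)
    x = stacked[METRIC_COLUMNS].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(METRIC_COLUMNS, keep) if not k]
        warnings.warn(f"dropping zero-variance metrics: {dropped}")
    cols = [c for c, k in zip(METRIC_COLUMNS, keep) if k]
    xs = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for c in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u[:, :2] * s[:2]
    evr = (s**2) / np.sum(s**2)
    scores_df = pd.DataFrame(scores, columns=["PC1", "PC2"])
    scores_df.insert(0, "network", stacked["network"].to_numpy())
    loadings = pd.DataFrame(vt[:2].T, index=cols, columns=["PC1", "PC2"])
    centroids = scores_df.groupby("network")[["PC1", "PC2"]].mean()
    dists: dict[tuple[str, str], float] = {}
    labels = list(centroids.index)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            dists[(a, b)] = float(
                np.linalg.norm(centroids.loc[a].to_numpy() - centroids.loc[b].to_numpy())
            )
    return TopologyPcaResult(
        scores=scores_df,
        loadings=loadings,
        explained_variance_ratio=evr[:2],
        centroids=centroids,
        centroid_distances=dists,
    )
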