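"""Brute-force topology oracle used by the tests.

Independent of the library implementation: distances come from
Floyd-Warshall, and path-dependent metrics (betweenness, stress) are
computed by explicitly enumerating every shortest path as a node
sequence.  Intended for small graphs only.
"""

from itertools import combinations

import numpy as np

INF = float("inf")


def floyd_warshall(nodes, adj):
    d = {u: {v: (0 if u == v else INF) for v in nodes} for u in nodes}
    for u in nodes:
        for v in adj[u]:
            d[u][v] = 1
    for k in nodes:
        for i in nodes:
            dik = d[i][k]
            if dik == INF:
                continue
            for j in nodes:
                if dik + d[k][j] < d[i][j]:
                    d[i][j] = dik + d[k][j]
    return d


def enumerate_shortest_paths(s, t, adj, dist):
    """All shortest s-t paths as node tuples, by depth-first extension."""
    if dist[s][t] == INF:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in adj[u]:
            if dist[w][t] == dist[u][t] - 1:
                extend(path + [w])

    extend([s])
    return paths


def oracle_metrics(nodes, edges):
    adj = {u: set() for u in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = floyd_warshall(nodes, adj)
    comp_of = {}
    comps = []
    for u in nodes:
        if u in comp_of:
            continue
        comp = [v for v in nodes if dist[u][v] < INF]
        comps.append(comp)
        for v in comp:
            comp_of[v] = comp

    paths = {}
    for s, t in combinations(nodes, 2):
        paths[(s, t)] = enumerate_shortest_paths(s, t, adj, dist)

    out = {}
    for v in nodes:
        k = len(adj[v])
        comp = comp_of[v]
        nc = len(comp)
        finite = [dist[v][u] for u in comp if u != v]
        aspl = float(np.mean(finite)) if finite else 0.0
        ecc = max(finite) if finite else 0
        diam = max(dist[a][b] for a in comp for b in comp) if nc > 1 else 0

        if k >= 2:
            nbrs = sorted(adj[v])
            links = sum(1 for a, b in combinations(nbrs, 2) if b in adj[a])
            clustering = 2.0 * links / (k * (k - 1))
        else:
            clustering = 0.0

        betw = 0.0
        stress = 0
        for s, t in combinations(comp, 2):
            if v in (s, t):
                continue
            key = (s, t) if (s, t) in paths else (t, s)
            plist = paths[key]
            if not plist:
                continue
            through = sum(1 for p in plist if v in p[1:-1])
            stress += through
            betw += through / len(plist)
        betw = betw / ((nc - 1) * (nc - 2) / 2.0) if nc > 2 else 0.0

        tc = 0.0
        if k > 1:
            js = []
            for m in nodes:
                if m == v:
                    continue
                shared = len(adj[v] & adj[m])
                if shared:
                    js.append(shared + (1 if m in adj[v] else 0))
            tc = float(np.mean(js)) / k if js else 0.0

        out[v] = {
            "degree": k,
            "average_shortest_path_length": aspl,
            "betweenness_centrality": betw,
            "closeness_centrality": 1.0 / aspl if aspl > 0 else 0.0,
            "clustering_coefficient": clustering,
            "eccentricity": ecc,
            "neighborhood_connectivity": (
                float(np.mean([len(adj[u]) for u in adj[v]])) if k else 0.0
            ),
            "radiality": (diam + 1.0 - aspl) / diam if diam > 0 else 0.0,
            "stress": stress,
            "topological_coefficient": tc,
        }
    return out
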