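"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the code paths (and libraries) they check: closeness
via a Floyd–Warshall matrix recursion, betweenness via explicit BFS
shortest-path counting, clustering via a triple loop, contact networks via an
O(n²) distance scan, and accessibility via a from-scratch Shrake–Rupley
sphere-point sampler.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

INF = float("inf")


def floyd_warshall_distances(nodes, edges):
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    d = np.full((n, n), INF)
    np.fill_diagonal(d, 0.0)
    for u, v in edges:
        d[idx[u], idx[v]] = 1.0
        d[idx[v], idx[u]] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    return d


def closeness_oracle(nodes, edges, wf_scaling=True):
    """(N−1)/Σd closeness with optional Wasserman–Faust component scaling."""
    nodes = list(nodes)
    n = len(nodes)
    d = floyd_warshall_distances(nodes, edges)
    out = {}
    for i, node in enumerate(nodes):
        finite = d[i][np.isfinite(d[i])]
        reach = len(finite)  # includes the node itself
        total = finite.sum()
        if reach <= 1 or total == 0:
            out[node] = 0.0
            continue
        value = (reach - 1) / total
        if wf_scaling and n > 1:
            value *= (reach - 1) / (n - 1)
        out[node] = value
    return out


def degree_oracle(nodes, edges, normalized=True):
    nodes = list(nodes)
    deg = {n: 0 for n in nodes}
    for u, v in edges:
        deg[u] += 1
        deg[v] += 1
    if not normalized:
        return {n: float(d) for n, d in deg.items()}
    denom = max(len(nodes) - 1, 1)
    return {n: d / denom for n, d in deg.items()}


def _bfs_paths(adj, source):
    """Hop distances and shortest-path counts from one source."""
    dist = {source: 0}
    sigma = {source: 1.0}
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0.0
                q.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def betweenness_oracle(nodes, edges):
    """Pair-normalized betweenness by explicit shortest-path enumeration."""
    nodes = list(nodes)
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_paths(adj, s)
    bc = {n: 0.0 for n in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            n_st = sigma[s][t]
            for v in nodes:
                if v is s or v is t:
                    continue
                if v in dist[s] and v in dist[t] and dist[s][v] + dist[t][v] == d_st:
                    bc[v] += sigma[s][v] * sigma[t][v] / n_st
    n = len(nodes)
    norm = (n - 1) * (n - 2) / 2.0
    if norm > 0:
        bc = {k: v / norm for k, v in bc.items()}
    return bc


def clustering_inv_oracle(nodes, edges):
    """1/clustering by triple-loop triangle counting; NaN where undefined."""
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    out = {}
    for x in nodes:
        nbrs = sorted(adj[x], key=str)
        k = len(nbrs)
        if k < 2:
            out[x] = math.nan
            continue
        tri = 0
        for i in range(k):
            for j in range(i + 1, k):
                if nbrs[j] in adj[nbrs[i]]:
                    tri += 1
        c = tri / (k * (k - 1) / 2)
        out[x] = 1.0 / c if c > 0 else math.nan
    return out


def contact_edges_oracle(ids, coords, cutoff):
    """All-pairs distance scan: inclusive cutoff, unordered pairs."""
    edges = set()
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                edges.add(frozenset((ids[i], ids[j])))
    return edges


_VDW = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8}


def shrake_rupley_oracle(coords, elements, n_points=960, probe=1.4):
    """From-scratch sphere-point accessibility (Å² per atom)."""
    i = np.arange(n_points)
    golden = math.pi * (3.0 - math.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    r = np.sqrt(1.0 - z * z)
    sphere = np.stack([r * np.cos(golden * i), r * np.sin(golden * i), z], axis=1)
    radii = np.array([_VDW[e] + probe for e in elements])
    coords = np.asarray(coords, dtype=float)
    areas = np.empty(len(coords))
    for a in range(len(coords)):
        pts = coords[a] + radii[a] * sphere
        exposed = np.ones(n_points, dtype=bool)
        for b in range(len(coords)):
            if b == a:
                continue
            d = np.linalg.norm(pts - coords[b], axis=1)
            exposed &= d >= radii[b]
        areas[a] = 4.0 * math.pi * radii[a] ** 2 * exposed.mean()
    return areas


def interface_oracle(atoms_a, owners_a, atoms_b, owners_b, cutoff):
    """All-pairs atom scan: residue IDs of each side within cutoff of the other."""
    set_a, set_b = set(), set()
    for i, xa in enumerate(atoms_a):
        for j, xb in enumerate(atoms_b):
            if np.linalg.norm(xa - xb) <= cutoff:
                set_a.add(owners_a[i])
                set_b.add(owners_b[j])
    return set_a, set_b
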