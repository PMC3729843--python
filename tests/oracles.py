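"""Independent brute-force oracles used across the test suite.

Everything here is written with naive loops and its own logic, never
calling the package internals it checks (resampling, label lookup,
mode counting, BFS, triple enumeration are all reimplemented from the
definitions).
"""

import numpy as np


# -- mapping -------------------------------------------------------------

def oracle_sequence(polyline, parcellation, step):
    """Collapsed label sequence via naive point-by-point sampling."""
    pts = [np.asarray(polyline[0], float)]
    for a, b in zip(polyline[:-1], polyline[1:]):
        a, b = np.asarray(a, float), np.asarray(b, float)
        L = float(np.linalg.norm(b - a))
        k = max(1, int(np.ceil(L / step)))
        for t in range(1, k + 1):
            pts.append(a + (b - a) * t / k)
    inv = np.linalg.inv(parcellation.affine)
    shape = parcellation.label_volume.shape
    seq = []
    for p in pts:
        v = inv[:3, :3] @ p + inv[:3, 3]
        idx = [int(round(c)) for c in v]
        if all(0 <= idx[i] < shape[i] for i in range(3)):
            lab = int(parcellation.label_volume[idx[0], idx[1], idx[2]])
            if lab > 0 and (not seq or seq[-1] != lab):
                seq.append(lab)
    return seq


def oracle_map(streamlines, parcellation, mode, step):
    """Naive reimplementation of the three mapping rules."""
    labels = [int(l) for l in parcellation.labels]
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n), dtype=int)
    retained = 0
    for sl in streamlines:
        seq = oracle_sequence(sl, parcellation, step)
        if mode == "all_pairs":
            R = sorted(set(seq))
            pairs = [(a, b) for i, a in enumerate(R) for b in R[i + 1:]]
        elif mode == "transitions":
            pairs = [tuple(sorted(p)) for p in zip(seq[:-1], seq[1:])]
        elif mode == "endpoints":
            pairs = ([tuple(sorted((seq[0], seq[-1])))]
                     if len(seq) >= 2 and seq[0] != seq[-1] else [])
        else:
            raise ValueError(mode)
        if pairs:
            retained += 1
        for a, b in pairs:
            M[index[a], index[b]] += 1
            M[index[b], index[a]] += 1
    return M, retained


# -- graph metrics -------------------------------------------------------

def bfs_distances(adj, source):
    n = len(adj)
    dist = [-1] * n
    dist[source] = 0
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in range(n):
                if adj[u][v] and dist[v] < 0:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def oracle_nodal(A):
    """Exhaustive nodal metrics on a 0/1 adjacency matrix."""
    A = (np.asarray(A) > 0).astype(int)
    n = A.shape[0]
    deg = A.sum(axis=1)
    tri = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if A[i, j] and A[i, k] and A[j, k] and j != i and k != i:
                    tri[i] += 1
    clust = np.array([2 * tri[i] / (deg[i] * (deg[i] - 1)) if deg[i] >= 2 else 0.0
                      for i in range(n)])

    # closeness with the reachable-fraction (Wasserman-Faust) scaling
    close = np.zeros(n)
    for i in range(n):
        d = bfs_distances(A.tolist(), i)
        reach = [x for j, x in enumerate(d) if x > 0]
        if reach:
            r = len(reach) + 1
            close[i] = (r - 1) / sum(reach) * (r - 1) / (n - 1)

    # betweenness by explicit shortest-path counting (unnormalized)
    dist = [bfs_distances(A.tolist(), s) for s in range(n)]
    sigma = np.zeros((n, n))
    for s in range(n):
        order = sorted(range(n), key=lambda v: dist[s][v])
        for v in order:
            if v == s:
                sigma[s][v] = 1
            elif dist[s][v] > 0:
                sigma[s][v] = sum(sigma[s][u] for u in range(n)
                                  if A[u][v] and dist[s][u] == dist[s][v] - 1)
    btw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if s == v or t == v or dist[s][t] <= 0:
                    continue
                if dist[s][v] >= 0 and dist[v][t] >= 0 and \
                        dist[s][v] + dist[v][t] == dist[s][t]:
                    btw[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]

    # k-core by iterative pruning
    core = np.zeros(n, dtype=int)
    alive = [True] * n
    k = 0
    while any(alive):
        k += 1
        while True:
            degs = [sum(A[i][j] for j in range(n) if alive[j]) if alive[i] else -1
                    for i in range(n)]
            drop = [i for i in range(n) if alive[i] and degs[i] < k]
            if not drop:
                break
            for i in drop:
                alive[i] = False
        for i in range(n):
            if alive[i]:
                core[i] = k
    return {"degree": deg.astype(float), "clustering": clust,
            "triangles": tri.astype(float), "closeness": close,
            "betweenness": btw, "degree_centrality": deg / (n - 1),
            "kcore": core.astype(float)}


def oracle_global(A, centroids, weights=None):
    """Exhaustive global metrics; ``weights`` defaults to the matrix itself."""
    W = np.asarray(A)
    A = (W > 0).astype(int)
    n = A.shape[0]
    m = int(A.sum()) // 2
    density = 2 * m / (n * (n - 1))

    seen = [False] * n
    comps = []
    for s in range(n):
        if seen[s]:
            continue
        d = bfs_distances(A.tolist(), s)
        comp = [v for v in range(n) if d[v] >= 0]
        for v in comp:
            seen[v] = True
        comps.append(comp)

    closed = sum(1 for i in range(n) for j in range(n) for k in range(n)
                 if i != j and j != k and i != k and A[i][j] and A[j][k] and A[i][k])
    triples = sum(1 for i in range(n) for j in range(n) for k in range(n)
                  if i != j and j != k and i != k and A[j][i] and A[j][k])
    transitivity = closed / triples if triples else 0.0

    giant = max(comps, key=len)
    if len(giant) >= 2:
        tot, cnt = 0, 0
        for a in giant:
            d = bfs_distances(A.tolist(), a)
            for b in giant:
                if b != a:
                    tot += d[b]
                    cnt += 1
        aspl = tot / cnt
    else:
        aspl = float("nan")

    wiring = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if W[i][j] > 0:
                wiring += float(W[i][j]) * float(np.linalg.norm(
                    np.asarray(centroids[i]) - np.asarray(centroids[j])))
    return {"density": density, "n_components": len(comps),
            "transitivity": transitivity, "avg_shortest_path": aspl,
            "wiring_cost": wiring}
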