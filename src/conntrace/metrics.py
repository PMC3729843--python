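"""Nodal and global graph metrics for track-count connectomes.

All metrics operate on the binarized graph (an edge is present iff its
track count is positive); the count weights have no canonical distance
transform, so hop-count shortest paths are the default and a
1/weight-distance variant is available behind a flag.  Wiring cost is
the exception: it is Sum_edges weight(i,j) * ||centroid_i - centroid_j||
in mm-weighted units by default, with an unweighted toggle.

Computation is delegated to networkx; this module fixes the
conventions (betweenness unnormalized, degree centrality = deg/(n-1),
clustering of degree<2 nodes = 0) and packages per-subject summaries
for group comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .core import Cohort, Connectome

__all__ = [
    "NodalMetrics",
    "GlobalMetrics",
    "nodal_metrics",
    "global_metrics",
    "subject_summary",
    "NODAL_COLUMNS",
    "GLOBAL_COLUMNS",
]

NODAL_COLUMNS = ("degree", "clustering", "triangles", "closeness",
                 "betweenness", "degree_centrality", "kcore")
GLOBAL_COLUMNS = ("density", "n_components", "transitivity",
                  "avg_shortest_path", "efficiency", "wiring_cost",
                  "total_tracks")


@dataclass
class NodalMetrics:
    """Per-node metric vectors, aligned with the connectome's node order."""

    degree: np.ndarray
    clustering: np.ndarray
    triangles: np.ndarray
    closeness: np.ndarray
    betweenness: np.ndarray
    degree_centrality: np.ndarray
    kcore: np.ndarray

    def to_frame(self, labels=None) -> pd.DataFrame:
        d = {c: getattr(self, c) for c in NODAL_COLUMNS}
        df = pd.DataFrame(d)
        if labels is not None:
            df.insert(0, "label", labels)
        return df

    def means(self) -> dict:
        return {c: float(np.mean(getattr(self, c))) for c in NODAL_COLUMNS}


@dataclass
class GlobalMetrics:
    density: float
    n_components: int
    transitivity: float
    avg_shortest_path: float  # NaN when no component has >= 2 nodes
    efficiency: float         # 1 / avg_shortest_path
    wiring_cost: float
    total_tracks: int

    def as_dict(self) -> dict:
        return {c: getattr(self, c) for c in GLOBAL_COLUMNS}


def _binary_graph(connectome: Connectome, subset=None) -> nx.Graph:
    M = connectome.matrix
    n = M.shape[0]
    if subset is not None:
        subset_idx = _subset_indices(connectome, subset)
        M = M[np.ix_(subset_idx, subset_idx)]
        n = len(subset_idx)
    G = nx.from_numpy_array((M > 0).astype(np.int8))
    return G


def _subset_indices(connectome: Connectome, subset) -> np.ndarray:
    """Node indices for a set of node *labels* (e.g. cortical regions only)."""
    labels = connectome.node_labels()
    wanted = set(int(x) for x in subset)
    unknown = wanted - set(labels.tolist())
    if unknown:
        raise ValueError(f"subset references unknown node labels: {sorted(unknown)}")
    return np.flatnonzero(np.isin(labels, sorted(wanted)))


def nodal_metrics(connectome: Connectome, subset=None) -> NodalMetrics:
    """Degree, clustering, triangles, three centralities, and core number.

    Computed on the binarized (sub)graph.  Betweenness is unnormalized;
    degree centrality is degree/(n-1); a node's kcore is the largest k
    whose k-core still contains it.  ``subset`` restricts to the induced
    subgraph on the given node labels (e.g. corticocortical analysis).
    """
    G = _binary_graph(connectome, subset)
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("nodal metrics require at least 2 nodes")
    order = list(G.nodes())
    deg = dict(G.degree())
    tri = nx.triangles(G)
    clust = nx.clustering(G)
    close = nx.closeness_centrality(G)
    btw = nx.betweenness_centrality(G, normalized=False)
    core = nx.core_number(G)
    return NodalMetrics(
        degree=np.array([deg[v] for v in order], dtype=float),
        clustering=np.array([clust[v] for v in order], dtype=float),
        triangles=np.array([tri[v] for v in order], dtype=float),
        closeness=np.array([close[v] for v in order], dtype=float),
        betweenness=np.array([btw[v] for v in order], dtype=float),
        degree_centrality=np.array([deg[v] / (n - 1) for v in order], dtype=float),
        kcore=np.array([core[v] for v in order], dtype=float),
    )


def global_metrics(connectome: Connectome, subset=None,
                   weighted_paths: bool = False,
                   weighted_wiring: bool = True) -> GlobalMetrics:
    """Whole-network summary: density, components, transitivity, paths, cost.

    Average shortest path length is computed on the largest connected
    component (hop counts by default; distance = 1/weight when
    ``weighted_paths``).  If no component has two nodes the path length
    is NaN (flagged, never silently 0) and so is efficiency.  Wiring
    cost multiplies each present edge's Euclidean centroid distance by
    its track count unless ``weighted_wiring=False``.
    """
    if subset is not None:
        idx = _subset_indices(connectome, subset)
    else:
        idx = np.arange(connectome.n_nodes)
    M = connectome.matrix[np.ix_(idx, idx)]
    n = M.shape[0]
    if n < 2:
        raise ValueError("global metrics require at least 2 nodes")
    G = nx.from_numpy_array((M > 0).astype(np.int8))
    m = G.number_of_edges()
    density = 2.0 * m / (n * (n - 1))
    comps = list(nx.connected_components(G))
    transitivity = nx.transitivity(G)

    giant = max(comps, key=len)
    if len(giant) < 2:
        aspl = math.nan
    elif weighted_paths:
        H = nx.Graph()
        H.add_nodes_from(giant)
        sub = sorted(giant)
        for i, u in enumerate(sub):
            for v in sub[i + 1:]:
                if M[u, v] > 0:
                    H.add_edge(u, v, dist=1.0 / M[u, v])
        aspl = nx.average_shortest_path_length(H, weight="dist")
    else:
        aspl = nx.average_shortest_path_length(G.subgraph(giant))
    efficiency = 1.0 / aspl if aspl and not math.isnan(aspl) else math.nan

    cent = connectome.nodes[["cx", "cy", "cz"]].to_numpy(dtype=float)[idx]
    iu = np.triu_indices(n, k=1)
    dists = np.linalg.norm(cent[iu[0]] - cent[iu[1]], axis=1)
    w = M[iu].astype(float)
    if weighted_wiring:
        wiring = float(np.sum(w * dists))
    else:
        wiring = float(np.sum((w > 0) * dists))

    total = int(connectome.total_tracks_retained) if connectome.total_tracks_retained \
        else int(M.sum() // 2)
    return GlobalMetrics(density=float(density), n_components=len(comps),
                         transitivity=float(transitivity),
                         avg_shortest_path=float(aspl), efficiency=float(efficiency),
                         wiring_cost=wiring, total_tracks=total)


def subject_summary(cohort: Cohort, subset=None) -> pd.DataFrame:
    """One row per subject: node-averaged nodal metrics + global metrics.

    This is the table fed to the scalar group tests: each nodal metric
    averaged over nodes per subject, plus density, components,
    transitivity, path length, efficiency, wiring cost, and the total
    track count.
    """
    rows = []
    for i in range(cohort.n_subjects):
        con = cohort.connectome(i)
        nm = nodal_metrics(con, subset=subset).means()
        gm = global_metrics(con, subset=subset).as_dict()
        row = {"subject_id": cohort.subject_ids[i], "group": cohort.groups[i]}
        row.update({f"mean_{k}": v for k, v in nm.items()})
        row.update(gm)
        rows.append(row)
    return pd.DataFrame(rows)
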