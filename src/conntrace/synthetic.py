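"""Synthetic parcellations, streamline phantoms, and two-group cohorts.

Every downstream stage (mapping, graph metrics, the network-based
statistic, the classifier) is exercised on data generated here with
known ground truth, standing in for the imaging-derived inputs of a
real study:

* parcellations are grown by nearest-seed (Voronoi) assignment in voxel
  space — connected regions without any atlas;
* streamlines are jittered straight segments between region interiors —
  mapping correctness, not anatomical realism, is what matters;
* cohorts draw integer edge weights from a negative-binomial
  (gamma-Poisson) distribution, matching the overdispersed track counts
  (roughly 1 to 1e3 per edge) of probabilistic tractography, with a
  planted connected component of elevated means in one group.  A
  fraction of the planted edges can be *novel*: mean zero in the
  reference group, emulating connections present in only one genotype.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import Cohort, Connectome, Parcellation, StreamlineSet

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "make_parcellation",
    "make_streamlines",
    "make_cohort",
    "random_connected_edges",
]


@dataclass
class SyntheticConfig:
    """Parameters of a two-group synthetic connectome cohort.

    ``effect_ratio`` multiplies the mean of every planted edge in group
    B; ``novel_fraction`` of the planted edges instead get mean 0 in
    group A (and ``base_mean * effect_ratio`` in B).  ``dispersion`` is
    the negative-binomial shape theta: variance = mu * (1 + mu/theta);
    ``inf`` gives Poisson counts.
    """

    n_regions: int = 60
    volume_shape: tuple = (16, 16, 16)
    n_subjects_a: int = 21
    n_subjects_b: int = 15
    base_mean: float = 30.0
    edge_density: float = 0.3
    planted_edges: frozenset = frozenset()
    effect_ratio: float = 1.0
    novel_fraction: float = 0.0
    dispersion: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if self.n_subjects_a < 1 or self.n_subjects_b < 1:
            raise ValueError("subject counts must be positive")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if self.effect_ratio < 1:
            raise ValueError("effect_ratio must be >= 1")
        if not (0 <= self.novel_fraction <= 1):
            raise ValueError("novel_fraction must be in [0, 1]")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if self.base_mean <= 0:
            raise ValueError("base_mean must be positive")
        edges = frozenset((min(int(a), int(b)), max(int(a), int(b)))
                          for a, b in self.planted_edges)
        for a, b in edges:
            if a == b:
                raise ValueError("planted edges must join distinct nodes")
            if not (0 <= a < self.n_regions and 0 <= b < self.n_regions):
                raise ValueError(f"planted edge ({a},{b}) outside 0..{self.n_regions - 1}")
        object.__setattr__(self, "planted_edges", edges)


@dataclass
class GroundTruth:
    """Exact generative record: planted edges and per-group edge means."""

    planted_edges: frozenset
    mean_a: np.ndarray  # (n, n) per-edge mean, group A
    mean_b: np.ndarray  # (n, n) per-edge mean, group B
    novel_edges: frozenset = frozenset()  # planted edges with mean 0 in A


def random_connected_edges(n_edges: int, n_nodes: int, rng) -> frozenset:
    """A random connected subgraph with exactly ``n_edges`` edges.

    Grown as a random tree first (guaranteeing connectivity), then
    densified with random extra edges among the tree's nodes.
    """
    rng = np.random.default_rng(rng)
    if n_edges < 1:
        raise ValueError("n_edges must be >= 1")
    n_span = n_edges + 1  # tree on k nodes has k-1 edges
    if n_span > n_nodes:
        n_span = n_nodes
    nodes = rng.choice(n_nodes, size=n_span, replace=False)
    edges = set()
    for i in range(1, n_span):
        j = int(rng.integers(0, i))
        a, b = int(nodes[i]), int(nodes[j])
        edges.add((min(a, b), max(a, b)))
    while len(edges) < n_edges:
        a, b = rng.choice(nodes, size=2, replace=False)
        a, b = int(a), int(b)
        edges.add((min(a, b), max(a, b)))
    return frozenset(edges)


def make_parcellation(n_regions: int, volume_shape=(16, 16, 16), seed: int = 0,
                      voxel_size: float = 2.0) -> Parcellation:
    """Grow a connected parcellation by nearest-seed voxel assignment.

    Every voxel receives the label of its nearest seed point (ties
    broken by lowest label), so regions are digital Voronoi cells:
    nonempty, voxel-connected, tiling the volume with no background.
    The affine is a uniform ``voxel_size`` mm scaling with a small
    translation so world and voxel coordinates never coincide.
    """
    shape = tuple(int(s) for s in volume_shape)
    n_vox = int(np.prod(shape))
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if n_regions > n_vox:
        raise ValueError(
            f"cannot fit {n_regions} regions into a volume of {n_vox} voxels: "
            "every region needs at least one voxel")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_vox, size=n_regions, replace=False)
    seeds = np.column_stack(np.unravel_index(flat, shape))

    # Multi-source BFS growth: every region is 6-connected by construction
    # (a voxel is only claimed from an already-claimed neighbor), and the
    # cells approximate L1 Voronoi regions of the seed points.
    labels = np.zeros(shape, dtype=np.int32)
    queue = deque()
    for lab, (x, y, z) in enumerate(seeds, start=1):
        labels[x, y, z] = lab
        queue.append((int(x), int(y), int(z)))
    steps = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1))
    nx_, ny_, nz_ = shape
    while queue:
        x, y, z = queue.popleft()
        lab = labels[x, y, z]
        for dx, dy, dz in steps:
            a, b, c = x + dx, y + dy, z + dz
            if 0 <= a < nx_ and 0 <= b < ny_ and 0 <= c < nz_ and labels[a, b, c] == 0:
                labels[a, b, c] = lab
                queue.append((a, b, c))

    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = [-1.0, 2.0, 0.5]

    rows = []
    R, t = affine[:3, :3], affine[:3, 3]
    for lab in range(1, n_regions + 1):
        vox = np.argwhere(labels == lab).astype(float)
        c = vox.mean(axis=0) @ R.T + t
        rows.append((lab, f"region_{lab:04d}", c[0], c[1], c[2]))
    regions = pd.DataFrame(rows, columns=["label", "name", "cx", "cy", "cz"])
    return Parcellation(label_volume=labels, affine=affine, regions=regions)


def _interior_points(parcellation: Parcellation, label: int) -> np.ndarray:
    vox = np.argwhere(parcellation.label_volume == label).astype(float)
    if len(vox) == 0:
        raise ValueError(f"region {label} is empty")
    R, t = parcellation.affine[:3, :3], parcellation.affine[:3, 3]
    return vox @ R.T + t  # voxel centers in world mm


def make_streamlines(connectome_target, parcellation: Parcellation,
                     jitter: float = 0.0, seed: int = 0) -> StreamlineSet:
    """Emit straight, densified streamlines realizing a target count matrix.

    For each region pair (i, j) with target count c, draws c pairs of
    voxel-center points inside regions i and j and connects them with a
    straight polyline resampled at half the minimum voxel edge.  Only
    *interior* points are jittered, so each polyline's endpoints are
    guaranteed to lie inside their regions and endpoint-mode mapping
    recovers the target exactly.
    """
    from .mapping import resample_polyline  # local import avoids cycle

    T = np.asarray(connectome_target)
    labels = parcellation.labels
    if T.shape != (len(labels), len(labels)):
        raise ValueError("target shape must match the parcellation's region count")
    if not np.array_equal(T, T.T) or np.any(T < 0):
        raise ValueError("target must be symmetric and nonnegative")
    if not np.allclose(T, np.round(T)):
        raise ValueError("target counts must be integers")
    rng = np.random.default_rng(seed)
    step = 0.5 * float(parcellation.voxel_sizes.min())
    streamlines = []
    for ia in range(len(labels)):
        for ib in range(ia + 1, len(labels)):
            c = int(round(T[ia, ib]))
            if c == 0:
                continue
            pa = _interior_points(parcellation, int(labels[ia]))
            pb = _interior_points(parcellation, int(labels[ib]))
            for _ in range(c):
                a = pa[rng.integers(len(pa))]
                b = pb[rng.integers(len(pb))]
                line = resample_polyline(np.vstack([a, b]), step)
                if jitter > 0 and len(line) > 2:
                    line = line.copy()
                    line[1:-1] += rng.normal(0.0, jitter, size=line[1:-1].shape)
                streamlines.append(line)
    return StreamlineSet(streamlines, coordinate_space="structural")


def _base_mean_matrix(cfg: SyntheticConfig, rng) -> tuple:
    """Baseline (group A) mean matrix and the derived group-B matrix."""
    n = cfg.n_regions
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    present = rng.random(n_pairs) < cfg.edge_density
    mean_a = np.zeros((n, n))
    mean_a[iu] = np.where(present, cfg.base_mean, 0.0)

    planted = sorted(cfg.planted_edges)
    novel = set()
    if planted and cfg.novel_fraction > 0:
        k = int(round(cfg.novel_fraction * len(planted)))
        if k > 0:
            picks = rng.choice(len(planted), size=k, replace=False)
            novel = {planted[i] for i in picks}

    mean_b = mean_a.copy()
    for a, b in planted:
        if (a, b) in novel:
            mean_a[a, b] = 0.0
            mean_b[a, b] = cfg.base_mean * cfg.effect_ratio
        else:
            if mean_a[a, b] == 0.0:
                mean_a[a, b] = cfg.base_mean  # planted edges exist in both groups
            mean_b[a, b] = mean_a[a, b] * cfg.effect_ratio
    mean_a = mean_a + mean_a.T
    mean_b = mean_b + mean_b.T
    return mean_a, mean_b, frozenset(novel)


def _nb_draw(rng, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and shape ``theta``."""
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    mu = mean[pos]
    if np.isinf(theta):
        out[pos] = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=theta, scale=mu / theta)
        out[pos] = rng.poisson(lam)
    return out


def make_cohort(config: SyntheticConfig):
    """Draw a two-group cohort of symmetric count matrices.

    Returns ``(Cohort, GroundTruth)``.  Group labels are "A" (reference,
    size ``n_subjects_a``) and "B" (size ``n_subjects_b``); subjects are
    i.i.d. across edges and subjects given the group mean matrix.
    """
    rng = np.random.default_rng(config.seed)
    mean_a, mean_b, novel = _base_mean_matrix(config, rng)
    n = config.n_regions
    iu = np.triu_indices(n, k=1)
    mats = []
    groups = []
    for g, mean, count in (("A", mean_a, config.n_subjects_a),
                           ("B", mean_b, config.n_subjects_b)):
        mu = mean[iu]
        for _ in range(count):
            w = _nb_draw(rng, mu, config.dispersion)
            M = np.zeros((n, n), dtype=np.int64)
            M[iu] = w
            mats.append(M + M.T)
            groups.append(g)
    cohort = Cohort(matrices=np.stack(mats), groups=np.array(groups))
    truth = GroundTruth(planted_edges=config.planted_edges,
                        mean_a=mean_a, mean_b=mean_b, novel_edges=novel)
    return cohort, truth
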