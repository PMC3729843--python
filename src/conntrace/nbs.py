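"""Network-based statistic: edgewise t-tests with component-level FWER.

The procedure tests, at every network edge, whether mean track counts
differ between two groups, thresholds the t-statistics (t > 3 in the
original analysis), extracts connected components from the
supra-threshold edges, and compares each observed component's size
(edge count) against the distribution of the *maximal* component size
under group-label permutation.  Because the maximum over the whole
network is used as the null statistic, the resulting p-values control
the family-wise error rate across all edges.

Edges are unordered pairs of 0-based node indices throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Cohort

__all__ = [
    "T_CAP",
    "NBSResult",
    "edgewise_tstat",
    "suprathreshold_components",
    "nbs_test",
    "novel_edges",
    "ratio_bins",
    "PAPER_BIN_EDGES",
]

# Surrogate t for edges with zero pooled variance but a nonzero mean
# difference (all-or-nothing edges, common with sparse integer counts).
# Large enough to exceed any sane threshold, finite so arithmetic stays
# clean.
T_CAP = 1e8

# Percent-increase boundaries used in the original ratio binning:
# [75, 200), [200, 400), [400, 900), [900, inf), plus the "novel" bin.
PAPER_BIN_EDGES = (75.0, 200.0, 400.0, 900.0)

CONTRASTS = ("A>B", "B>A", "two-sided")


@dataclass
class NBSResult:
    t_matrix: np.ndarray
    threshold: float
    components: list            # list of frozenset of (i, j) index pairs
    component_sizes: list       # edge counts, aligned with components
    p_values: np.ndarray        # one per component, in (0, 1]
    null_max_sizes: np.ndarray  # length n_perm
    n_perm: int
    seed: int
    contrast: str

    def significant_edges(self, alpha: float = 0.05) -> frozenset:
        """Union of edges over all components with p < alpha."""
        out = set()
        for comp, p in zip(self.components, self.p_values):
            if p < alpha:
                out |= set(comp)
        return frozenset(out)


def _vectorize_cohort(cohort: Cohort):
    n = cohort.n_nodes
    iu = np.triu_indices(n, k=1)
    X = cohort.matrices[:, iu[0], iu[1]].astype(float)  # (n_subj, n_edges)
    return X, iu


def _t_from_masks(X, X2, masks, n_a, n_b):
    """Pooled-variance two-sample t for each row of boolean ``masks``.

    ``masks`` is (n_perm, n_subj), True marking group-A membership; the
    statistic is positive where group A's mean exceeds group B's.
    Zero-pooled-variance edges get +-T_CAP when the means differ and 0
    when they do not.
    """
    P = masks.astype(float)
    tot = X.sum(axis=0)
    tot2 = X2.sum(axis=0)
    sum_a = P @ X
    sum2_a = P @ X2
    sum_b = tot - sum_a
    sum2_b = tot2 - sum2_a
    mean_a = sum_a / n_a
    mean_b = sum_b / n_b
    ss_a = sum2_a - n_a * mean_a ** 2
    ss_b = sum2_b - n_b * mean_b ** 2
    df = n_a + n_b - 2
    sp2 = (ss_a + ss_b) / df
    np.clip(sp2, 0.0, None, out=sp2)  # guard tiny negatives from cancellation
    diff = mean_a - mean_b
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    degenerate = denom < 1e-12
    t[degenerate & (np.abs(diff) < 1e-12)] = 0.0
    t[degenerate & (diff >= 1e-12)] = T_CAP
    t[degenerate & (diff <= -1e-12)] = -T_CAP
    return t


def _signed(t: np.ndarray, contrast: str) -> np.ndarray:
    if contrast == "A>B":
        return t
    if contrast == "B>A":
        return -t
    if contrast == "two-sided":
        return np.abs(t)
    raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")


def edgewise_tstat(cohort: Cohort, contrast: str = "B>A") -> np.ndarray:
    """Symmetric matrix of pooled-variance two-sample t-statistics.

    The sign follows the contrast: positive where the favored group's
    mean is larger ("B>A" tests for increases in the second group, the
    directional finding of interest).  "two-sided" returns |t|.
    """
    A, B = cohort.split()
    n_a, n_b = len(A), len(B)
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need >= 2 subjects for a t-test")
    X, iu = _vectorize_cohort(cohort)
    mask = (cohort.groups == cohort.group_names()[0])[None, :]
    t = _signed(_t_from_masks(X, X ** 2, mask, n_a, n_b)[0], contrast)
    n = cohort.n_nodes
    T = np.zeros((n, n))
    T[iu] = t
    return T + T.T


def suprathreshold_components(t_matrix: np.ndarray, threshold: float) -> list:
    """Connected components (edge sets) of the graph of edges with t > threshold.

    Returned largest-first; a single supra-threshold edge is a valid
    one-edge component.
    """
    T = np.asarray(t_matrix)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("t_matrix must be square")
    n = T.shape[0]
    iu = np.triu_indices(n, k=1)
    keep = T[iu] > threshold
    rows, cols = iu[0][keep], iu[1][keep]
    return _components_from_edges(rows, cols)


def _components_from_edges(rows, cols) -> list:
    parent = {}

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in zip(rows, cols):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for a, b in zip(rows, cols):
        groups.setdefault(find(a), []).append((int(a), int(b)))
    comps = [frozenset(edges) for edges in groups.values()]
    comps.sort(key=len, reverse=True)
    return comps


def _max_component_size(rows, cols) -> int:
    if len(rows) == 0:
        return 0
    comps = _components_from_edges(rows, cols)
    return len(comps[0])


def nbs_test(cohort: Cohort, threshold: float = 3.0, n_perm: int = 5000,
             contrast: str = "B>A", seed: int = 0,
             _batch: int = 256) -> NBSResult:
    """Run the full permutation NBS on a two-group cohort.

    Group labels are permuted uniformly without replacement (group
    sizes preserved) ``n_perm`` times; the null statistic is the
    maximal supra-threshold component size per permutation (0 when no
    edge survives).  Each observed component's p-value is
    ``(1 + #{null_max >= size}) / (n_perm + 1)`` — never exactly zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    A, B = cohort.split()
    n_a, n_b = len(A), len(B)
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need >= 2 subjects")
    n_subj = cohort.n_subjects
    X, iu = _vectorize_cohort(cohort)
    X2 = X ** 2

    obs_mask = (cohort.groups == cohort.group_names()[0])[None, :]
    t_vec = _signed(_t_from_masks(X, X2, obs_mask, n_a, n_b)[0], contrast)
    n = cohort.n_nodes
    T = np.zeros((n, n))
    T[iu] = t_vec
    T = T + T.T
    components = suprathreshold_components(T, threshold)
    sizes = [len(c) for c in components]

    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        b = min(_batch, n_perm - done)
        masks = np.zeros((b, n_subj), dtype=bool)
        for k in range(b):
            perm = rng.permutation(n_subj)
            masks[k, perm[:n_a]] = True
        t_perm = _signed(_t_from_masks(X, X2, masks, n_a, n_b), contrast)
        above = t_perm > threshold
        for k in range(b):
            idx = np.flatnonzero(above[k])
            null_max[done + k] = _max_component_size(iu[0][idx], iu[1][idx])
        done += b

    p = np.array([(1.0 + np.count_nonzero(null_max >= s)) / (n_perm + 1.0)
                  for s in sizes])
    return NBSResult(t_matrix=T, threshold=float(threshold), components=components,
                     component_sizes=sizes, p_values=p, null_max_sizes=null_max,
                     n_perm=int(n_perm), seed=int(seed), contrast=contrast)


def novel_edges(cohort: Cohort, component_edges, reference_group=None) -> frozenset:
    """Component edges absent from every subject of the reference group.

    An edge qualifies when its weight is 0 in all reference-group
    subjects and nonzero in at least one subject of the other group —
    connections "present only" in the non-reference group.  The
    reference defaults to the first group in sorted label order.
    """
    ga, gb = cohort.group_names()
    if reference_group is None:
        reference_group = ga
    if reference_group not in (ga, gb):
        raise ValueError(f"unknown group {reference_group!r}")
    ref = cohort.matrices[cohort.groups == reference_group]
    other = cohort.matrices[cohort.groups != reference_group]
    out = set()
    for i, j in component_edges:
        if np.all(ref[:, i, j] == 0) and np.any(other[:, i, j] > 0):
            out.add((min(i, j), max(i, j)))
    return frozenset(out)


def ratio_bins(cohort: Cohort, component_edges, bin_edges=PAPER_BIN_EDGES,
               reference_group=None) -> dict:
    """Histogram of per-edge percent increases over the reference group.

    Percent increase = 100 * (mean_other - mean_ref) / mean_ref.  Edges
    with mean_ref = 0 go to a separate "novel" bin; increases below the
    first boundary go to "below".  The counts always partition the
    component: they sum to ``len(component_edges)``.
    """
    edges = list(bin_edges)
    if any(b >= a for a, b in zip(edges[1:], edges[:-1])) or len(edges) < 1:
        raise ValueError("bin_edges must be strictly increasing")
    ga, gb = cohort.group_names()
    if reference_group is None:
        reference_group = ga
    ref = cohort.matrices[cohort.groups == reference_group]
    other = cohort.matrices[cohort.groups != reference_group]
    names = ([f"below_{edges[0]:g}"] +
             [f"[{a:g},{b:g})" for a, b in zip(edges[:-1], edges[1:])] +
             [f"[{edges[-1]:g},inf)", "novel"])
    counts = dict.fromkeys(names, 0)
    for i, j in component_edges:
        m_ref = float(ref[:, i, j].mean())
        m_oth = float(other[:, i, j].mean())
        if m_ref == 0.0:
            counts["novel"] += 1
            continue
        pct = 100.0 * (m_oth - m_ref) / m_ref
        k = int(np.searchsorted(edges, pct, side="right"))
        counts[names[k]] += 1
    return counts
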