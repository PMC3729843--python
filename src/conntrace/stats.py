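"""Supporting statistics: Hardy-Weinberg equilibrium, scalar group tests,
and distribution summaries for gaussianity checks.

The HWE test compares observed genotype counts for a biallelic SNP
against the frequencies expected under random mating (p^2, 2pq, q^2
with p estimated from the allele counts) using a Pearson chi-square on
1 degree of freedom, without continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GenotypeCounts",
    "hwe_chisq",
    "group_ttest",
    "distribution_summary",
]


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts: major homozygote, heterozygote, minor homozygote."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self):
        for name in ("n_AA", "n_Aa", "n_aa"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer")
        if self.n_AA + self.n_Aa + self.n_aa < 1:
            raise ValueError("at least one individual required")

    @property
    def n(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


def hwe_chisq(counts: GenotypeCounts):
    """Pearson chi-square test of Hardy-Weinberg equilibrium.

    Allele frequency p_hat = (2 n_AA + n_Aa) / 2n; expected counts
    (n p^2, 2 n p q, n q^2); chi-square with 1 df (3 genotype classes
    minus 1 estimated allele frequency minus 1), no continuity
    correction; p-value from the upper tail.

    Returns (chi2, p).
    """
    if not isinstance(counts, GenotypeCounts):
        counts = GenotypeCounts(*counts)
    n = counts.n
    p_hat = (2 * counts.n_AA + counts.n_Aa) / (2 * n)
    q_hat = 1.0 - p_hat
    expected = np.array([n * p_hat ** 2, 2 * n * p_hat * q_hat, n * q_hat ** 2])
    observed = np.array([counts.n_AA, counts.n_Aa, counts.n_aa], dtype=float)
    for e, o, allele in zip(expected, observed, ("A", "Aa", "a")):
        if e == 0 and o > 0:
            raise ValueError(
                f"expected count for genotype class {allele!r} is zero "
                "(degenerate allele frequency) but observations are present")
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def group_ttest(values_a, values_b):
    """Pooled-variance two-sample Student's t-test, two-sided.

    Used to compare scalar per-subject network summaries (global
    metrics, node-averaged nodal metrics, total track counts) between
    the two genotype groups.  Returns (t, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    ss = (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
    if ss == 0 and a.mean() != b.mean():
        raise ValueError("zero pooled variance with differing means: t undefined")
    if ss == 0:
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def distribution_summary(values, n_bins: int = 10, grid_size: int = 200):
    """Histogram plus Gaussian-kernel density table for gaussianity checks.

    Returns a dict with ``bin_edges``, ``bin_counts``, ``grid`` and
    ``density``.  The KDE bandwidth follows Silverman's rule; the grid
    spans the data range padded by three bandwidths so the density mass
    is essentially fully covered.  Degenerate (constant) samples fall
    back to a single occupied bin and a narrow Gaussian bump centred on
    the constant.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values")
    counts, edges = np.histogram(x, bins=n_bins)
    spread = x.std(ddof=1)
    if spread == 0:
        h = max(abs(x[0]) * 1e-3, 1e-3)
        grid = np.linspace(x[0] - 4 * h, x[0] + 4 * h, grid_size)
        density = np.exp(-0.5 * ((grid - x[0]) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    else:
        kde = sps.gaussian_kde(x, bw_method="silverman")
        h = spread * kde.factor
        grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, grid_size)
        density = kde(grid)
    return {"bin_edges": edges, "bin_counts": counts,
            "grid": grid, "density": density}
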