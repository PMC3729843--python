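# Methods

## Contact-point connectome mapping

A streamline is mapped onto a parcellation by resampling it at spacing
≤ `step` (default: half the smallest voxel edge, in mm), converting each
sample to voxel indices through the inverse affine, rounding to the
nearest voxel (voxel-center, 0-based convention; labels are categorical
and never interpolated), discarding background and out-of-volume
samples, and collapsing consecutive duplicate labels. Three counting
rules are exposed over the resulting label sequence:

* **all_pairs** — every unordered pair of *distinct* regions the
  streamline touches is incremented once per streamline. This reads
  "counts a fiber between every pair of regions it contacts" as
  once-per-pair: re-entries do not double-count, so an edge weight is
  bounded by the fiber count.
* **transitions** — only pairs adjacent in the collapsed sequence,
  once per occurrence; re-crossings count again. This is the
  per-traversal reading of the same rule; neither reading is asserted
  as the original analysis's exact behavior, both are available.
* **endpoints** — the classical start/end convention: the (first, last)
  pair, only when both exist and differ.

`transitions ≤ all_pairs` and `endpoints ≤ all_pairs` hold entrywise
(both transition pairs and the endpoint pair are touched pairs); no
ordering between transitions and endpoints is claimed. The
endpoint-mode matrix total is bounded by the streamline count.
`total_tracks_retained` counts streamlines contributing at least one
increment; streamlines touching fewer than two regions are counted in
a log summary and contribute nothing.

**Sampling is a real approximation.** Any finite sampling density can
miss a voxel the polyline clips at a corner; we measured that even an
exact analytic traversal differs from 10×-oversampled point sampling
on ~2% of generator-native streamlines. The oracle tests therefore
compare against an independent brute-force reimplementation *at the
same spacing* (at both the default and 10×-finer spacing), which
verifies the counting/collapse/indexing logic; cross-resolution
equality is not a property this algorithm (or any sampled variant of
it) has. Reported weights should be read as "contacts at the stated
resolution".

Reverse mapping (`filter_tracks_by_edges`) returns exactly the
streamlines that would increment at least one edge of a query set
under a given mode — used to project a significant component back onto
the tractogram.

## Synthetic data

The generator provides the ground truth the statistics are validated
against; it emulates the *statistical* structure of tractography
output, not its anatomy:

* **Parcellations** are grown by multi-source BFS from random voxel
  seeds, giving nonempty, voxel-connected regions that tile the volume
  (approximate L1 Voronoi cells). The affine is a uniform 2 mm scaling
  with a nonzero translation so world and voxel coordinates never
  coincide silently.
* **Streamlines** are straight segments between voxel centers inside
  the two target regions, densified to half a voxel edge, with optional
  Gaussian jitter applied to interior points only — endpoints stay
  inside their regions, so endpoint-mode mapping recovers the target
  matrix exactly at any jitter, and jitter=0 keeps all modes simple.
  Curved geometry is deliberately out of scope: mapping correctness,
  not anatomical realism, is what downstream tests need.
* **Cohorts** draw each subject's upper-triangle edge counts
  independently from a negative-binomial (gamma-Poisson): mean matrix
  per group, shape `dispersion` θ with variance μ(1 + μ/θ), θ=∞ giving
  exact Poisson. The NB2 constant-shape parameterization is the field
  standard for overdispersed counts; the default θ=10 puts
  variance/mean ≈ 4 at the default base mean 30 (track counts of
  probabilistic tractography are strongly overdispersed; no
  subject-level noise model is available to fit, so θ is a surfaced
  config knob, never hard-coded). A planted connected edge set gets
  its group-B means multiplied by `effect_ratio`; a `novel_fraction`
  of planted edges instead has mean 0 in group A — connections present
  in only one group. Everything used for generation is returned as
  `GroundTruth`.

What a green test does **not** establish: robustness to spatially
correlated noise, subject-level global scaling (head size, SNR),
curved-fiber mapping artifacts, or distance-dependent edge density —
none of which the generator models.

## Network-based statistic

Edgewise pooled-variance (Student) two-sample t-statistics are computed
on the vectorized upper triangle (the cited NBS convention; Welch is
not used). Sparse integer edges can have zero pooled variance: with a
nonzero mean difference the statistic is set to the documented cap
`T_CAP = 1e8` (supra-threshold by construction, letting all-or-nothing
edges join components), with zero difference it is 0. One contrast per
run: "A>B", "B>A", or "two-sided" (|t|).

Components are the connected components of the graph of edges with
`t > threshold` (default 3); component size is the **edge count**
(extent, matching a maximal-component-size null), and a single edge is
a valid component. The null distribution is the maximal component size
over `n_perm` uniform label permutations preserving group sizes
(default 5000); each observed component gets
`p = (1 + #{null_max ≥ size}) / (n_perm + 1)`, which is never zero and
identical to appending the observed maximum to its own null.

**Calibration.** The permutation test is exact in the super-uniform
sense — the familywise rejection rate never exceeds the nominal level —
but it is *conservative* here: the null statistic is a small integer
with heavy ties, so at α=0.05 the attained level measured over 1400
simulated null cohorts (40 nodes, 20 vs 20) is ≈0.017. This is a
property of max-component permutation tests on discrete statistics,
not an implementation artifact (the t-statistics, component extraction
and p-value convention are each verified against independent oracles).
Two-sided calibration bands around the nominal level will read low.

`novel_edges` flags component edges with weight 0 in every
reference-group subject and nonzero weight in at least one other-group
subject. `ratio_bins` histograms percent increases
`100·(mean_other − mean_ref)/mean_ref` over the boundaries
(75, 200, 400, 900), with `mean_ref = 0` edges in a separate "novel"
bin and a "below" bin so the counts always partition the edge set.

## Graph metrics

All metrics are computed on the binarized graph (edge present iff
weight > 0): track-count weights have no canonical distance transform,
and no weighted variant of the original analysis is documented. A
1/weight-distance shortest-path option exists behind a flag. Fixed
conventions: betweenness unnormalized; degree centrality
degree/(n−1); closeness with the reachable-fraction (Wasserman-Faust)
scaling; clustering of degree<2 nodes is 0; a node's k-core number is
the largest k whose k-core contains it. Whether the original analysis
normalized centralities is unknowable; group comparisons are invariant
to these choices only under monotone transforms, so the conventions
are documented rather than argued.

Average shortest path length uses hop counts on the largest connected
component (a disconnected graph would otherwise have no finite value);
when no component has two nodes it is NaN — flagged, never silently 0.
Efficiency is its reciprocal. Wiring cost is
`Σ_edges weight·‖centroid_i − centroid_j‖` (mm-weighted units) with an
unweighted toggle (`Σ distances` over present edges), since the
source definition does not say whether weights enter. Restriction to a
node subset (e.g. corticocortical) is the same computation on the
induced subgraph, exposed as a `subset` parameter. `subject_summary`
emits one row per subject: node-averaged nodal metrics, global
metrics, and the retained track count — the table the scalar group
t-tests consume.

## Gaussian-process classification

Connectomes are vectorized as upper-triangle rows (fixed node order,
inverse map retained; no topology or spatial information). The binary
GP classifier uses the linear kernel `k(x,x') = σ²·xᵀx'/d + b` (d =
feature count, for conditioning), Bernoulli likelihood with probit
link, and the Laplace approximation: Newton iteration for the
posterior mode with the standard numerically stable Cholesky form, and
the closed-form probit predictive `Φ(μ*/√(1+σ*²))`. Laplace was chosen
over expectation propagation for determinism and simplicity; the
averaged predictive it produces is *moderated* — for cleanly separable
data it plateaus near 0.89 regardless of margin — so a "plugin"
predictive `Φ(μ*)` is available when a sharp confidence readout is
wanted (both give identical classifications). Kernel hyperparameters
(σ², b) are set per training fold by Nelder-Mead maximization of the
Laplace marginal likelihood (an explicit initial simplex avoids the
degenerate default at log θ = 0); `optimize=False` keeps fixed unit
values for exact-reproducibility tests. Features are mean-centered per
training fold by default (toggleable; whether the original toolbox
centered is unknowable).

Because the kernel is linear the primal weights are recoverable from
the representer coefficients: `w = σ²·Xᵀα/d`, intercept `b·Σα`, with
`f(x) = wᵀ(x − x̄) + intercept` — asserted to 1e-6 per fold in tests.
`threshold_weights` keeps the top `⌈keep_fraction · n_nonzero⌉` edges
by |w| and reports the retained fraction of total absolute weight.

Evaluation is leave-one-out cross-validation; predictions use the 0.5
probability threshold with exact ties assigned to the first class in
sorted label order (deterministic). A fold whose training labels
collapse to one class raises an error naming the fold — flagged, never
silently skipped. Accuracy and per-class predictive value (precision:
among subjects predicted into a class, the fraction truly in it) come
from the pooled confusion matrix. Significance is assessed by
repeating the entire LOO procedure under label permutation
(`p = (1 + #{perm ≥ observed})/(n_perm + 1)`, default 1000
permutations); how the original study obtained its classification
p-values is unstated, and whole-procedure label permutation is the
conservative standard choice. Permuted replicates with an undefined
statistic (no predictions into the class) never count as exceeding.

## Supporting statistics

* **Hardy-Weinberg**: allele frequency p̂ = (2n_AA + n_Aa)/2n, expected
  counts (np̂², 2np̂q̂, nq̂²), Pearson chi-square on 1 df without
  continuity correction, upper-tail p. For the worked 134-subject
  example (80, 42, 12) this gives χ² = 3.25, p = 0.07; that triple is
  the unique integer reconstruction consistent with the printed
  genotype frequencies and statistic (verified by exhaustive search in
  the tests) — a reconstruction, not reported data. The
  zero-expectation error branch is unreachable for self-consistent
  counts (p̂ = 0 forces the observed class to zero too) and exists as a
  guard. With Yates' correction the statistic would differ; none is
  applied.
* **Scalar group tests**: pooled-variance two-sample Student's t,
  two-sided, via scipy; zero pooled variance with differing means is
  an error in this scalar context (unlike the capped edgewise case).
* **Distribution summaries** return histogram counts plus a Gaussian
  KDE (Silverman bandwidth) on a padded grid for gaussianity
  inspection by plotting; no formal normality statistic is invented.

## Numerical and design notes

* Seeds: every stochastic routine takes an integer seed and is
  bit-reproducible; batch permutation generation is chunked (256 per
  block) to bound memory at 1015-node scale.
* The NBS permutation engine computes all group sums by mask-matrix
  multiplication; a 40-node, 40-subject, 500-permutation run takes
  ~0.05 s, and 5000 permutations at 60 nodes ~2 s on one CPU.
* Tie-breaks: component lists are sorted largest-first; weight
  thresholding uses a stable sort so equal |w| edges keep index order.
* Degenerate inputs: all-isolated graphs yield NaN path length (and
  NaN efficiency); empty streamline sets and empty edge sets are valid
  and yield empty outputs; a connectome constructor validates symmetry,
  zero diagonal, nonnegative integer weights on every instance the
  pipeline creates.
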