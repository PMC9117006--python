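# Methods

`efcpipe` implements an edge-centric functional-connectivity (eFC) analysis
for distinguishing two groups of subjects from regional BOLD time series,
together with a synthetic-cohort generator that makes the entire pipeline
testable without access to clinical data. This note documents the models,
the parameters that matter, the numerical choices, and what the synthetic
experiments can and cannot show.

## The edge-centric pipeline

**Edge time series.** For a subject with a T × R time-series matrix, each of
the E = R(R−1)/2 region pairs ("edges") gets a time series of sliding-window
Pearson correlations (window length w TRs, step 1 TR, N_window = T − w + 1
windows). Edge order is fixed: row-major over pairs (i < j), 0-based
internally, 1-based in written tables.

**Edge clustering.** Edge series are z-scored within each subject (so
between-subject level differences do not dominate the Euclidean geometry),
concatenated across subjects along the window axis, and partitioned by
k-means (k-means++ initialization, 10 restarts, fixed seed). Empty clusters
are dropped and ids compacted. By default the clustering is fitted on all
subjects, replicating the original analysis protocol; a `cluster_scope =
"train"` mode refits on outer-training subjects only and carries the
edge→cluster map (a function of edges, not subjects) to held-out subjects.

**eFC and features.** Averaging member edges gives one series per cluster
and subject; the K × K Pearson correlations among those averages form the
subject's eFC network, whose nodes are edge clusters. The classifier input
is one weighted local clustering coefficient (WLCC) per node — the Onnela
geometric-mean-of-triangles form on weights normalized by the largest
off-diagonal magnitude, with C_i = 0 for degree < 2. Negative correlations
enter by absolute value (`negatives="abs"`; zeroing is available). The
coefficient is invariant under global positive rescaling and lies in [0, 1].
Note that on a dense correlation graph every weak sampled correlation counts
toward the degree, so even a perfect triangle does not reach C = 1 unless
the rest of the graph is exactly zero.

**Classification.** Repeated, nested, stratified 10-fold CV: 10 repetitions
× 10 outer folds = 100 trained models. For each outer training set, an inner
stratified 10-fold CV scores every (w, K) configuration — LASSO selection
followed by a linear soft-margin SVM (C = 1) inside every inner split — and
the configuration with the largest mean inner accuracy wins (ties toward
fewer clusters, then shorter windows). The winner is refit on the full outer
training set and scored on the held-out fold. Features are standardized with
training-set statistics only; no held-out value enters standardization,
LASSO, or SVM fitting. The LASSO is L1-penalized linear regression on the
±1 labels; its penalty is chosen by an internal 3-fold CV over a two-decade
logarithmic path of 12 values below the smallest all-zero penalty, and an
empty selection falls back to the single best two-sample-t feature.
Accuracy, sensitivity, specificity and F1 (positive class = the
exposed-analogue, +1) are pooled over the outer folds of each repetition;
AUC is the rank statistic of the pooled decision scores per repetition;
means over repetitions are reported.

**Permutation validation.** Labels are shuffled n_perm times and the entire
nested CV is rerun per shuffle; p = (1 + #{null ≥ real}) / (1 + n_perm). The
feature bank does not depend on labels, so it is computed once and reused
across permutations.

**Attribution.** A cluster's occurrence rate is its selection count over the
100 fits divided by 100; its normalized weight is its mean (signed) SVM
weight over the fits where selected, times the occurrence rate. Each member
edge of a selected cluster accumulates the full |normalized weight|
("connection-wise contribution"; a size-normalized mode divides by cluster
size). Region contributions sum incident-edge mass. Network indices project
edge mass through a fractional ROI→network affiliation table: for edge
(i, j) with mass c, the ordered network pair (a, b) receives c·p_i(a)·p_j(b);
diagonal mass is the intra-network index, off-diagonal mass enters the
symmetric pairwise matrix and — halved per endpoint network — the
inter-network index. Three identities hold exactly and are asserted in the
tests: total edge mass equals Σ|normalized weight|·(cluster size); intra +
inter mass equals total edge mass; the upper triangle (with diagonal) of the
pairwise matrix equals total edge mass. A `hard` mode collapses each ROI to
its maximum-affiliation network first. The top-fraction list takes
⌊fraction · n_nonzero⌋ edges by |contribution|, ties broken by ascending
edge id.

## The synthetic cohort generator

Each subject is drawn from a zero-mean Gaussian process with time-varying
covariance Σ(t) = Σ_base + g·δ_eff·s(t)·Δ. Σ_base is a block correlation
matrix (unit diagonal, `rho_within` = 0.4 inside each of M contiguous
network blocks, `rho_between` = 0.1 across blocks — well-conditioned values
in the range reported for within/between-network FC). s(t) is white noise
smoothed with a Gaussian kernel (σ = `modulation_timescale`/2) and
standardized to mean 0, SD 1 within the subject; Δ has ±1 entries at the
planted ROI pairs; the gate g is 1 for group A ("positive", +1) and 0 for
group B (−1). Because s has exact zero mean per subject, expected static
covariance is Σ_base in both groups: the groups differ only in dynamics.
After sampling, an AR(1) filter (coefficient 0.3) adds temporal
autocorrelation and columns are re-standardized.

δ_eff is the largest amplitude ≤ `delta` keeping Σ(t) positive semidefinite
for every realized s(t); since Σ is linear in s and the PSD cone is convex,
checking the two realized extremes of s suffices, and the amplitude shrinks
geometrically by 0.9 until both pass (error if it falls below 10⁻³·delta).
Shrinkage rather than eigenvalue clipping keeps the planted pattern
undistorted; the realized amplitude is recorded in the ground truth.

Default desk-scale cohort: R = 30 ROIs in M = 4 networks, T = 240 time
points, 20 + 20 subjects, `delta` = 0.4, 12 planted inter-network edges.
The planted pairs are ROI-disjoint (pairing consecutive network blocks
positionally) with alternating ±1 signs: disjointness keeps ‖Δ‖₂ = 1, which
minimizes PSD shrinkage, and mixed signs create anti-correlated edge groups
so the effect appears *between* edge clusters, where eFC can see it.
`modulation_timescale` = 30 TRs — the same order as the sliding windows, so
windowed correlations can track the modulation, and comparable to the
tens-of-seconds co-fluctuation timescales described for resting-state
dynamics.

The toy affiliation table assigns each ROI to its covariance block; a
configurable fraction of ROIs get split 0.6/0.4 membership across two
networks, emulating parcels that overlap two canonical networks.

**What the generator does not emulate:** scanner physics, head motion,
physiological confounds, spatial autocorrelation within parcels,
hemodynamic lag, or any voxel-level structure. Passing tests show the
pipeline's statistical machinery behaves correctly under a controlled
dynamic-only group difference; they say nothing about effect sizes in real
infant cohorts.

## A realizability ceiling on the planted amplitude

The PSD rule and the standardized Gaussian latent jointly cap the realizable
modulation: with |s| reaching ≈ 3.4 over 20 subjects × 240 TRs and a
unit-diagonal base correlation (smallest eigenvalue ≤ 1), δ_eff ≤
λ_min(Σ_base)/max|s| ≈ 0.18–0.21 regardless of the requested `delta`. At
that amplitude the correlation between two co-modulated disjoint edges'
windowed series within group A is ≈ 0.2 (halved again across the
concatenation with group B), *weaker* than the shared-ROI sampling-noise
affinity that k-means clusters on. Planted edges therefore scatter across
clusters on most seeds, eFC-WLCC group effects are modest (max |t| ≈ 2–4
across features), and downstream classification and recovery results vary
strongly from seed to seed: some cohorts yield a clear dynamic-vs-static
advantage, others none. The desk-scale comparison in the acceptance tests
reports this honestly rather than raising the planted amplitude beyond its
documented default.

## Problem sizes used in tests and the acceptance script

- Dynamic-vs-static comparison: 5 cohorts (seeds 0–4) at the full 10 × 10
  protocol with the desk grids w ∈ {20, 30, 40}, K ∈ {8, 16, 32}; 5 further
  cohorts (seeds 5–9) at 3 repetitions feed only the attribution/recovery
  summaries. The acceptance script uses 2 cohorts.
- Permutation type-I calibration: 20 null cohorts (R = 16, T = 120, 8 + 8
  subjects, `delta` = 0), 99 permutations each, single configuration
  (w = 20, K = 8), 2 repetitions, 4 outer folds.
- Permutation power: the default planted cohort, 99 permutations, the
  grid-midpoint configuration (w = 30, K = 16), 2 repetitions.

These sizes keep the whole study on the scale of minutes per cohort on one
CPU; the full-size protocol (windows 50–120 TRs step 10, 100–800 clusters
step 100, 5000 permutations) is available via `efcpipe.full_scale_protocol()` and
the configuration file.

## Numerical and degenerate-input policies

- Windowed correlations from cumulative first/second moments, clipped to
  [−1, 1]; zero-variance windows yield 0 for affected edges with a warning.
- eFC rows with zero variance get zero correlations (diagonal stays 1).
- Constant features are neutralized before standardization; an all-constant
  feature matrix is an error.
- k-means label compaction is by first appearance, making relabeling
  deterministic; all seeds derive from the configuration seed via
  `numpy.random.SeedSequence`, and reruns are bit-identical.
- Cohort TSVs are written at %.17g and read with round-trip float parsing,
  so file round trips are exact.

## Known limitations

- The inner grid search selects among 9 configurations from ≈ 36 training
  subjects; the winner's inner accuracy is optimistically biased (a standard
  winner's-curse effect), which at weak effect sizes makes the outer
  estimate noisy.
- The LASSO-on-labels recipe treats ±1 labels as a regression target;
  an L1-logistic variant would be a natural alternative (not implemented).
- Attribution under `cluster_scope="train"` generalizes the occurrence-rate
  bookkeeping to per-fold clusterings; published normalized weights assume
  the shared-clustering (`"all"`) protocol.
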