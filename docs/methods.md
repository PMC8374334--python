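# Methods

`modselect` implements a modularity-guided pipeline for classifying subjects
from functional brain networks (FBNs): network estimation, module discovery,
module-aware feature selection, and linear-SVM classification under nested
subject-level cross-validation. This note records the models, the defaults
and why, the numerical choices, and what the synthetic benchmarks do and do
not demonstrate.

## Network estimation

An FBN for one scan is the m×m matrix of pairwise Pearson correlations of
the ROI BOLD time series, optionally Fisher r-to-z transformed
(`z = arctanh(r)`, variance-stabilising). The diagonal is fixed at 0 in all
estimators: self-edges carry no information and `arctanh(1)` diverges.
Perfect correlations (degenerate synthetic inputs) are clipped to
`1 − 1e−7` before the transform. An alternative estimator is sparse inverse
covariance (graphical lasso via scikit-learn), reported as partial
correlations `−Θ_ij/√(Θ_ii Θ_jj)`; its penalty `reg` directly controls
network sparsity. Edge-noise perturbations draw one Gaussian per unordered
pair and mirror it, so perturbed matrices stay valid symmetric FBNs.

## Module discovery

FBNs are signed graphs. The signed degree `d_i = Σ_j |w_ij|` makes the
normalized Laplacian `L = I − D^{−1/2} W D^{−1/2}` positive semi-definite
with spectrum in [0, 2] even with negative weights. Clustering follows the
classical spectral recipe on this signed L: eigenvectors of the K smallest
eigenvalues, row-normalised to unit length (all-zero rows are left at zero,
since they cannot be scaled), then k-means on the rows. k-means uses
k-means++ with 20 restarts and a threaded seed, so partitions are
deterministic per seed; eigenvector sign/ordering ambiguity and eigenvalue
ties mean partitions are unique only up to this ambiguity. Partition quality
is the signed normalized cut `sNcut = Σ_k (x_kᵀ L x_k)/(x_kᵀ D x_k)`;
spectral clustering minimises its continuous relaxation, so on small
instances we check near-optimality (within 10%) against exhaustive
enumeration rather than exact optimality. The enumeration suite uses signed
planted-partition instances (m = 6–8, K = 2–3, within-block weight +0.5,
between-block −0.2, edge noise σ ∈ {0.05, 0.1, 0.2}) — the modular regime
the method is designed for.

The group-level partition is obtained by clustering the element-wise mean
of the control-group networks (a simple, linear group representative).
Inside cross-validation the partition is recomputed per outer fold from the
*training-fold* controls only, which is the defensible no-leakage default.
K is a hyperparameter swept externally, not tuned in the inner loop.

## Grouped edge features and selection

Each network is symmetrically permuted so nodes of a module are adjacent,
and the strict upper triangle is unrolled: within-module edges first
(module blocks in order, row-major), then between-module edges
(module-pair blocks in lexicographic order). The order is frozen and the
original region pair of every feature is recorded, so selections map back
to region pairs reproducibly. Groups: one group per module with ≥ 2 nodes
(singleton modules contribute no within edges; their slot is dropped), plus
one singleton group per between-module edge.

Selection solves

    min_w  ½‖y − Xw‖² + λ Σ_g c_g ‖w_g‖₂ ,   c_g = √d_g (default),

with labels coded −1/+1 and y centred (equivalent to an unpenalised
intercept). The √d_g weight is the standard group-LASSO normalisation used
by the common solvers; a `linear` (c_g = d_g) switch is provided. The
solver is proximal gradient with FISTA acceleration, exact Lipschitz step
`1/λ_max(XᵀX)`, block soft-thresholding prox, and a monotone safeguard: an
accelerated step that would raise the objective is replaced by a plain
proximal step (with momentum restart), so the objective trace is
non-increasing. Convergence is a relative objective change below 1e−10
(default) with a KKT residual reported; coefficients below 1e−11 are
snapped to exact zero, and "selected" means `|w_j| > 1e−8`.

λ is specified as a fraction of `λ_max = max_g ‖X_gᵀy‖/c_g`, the smallest
penalty with an all-zero solution, computed on each training set. The CV
grid {0.01, 0.1, …, 1} therefore has the same meaning for every design
size and scale. Columns are left on the Fisher-z scale by default (the
objective is stated on raw X); per-fold standardisation is available but
off by default.

Baselines mirror the common comparison schemes: a two-sample t-test filter
(its swept hyperparameter is the p-value threshold), a flat LASSO (the
group solver with singleton groups — verified against scikit-learn's
coordinate-descent LASSO), node statistics (LCC, DC, BC, CC, EC via
networkx on |W|, with distance = 1/|w| for path statistics; the weighted
conventions are not canonical, so different choices shift node-level
results), and the global clustering coefficient (mean LCC).

## Evaluation

Folds are assigned by subject: subjects are shuffled within class and dealt
round-robin into folds with a single running pointer across classes, which
guarantees fold subject counts differ by at most one while keeping classes
balanced (e.g. 174 subjects → folds of 34/35). All scans of a subject
follow its fold; predictions are scored per scan. The inner 5-fold CV picks
the selector hyperparameter by accuracy, ties broken toward the sparser
model (larger λ; smaller α for the t-test). The classifier is a linear SVM
with C = 1; AUC uses the SVM decision values. An empty selection falls back
to majority vote and is flagged. Repetitions redraw the fold partition with
per-repetition seeds; all methods share each repetition's partition, and
paired two-sided t-tests compare per-repetition accuracies (a method paired
with itself, or any all-zero difference, is flagged degenerate, never
significant). Default repetitions are 10 at desk scale (configurable
upward); reported SDs state the repetition count used. The bootstrap
ensemble resamples training *subjects* with replacement per outer fold,
trains one selector+SVM per resample at the fold's chosen hyperparameter,
and majority-votes test predictions.

Every fitted artefact (partition, selected features, classifier) logs the
scan ids it was computed from; an audit pass asserts these are
training-fold scans only.

## Synthetic cohorts

The time-series generator mirrors the real estimator chain: a block-modular
correlation matrix (unit diagonal, within-module +0.4, between-module −0.1
by default — a clearly modular signed structure that is positive definite
for the default geometry; infeasible structures are eigenvalue-floored at
1e−6 and flagged), T = 150 multivariate-normal timepoints per scan (a
typical resting-state length), 20 subjects per class. Patients have the
correlation on a small planted edge set reduced by 0.3 (connectivity loss
on two edges inside one module by default); each subject carries a shared
N(0, 0.05) shift on those edges, so a subject's repeat scans are correlated
and subject-level CV is meaningfully different from scan-level CV. A
direct-edge generator (class mean matrix + symmetric Gaussian edge noise)
skips the time-series stage for cheap evaluation-layer experiments. With
`effect_size = 0` the classes are exchangeable by construction, giving the
null cohorts used for calibration.

What these cohorts do not emulate: hemodynamics, head motion, scanner
artefacts, spatially heterogeneous module sizes, or realistic effect
topographies. Passing the benchmarks shows the pipeline is correct and
leak-free under its own assumptions, not that it attains any particular
accuracy on real cohorts.

## Benchmark design choices

Calibration of the paired test is measured over meta-repetitions in which
*each repetition regenerates the cohort* as well as the partition. On a
single fixed null cohort two different feature pipelines have
cohort-conditional accuracy differences, so the paired t-test on
partition-only repetitions is not a 5% test; fresh-cohort repetitions make
the per-repetition differences independent with mean zero, which is the
property being checked. Problem sizes in the canned experiments (m = 12–20
regions, 40 subjects, 10 repetitions, 200 meta-repetitions) are desk-scale
choices that keep the full validation run in minutes.

## Known limitations

- Module discovery and selection are two separate stages; the discovered
  modules are not optimised for the downstream classifier.
- The weighted node-statistic conventions (and hence node-level baselines)
  are one choice among several in use.
- k-means restarts make partitions deterministic per seed but not canonical;
  near-degenerate eigengaps can flip partitions between environments.
- The flat-LASSO equivalence and KKT checks validate the solver at
  moderate conditioning; extremely correlated designs will converge slowly.
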