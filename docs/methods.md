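# Methods

## Problem

Chromatin-accessibility (ATAC-seq) peak-score matrices for tumor cohorts
are extremely wide — hundreds of thousands of peaks against a few hundred
samples — which defeats clustering algorithms that work directly on the
feature space. `aaeclust` compresses each sample into a low-dimensional
latent code with an adversarially regularized autoencoder, clusters the
codes with a Gaussian mixture model (GMM), selects the number of clusters
by the Davies-Bouldin (DB) index, and then characterizes the clusters by
survival separation, clinical-covariate enrichment, and random-forest
marker peaks. The same machinery applies to any nonnegative normalized
expression-like matrix (e.g. RNA-seq).

## Embedding model

Three networks act on a sample vector x (p nonnegative peak scores):

* encoder `Q : x → z` — an MLP (default p → 1024 → d, leaky-ReLU, d = 200)
  producing a deterministic latent code;
* decoder `G : z → x'` — a single affine map. The decoder is deliberately
  *downgraded* to linear regression so that all nonlinear capacity sits in
  the encoder, whose output is the object of interest;
* discriminator `D : z → (0, 1)` — an MLP (d → 128 → 64 → 1, sigmoid)
  scoring whether a latent vector looks like a draw from the prior
  P(z) = N(0, I_d).

Losses (n = batch size):

    L_REC = (1/n) Σ_i ‖x_i − x'_i‖²
    L_D   = −E_{z'∼P(z)} log D(z') − E_{z∼Q} log(1 − D(z))
    L_G   = −E_{z∼Q} log D(z)
    L_GAN = L_D + L_G
    L_ALL = λ1·L_GAN + λ2·L_REC          (λ1 = λ2 = 1 by default)

At the equilibrium of the min–max game between Q and D, the pooled encoder
outputs are indistinguishable from the prior, so the code space the GMM
sees is bounded, roughly isotropic, and free of the scale pathologies raw
autoencoders produce.

### Training procedure

The three networks are updated **in turn** on every minibatch, each with
its own Adam optimizer:

1. discriminator step on λ1·L_D (prior draws are the positive class,
   encoder outputs — detached — the negative class);
2. reconstruction step on λ2·L_REC, updating encoder and decoder;
3. generator step on λ1·L_G, updating the encoder only.

Decoupling the moments matters: the raw reconstruction gradient scales
with the feature count (≫ the O(1) adversarial gradient), and a single
Adam step over the summed loss lets reconstruction swamp prior matching —
in experiments the discriminator then wins outright (D(prior) → 1) and the
latent distribution drifts arbitrarily far from N(0, I). With per-update
optimizers, Adam's per-parameter normalization puts the objectives on
the same footing. Since Adam is invariant to rescaling a loss by a
constant, λ1 and λ2 act as on/off switches and per-term gradients within
a step rather than as a relative weighting between steps; λ1 = 0 recovers
a plain (linear-decoder) autoencoder exactly.

### Stabilizing the game at cohort scale

A cohort is small (n in the hundreds) and the latent space is large
(d = 200), so any finite set of encoder outputs is linearly separable
from fresh prior draws — an unconstrained discriminator memorizes the
cohort and "wins" even when the pooled moments are reasonable, while a
strong generator mode-collapses the cloud onto whatever region D
currently accepts. Four standard or exact remedies keep the game honest
(all exposed in the configuration, all on by default):

* **instance noise** (σ = 0.5) added to every discriminator input, so D
  sees overlapping smoothed clouds rather than memorizable points;
* **one-sided label smoothing** (target 0.9 for prior draws), so D cannot
  saturate on the positive class;
* **output-layer whitening at initialization** (LSUV-style): the encoder's
  final layer is rescaled on a data batch so the initial codes have
  per-dimension mean 0 and variance 1. Nonnegative inputs otherwise give
  initial codes whose means sit many prior standard deviations from the
  origin — farther than lr-bounded Adam steps can travel back in any
  practical number of epochs;
* **latent moment calibration**: a pointwise discriminator cannot pin the
  first two moments of a small cohort, so they are matched to N(0, I)
  explicitly. The mean is recentred through the encoder output bias (an
  EMA of batch means, with a compensating decoder-bias shift so
  reconstructions are unchanged and the reconstruction updates have no
  gradient to undo the translation — a pure, geometry-preserving
  translation), and the variance penalty Σ_k (σ²_k − 1)² backpropagates
  with its exact gradient through a dedicated gentle optimizer
  (lr 2e-4). The translation component of the generator's latent
  gradient is projected out for the same reason: shifting the whole
  cloud along D's gradient is the generator's fastest move, and it
  would fight the mean calibration indefinitely.

Defaults: batch 32, Adam learning rates 1e-4 (D), 1e-3 (reconstruction),
1e-4 (generator), 2e-4 (variance calibration), 200 epochs max with early
stop when the epoch-mean L_REC changes by < 1e-5 (relative) across 10
epochs. Discriminator outputs are clamped to [1e-7, 1 − 1e-7] before
logs. Weights use He-scaled Gaussian initialization; everything
(initialization, batch order, prior and noise draws) derives from one
seeded generator, so runs are bit-reproducible. Training runs in single
precision; the exposed loss functions evaluate in double precision.
Non-finite losses abort with the epoch/batch location; a batch size
exceeding n is reduced with a warning.

The encoder hidden width (1024), discriminator widths (128, 64) and d=200
are configurable; d = 200 keeps enough room for cohort-scale cluster
geometry while staying small enough for diagonal-covariance GMMs at
n ≈ a few hundred.

## GMM clustering

The latent cohort H = {h_n} is modeled as p(h) = Σ_i π_i N(h | μ_i, Σ_i).
EM alternates responsibilities (E) and weighted parameter updates (M),
tracking the total log-likelihood each iteration; the fit stops when the
change drops below 1e-4 (absolute) or at 500 iterations, and the best of
10 restarts by final log-likelihood is kept. Restart r is seeded from
(seed, r). Initialization assigns one-hot responsibilities from
k-means++-seeded centers. Covariances are diagonal by default (full is
available for low-dimensional work): with d = 200 and a few hundred
samples, full ML covariances are singular. Every M step adds 1e-6 to the
variance diagonals, so the likelihood is bounded and EM monotonicity
holds to that floor. A component whose responsibility mass collapses is
reseeded at a random data point with the global diagonal covariance.
Hard labels are posterior argmax, ties to the lowest component index.

## Cluster-number selection

For each candidate K the GMM is fitted (seeded from (seed, K)) and the DB
index is computed on the hard labels *in the latent space*:

    DB = (1/K) Σ_i max_{j≠i} (S_i + S_j) / M_ij

with S_i the mean (q = 1) Euclidean distance of cluster-i points to their
centroid and M_ij the centroid distance. The selected K minimizes DB;
ties go to the smaller K. A K whose fitted solution leaves a component
empty is scored +inf and can never win. Coincident centroids with
nonzero scatter raise a degenerate-partition error rather than returning
an unbounded value. The default scan range is 2–30 (configurable; a
narrower dataset-specific range is often appropriate).

## Marker discovery

For each cluster, members are recoded one-vs-rest and a random forest
(default 1000 trees, Gini criterion, √p features per split, unlimited
depth, balanced class weights, seed = base_seed + cluster index) is
fitted on the full peak matrix. Features are ranked by normalized
mean-decrease-impurity (Gini importance, summing to 1 per forest); the
top 5 regions per cluster are reported with their annotation-linked
genes ("NA" when no link is annotated — gene linking is pass-through
from the supplied annotation, not a nearest-TSS computation).

## Evaluation

* **Survival**: K-sample log-rank test (chi-square, K−1 df; via
  lifelines) plus Kaplan-Meier curves per cluster. A permutation scheme
  (labels permuted R times, default 999) gives the empirical p-value
  p = (1 + #{perm ≥ observed}) / (1 + R) — the add-one estimator never
  returns 0.
* **Clinical enrichment**: per covariate, chi-square independence test for
  categorical (Fisher's exact for 2×2 tables with an expected count < 5),
  Kruskal-Wallis for continuous. p-values are raw and the summary is the
  count significant at α = 0.05 — a descriptive tally, so no multiplicity
  correction is applied. Constant covariates get p = 1 with a warning.
* **Partition comparison**: variation of information
  VI = H(A) + H(B) − 2 I(A;B) in nats (a true metric on partitions), and
  row-stochastic residence matrices (percent of cluster i of A inside
  cluster j of B).
* **Visualization**: Pearson-correlation similarity heatmap of the latent
  vectors and a seeded t-SNE map (perplexity 30 clamped to (N−1)/3,
  1000 iterations).

## Synthetic cohorts

The generator plants G latent clusters (balanced sizes, spherical unit
Gaussians around mutually orthogonal means with pairwise separation
`separation`), lifts them to p peaks through a fixed random linear map
followed by softplus (keeping scores nonnegative), adds Gaussian noise
(sd 0.5) before the softplus, elevates m marker peaks per cluster by
`marker_effect` for that cluster's members, and zeroes a `sparsity`
fraction of entries. Survival times are exponential with cluster-specific
hazards; censoring is independent Uniform(0, c) with c solved so the
expected censored fraction matches `censor_rate`. Clinical covariates mix
cluster-associated columns (categorical probability shift 0.8/0.2, or
continuous mean shift) with independent null columns.

Default study conditions: G = 6, n = 300, d_true = 10, p = 5000,
separation = 8, m = 20 markers per cluster with effect 2.0, sparsity 0.2,
hazards 0.004…0.0004 /day (median survival ≈ 170–1700 days), censoring
30%, 3 associated + 4 null covariates. The background lift scale is 0.2,
chosen so that a single background peak separates clusters far less than
a planted marker does (the markers are the most discriminative
*individual* features by construction) while the aggregate signal across
all p peaks remains strong for the embedding.

What the generator does *not* emulate: fragment-level counts, GC or
insert-size structure, peak-width variation, batch effects, correlated
peak blocks (co-accessibility), or non-exponential hazards. Passing tests
therefore show the machinery is correct on matrices with planted
low-dimensional structure, not that real tumor cohorts will yield equally
clean partitions.

## Problem sizes used in the automated checks

The test suite and the acceptance script run at desk scale: the standard
cohort above (n = 300, p = 5000), 60 training epochs in the acceptance
script and 35 epochs with a 512-unit hidden layer in the multi-seed
recovery check (well past the reconstruction plateau at this size; the
full 200-epoch, 1024-unit default with early stopping is exercised once
in the equilibrium check), GMM scans
over K = 2..10 with 5 restarts, and 300-tree forests for marker recovery
(1000 remains the library default). Marker-recovery checks use a
G = 4, n = 200, p = 1000 cohort. These sizes are stated so results are
interpretable, and all are plain keyword arguments.

## Known limitations

* Single-omics only; no integration of mutation/methylation/expression
  layers.
* The adversarial game is a stochastic equilibrium: discriminator
  calibration (D ≈ 0.5) is approximate and seed-dependent, and per-run
  latent geometry differs even when the induced partition is stable.
* Diagonal-covariance GMMs cannot represent strongly anisotropic
  clusters in the latent space.
* Gene linking is annotation pass-through; without an annotation, marker
  regions are reported with "NA" genes.
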