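# Methods

## The model

`vada` implements a deep generative model for longitudinal data: N
subjects, each observed at L common time points (or locations) on a
univariate outcome y_n = (y_n1, …, y_nL)' and P covariates
x_nl ∈ R^P.  The generative process for subject n is

1. c_n ~ Cat(π), a latent cluster label over K components;
2. for each measurement l: z_nl ~ N(μ_{c_n}, diag σ²_{c_n}) in a
   D-dimensional latent space; covariates x_nl are emitted by the
   X-decoder f_x(z_nl; θ) — a Gaussian head (mean and variance) per
   real-valued feature, a simplex head per categorical feature;
3. "pure outcomes" u_nl ~ N(β_{c_n,0} + z_nl'β_{c_n}, σ²_{u,c_n}) — a
   cluster-specific *linear marginal model* in the latent space,
   conditionally independent across l given the cluster;
4. the observed outcome vector y_n is emitted by the Y-decoder
   f_y(u_n; φ) applied to the *whole* vector u_n — Gaussian heads for a
   real outcome, one simplex per measurement for a categorical one.

Step 4 is what distinguishes the model from an independent-measurements
mixture: the Y-decoder mixes the conditionally independent pure
outcomes into mutually dependent observed outcomes, replacing the
"working correlation" assumption of GEE-based marginal modelling with a
learned map.

Inference is amortized variational Bayes with the mean-field family
q(u, Z, c | y, X) = q(u|y) q(Z|X) q(c|y, X), where q(u|y) and q(z_l|x_l)
are diagonal Gaussians produced by the Y-encoder g_u(y; λ) and X-encoder
g_z(x; γ), and q(c|y,X) is *derived*, not parameterized: the
responsibility function

    h(u, Z, k; H) = p(u|Z,k) p(Z|k) π_k / Σ_k' p(u|Z,k') p(Z|k') π_k'

is averaged over M reparameterized samples of (u, Z) to give
π̃_k ≈ q(c = k|y, X).  H = (π, μ, σ², β, σ²_u) collects the mixture and
marginal-model parameters.

### The objective

The ELBO decomposes into an outcome reconstruction term, a covariate
reconstruction term, and a KL divergence from the prior over (u, Z, c)
to the mean-field posterior.  Reconstructions are single-sample
Monte-Carlo estimates through the reparameterization trick (M = 1 during
training).  Given π̃, the KL term is evaluated in closed form as a
five-part expression (`vada.objective.kl_term`).  As written, that
expression equals the true divergence **plus the constant
(L + L·D)/2**; the per-dimension −½ constants are folded out.  The
offset is gradient-free, so training is unaffected; `kl_offset(L, D)`
exposes it, and the Monte-Carlo oracle tests subtract it before
comparing.  In the matched-unit-Gaussian identity case (K = 1, L = 4,
D = 10) the expression returns exactly 22.

For binary/categorical outcomes the Gaussian outcome reconstruction is
replaced by the negative cross-entropy of the per-measurement simplex
heads; the rest of the objective is unchanged.

### Clustering and prediction

Two rules are provided after fitting.  With outcomes observed
(*complete-data* rule) a subject is assigned to argmax_k π̃_k.  With
outcomes unobserved (*covariates-only* rule) the z-branch alone is used:
q(c = k|X) ≈ (1/M) Σ_m softmax_k[log p(Z^(m)|k) + log π_k].  Outcome
prediction composes: ẑ_nl = posterior mean of the X-encoder;
û^k_nl = β_{k,0} + ẑ_nl'β_k for every cluster k; ŷ^k = mean head of
f_y(û^k); final ŷ = Σ_k q(c = k|X) ŷ^k.  Argmax ties break to the
lowest cluster index.  Evaluation-time M defaults to 100 with a fixed
seed (the training default M = 1 is too noisy for stable reported
labels; the inference-time value is not specified by the reference
protocol).

## Training

Adam at learning rate 1e-3 on the negated ELBO, batches of 128 subjects
(the last partial batch is kept), 500 epochs, subjects reshuffled each
epoch, M = 1, no network pretraining.  All continuous variables are
re-scaled to zero mean and unit variance before training;
standardization statistics are computed on the training split only and
reused for held-out data (avoids leakage; at these sizes the effect on
reported numbers is negligible).  Splitting is by subject (4/1
train/test), so all L rows of a subject stay together.  Training is
bit-reproducible given the seed on fixed hardware; float32 is the
training precision (float64 available via `TrainConfig.dtype`, used by
the gradient-check tests).

Unconstrained parameterizations keep the invariants by construction: π
via softmax over logits, all variances via exponentiated logs.  Every
produced or evaluated variance is floored at 1e-6 (post-standardization
scale) to keep log-densities finite; mixture normalizations are done in
log space with max subtraction.  Gradients flow through π̃ into H — no
stop-gradient — matching the model family's convention.

### Mixture warm start

With a blind mixture initialization (uniform π, random component means,
unit variances) the latent mixture reliably degenerates: one wide
component captures the entire embedding cloud early, the others receive
vanishing responsibilities and die, and gradient descent cannot split a
merged component afterwards.  Empirically the encoder representations
separate the true clusters perfectly while the mixture stays collapsed —
the failure is purely in the mixture coordinates.  The trainer therefore
re-anchors the mixture once, at a fixed early epoch
(`TrainConfig.mixture_warmup`, default 50): k-means on the per-subject
average embeddings partitions the subjects; component means, variances
and weights are set from that partition, and the per-cluster marginal
models (β_{k,0}, β_k, σ²_{u,k}) are refit by closed-form least squares
of the Y-encoder means on the X-encoder means.  Network weights are
untouched — the networks are never pretrained — and `mixture_warmup=0`
disables the step entirely.  After the warm start, joint gradient
training continues on everything.

An optional multi-start guard (`TrainConfig.restarts`, default 1) races
several independently initialized runs over the first `race_epochs`
epochs and continues the one with the best training ELBO.  It is off by
default: the poor local optima described under *Known limitations* are
driven mostly by the dataset draw rather than the initialization, so
restarts buy little at roughly double the cost.

## Architectures

The reference network configurations are not public; the defaults here
are deliberately small dense nets: X-encoder/X-decoder one hidden layer
of 64 tanh units, Y-encoder/Y-decoder one hidden layer of 16 tanh units
(ReLU available), Glorot-uniform initialization, variance heads emitting
log-variance.
All heads of a network are computed by a single affine map from the last
hidden layer and split afterwards.  Everything is configurable through
`ArchitectureConfig`.  Because the true configurations are unknown,
numeric agreement with the published tables is approximate by
construction.

## Synthetic scenarios

Four generators produce benchmark datasets with ground-truth labels
(defaults N = 2500 subjects, L = 4, P = 100, K = 3 clusters, D_true = 10).
The two-digit code says whether covariates come from a nonlinear decoder
of latent codes (first digit 1) or directly from a Gaussian mixture in
feature space (first digit 0), and whether outcomes are coupled across
measurements by a nonlinear Y-decoder (second digit 1) or conditionally
independent (second digit 0).  Exact published generator parameters are
not available; the documented defaults are:

- cluster means at distance 6 from the origin along random orthogonal
  directions (latent space for scenarios 11/01; an informative block of
  D_true feature coordinates for 10/00), unit component variances,
  uniform cluster weights;
- marginal-effect vectors β*_k with i.i.d. standard-normal entries acting
  on the latent codes (11/10) or the informative coordinates (00);
- generating decoder maps are frozen random one-hidden-layer tanh nets
  (64 units on the covariate side, 16 on the outcome side) — never the
  fitted model's nets;
- every emitted signal (covariate columns, pure outcomes, outcomes) is
  standardized to unit variance *before* its noise is added, and all
  noise standard deviations are 0.2, so noise levels are directly
  interpretable and the regime matches the published tables
  qualitatively: near-perfect cluster recoverability with small
  irreducible prediction error.

Scenario 01's per-cluster nonlinearity sits in the z→y map (one
one-hidden-layer tanh net per cluster applied to each z_l
independently); the outcome coupling of scenarios 11/10 sits in u→y.
For scenario 00 the per-cluster regression acts on the informative
coordinates (the nuisance coordinates carry no outcome signal), keeping
the outcome representable by a D = D_true latent code.

Note an implication of the noise placement: in scenarios 11 and 10 the
pure-outcome noise (sd 0.2) passes through the Y-decoder, so the
irreducible error for predicting y from X exceeds the outcome noise
alone.  For scenario 11 at the defaults the total floor is ≈ 0.076 on
the standardized scale (measured by paired noise-free regeneration),
against ≈ 0.039 from outcome noise only.  Reported MSE values should be
read against that floor.

What the generators do *not* emulate: missing data, unequal measurement
lengths, categorical covariates (exercised by unit fixtures instead),
covariate–outcome confounding beyond the latent path, and any real-data
deviation from the assumed generative family.  Passing tests therefore
demonstrate internal correctness and recoverability under the stated
conditions, not performance on real cohorts.

## Baselines

- **VaDE+MM** — mixture-prior auto-encoder on the N·L observation rows
  (same X-network architecture), observation batches of 128·L = 512;
  its embeddings and cluster probabilities feed the marginal models.
- **VAE+GMM+MM** — standard-normal-prior auto-encoder; a full-covariance
  Gaussian mixture model on its embeddings provides clustering.
- **GMM+MM** — Gaussian mixture model directly on the standardized
  features.

Per-observation cluster probabilities are merged within subject by
summing over the L rows and taking the argmax.  Embeddings (or raw
features) are projected to principal components before the marginal
models — components are kept up to 99.99% cumulative variance and
components with eigenvalue below 1e-8 are dropped (rank-deficiency
guard).  One marginal model per cluster is fitted by generalized
estimating equations (statsmodels) under independence (MM0), AR(1)
(MM1) or exchangeable (MM2) working correlation, identity link for real
outcomes, logit for binary; at L = 2 the AR(1) and exchangeable
structures coincide up to the solver's moment-estimator tolerance.
Hard cluster assignment feeds the GEEs, and test subjects are predicted
by their merged hard label's cluster model; subjects landing in a
cluster that was empty at fit time fall back to their best fitted
cluster.  The VaDE/VAE KL terms use the exact-divergence convention
(zero for a matched standard normal), so a single-component VaDE and a
learned-prior VAE have identical objectives term by term.

## Evaluation

MSE on the standardized outcome scale over all N·L held-out entries;
adjusted Rand index between subject-level labels (pair-counting
contingency formula — label-switching-proof and defined for unequal
class counts); classification error rate for categorical outcomes.
`run_experiment` drives (scenario × method × D × K) grids with
replicate datasets; replicate r of any cell uses seed base+r end to end,
so any single cell can be reproduced in isolation.  Replicates default
to 3 (the published protocol uses 30) to stay desk-scale; the problem
sizes used by the acceptance script are the generator defaults
(N = 2500, 500 epochs, 3 replicates).

## Numerical choices and edge cases

- Variance floor 1e-6 everywhere a variance is produced or consumed;
  probability floors at 1e-30 inside logs (float32-safe).
- Log-space mixture normalization with max subtraction (responsibility
  and cluster-probability computations are invariant to a common
  rescaling of component densities).
- Argmax ties break to the lowest index; k-means in the warm start uses
  the training seed.
- Constant covariate columns are centered but not scaled.
- Empty generation requests (n = 0) return an empty dataset; empty
  clusters are dropped from GEE fitting with a warning.
- Training aborts on a non-finite loss with the last finite epoch's
  parameters attached to the raised error.

## Known limitations

- Equal-length, fully observed trajectories only.
- The latent pure-outcome scale is identified only through the linear
  marginal model; the Y-branch can settle on a warped pure-outcome
  parameterization (a local optimum in which σ²_u absorbs the warp),
  which inflates prediction error in the decoder-coupled scenarios
  while leaving clustering untouched; longer training does not remove
  it.
- Univariate outcomes; no missing-data mechanism; no loss-term
  weighting.
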