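# Methods

## Problem setting

Given a cohort with right-censored overall survival (time T, event indicator
E), bulk gene-expression and miRNA-expression matrices, clinical covariates
(age, stage, race), and pathway membership (GMT), the pipeline predicts a
per-patient prognostic index (PI, the estimated log relative hazard),
stratifies patients into high/low risk at the tuning-set median PI, and
attributes the predicted risk difference back to individual inputs.

## Preprocessing

- **Splits.** 20% of patients form an external test set; the remaining 80%
  (the *tuning set*) is divided 10 times into 80/20 train/validation parts
  (64%/16% of the whole cohort). Splits are stratified by the event indicator
  so deaths appear in every part; stratification is recorded in the split
  plan and can be disabled. All splits are deterministic functions of the
  master seed.
- **Normalization.** Each feature is min-max rescaled to [0, 1]. The default
  mode normalizes each split independently (test-set minima/maxima come from
  test-set data), which matches the protocol the architecture was designed
  under; a `tuning-stats` mode instead freezes tuning-set statistics and
  clips transformed values into [0, 1], for leakage-safe deployment.
  A feature constant within a split maps to 0 — such features carry no
  information and are removed by the variance filter anyway.
- **Variance filter.** Features with unbiased sample variance < 0.02 on the
  normalized tuning set are dropped; the retained feature list is frozen and
  reapplied unchanged to every other split.
- **Pathway mask.** GMT membership is intersected with the measured gene
  universe first; pathways with fewer than 15 or more than 300 in-universe
  member genes are dropped (boundaries inclusive: sizes 15 and 300 are
  kept), then genes in no surviving pathway are dropped. Gene and pathway
  orderings are lexicographic so the binary mask is reproducible. One mask
  object serves both the encoder and (transposed) the decoder.
- **Clinical encoding.** Numeric covariates pass through (standardization
  optional, on by default in the pipeline); categorical covariates are
  one-hot encoded against a declared reference level (default: first sorted
  observed level). Missing values fail fast by default; an opt-in mode adds
  an explicit missing-indicator level, which is never chosen as the implicit
  reference.

## Pathway-masked VAE

Architecture (entangle mode): gene layer → pathway layer (mask-constrained
affine, batchnorm, ReLU); the pathway activations are concatenated with the
miRNA layer (by default directly — an optional hidden miRNA branch is
configurable, since the original description leaves this open) → trunk dense
layer (default width 256; the synthetic-cohort pipeline uses 64, matched to
its input dimensionality) with batchnorm + ReLU → linear heads for μ and
log σ². The decoder mirrors this: trunk from z, a gene head whose final map
is the transposed mask, a direct miRNA head, sigmoid outputs. Batchnorm is
applied everywhere except the latent bottleneck; activation placement (ReLU
on hidden layers, linear bottleneck heads, sigmoid outputs) is a recorded
configuration choice. Single-omics variants drop the unused branch; the
`concatenate` integration trains two single-omics VAEs and concatenates
their latent means.

**Loss.** Binary cross-entropy on the min-max-scaled targets, *summed over
features and averaged over the batch* — this reduction keeps the meaning of
β independent of batch size and is configurable in principle; reconstruction
targets at exact 0/1 are clamped to [1e−7, 1−1e−7]. The KL term is the
closed form ½ Σ_d (μ_d² + σ_d² − log σ_d² − 1) per sample, averaged over the
batch. L2 regularization (λ₁) covers dense weights only, not biases or
batchnorm scale/shift. During training the BCE is computed from logits
(softplus(a) − x·a) for numerical stability; the public loss function
computes the identical quantity from clamped reconstructions.

**Masking.** Masked weight positions are zeroed at initialization and their
gradients are zeroed on every backward pass; since Adam's moment estimates
then stay zero and the L2 gradient is proportional to the (zero) weight,
masked positions remain *exactly* zero through any number of steps — this is
asserted, not assumed, in the tests.

**Optimization.** Adam (full hand-derived backprop, verified against central
finite differences at 1e−4 relative tolerance), mini-batches of 128, 120
epochs by default for the synthetic cohort. β follows the cyclic annealing
schedule below and is updated per epoch, so each epoch optimizes a fixed
objective.

## KL annealing schedule

Training is divided into `n_cycles` cycles of equal length (integer
division; the last cycle absorbs the remainder). Within a cycle of length L,
β rises linearly from 0 over the first `ramp = min(ceil(cutting_ratio·L),
L−1)` steps (β(pos) = pos/ramp) and is held at 1 for the rest of the cycle.
The cap at L−1 resolves an edge case: with cutting_ratio = 1 an uncapped
ramp would end one step short of 1, whereas the schedule's contract is that
every cycle attains the full VAE objective. A cosine ramp is available as
configuration. Defaults: 3 cycles, cutting ratio 0.5.

## Survival network

Input [μ ‖ clinical] → one tanh hidden layer (default width 16, dropout 0.2
on the hidden layer only, no batchnorm) → bias-free linear output PI. A
constant shift of PI cancels inside the partial likelihood, so an output
bias would be unidentifiable — hence none is used. The loss is the average
negative log partial likelihood over events with Breslow-style risk sets
{j : T_j ≥ T_i} (patient i included; censored patients tied at T_i
included; no Efron tie correction — ties are rare at day resolution), plus
λ₂ on weights only. Risk sets are global, so training is full-batch; the
log-sum-exp is computed stably. Zero observed events is an explicit error.

## Evaluation

- **C-index** (Harrell): pairs (i, j) with T_i < T_j and E_i = 1 are
  comparable, as are pairs tied in time with exactly one event (the death
  precedes the censored patient's unobserved failure); concordance requires
  PI_i > PI_j, PI ties earn 0.5. Verified against an O(n²) pair-enumeration
  oracle and scikit-survival.
- **Risk groups**: high iff PI strictly exceeds the tuning-set median PI
  (even-n median = midpoint of the central order statistics).
- **Kaplan-Meier / log-rank** via lifelines; the 95% band is the Greenwood
  variance on the log(−log) scale (lifelines' exponential Greenwood band).

## Model selection and comparison

Grid search follows the repeated-division protocol: for each of the 10
train/valid divisions, every grid point is trained on the train part and
scored on the validation part (lowest reconstruction loss for the VAE,
highest C-index for the survival network); each division's best point —
ties broken by declared grid order — is refit on the whole tuning set and
scored on the external test set, giving 10 test metrics reported as
mean ± sd. Failed grid points are warned about and excluded per division.
Paired test metrics from two models are compared with a one-tailed Wilcoxon
signed-rank test: zeros dropped, exact null distribution for ≤ 25 nonzero
pairs, normal approximation with continuity correction above; all-zero
differences return p = 1 with a warning.

## Attribution

Evaluation-state networks are folded into chains of affine maps (batchnorm
running statistics folded into the adjacent dense layer — exact in
evaluation mode and asserted against the eval forward pass) and elementwise
nonlinearities. For one explained sample and one reference, multipliers
propagate from the explained output through affine maps as m·Wᵀ and through
nonlinearities by the rescale rule — each unit scales by
(f(a_x) − f(a_r))/(a_x − a_r), falling back to f′(a_x) when |Δa| < 1e−7.
The contribution of input k is m_k (x_k − r_k), which satisfies
summation-to-delta exactly for this rule; the per-(sample, reference)
identity survives averaging as Σ_k C_k = f(x) − mean_r f(r), checked at
1e−4 relative tolerance.

Contributions are computed *per reference and averaged* (the Shapley-value
reading of DeepSHAP), not against an averaged reference. The reference
cohort is the predicted low-risk half of the tuning set; up to 100 explained
and 100 reference samples are drawn with a recorded seed (all members are
used without replacement when a group is smaller). Overall contribution =
mean |contribution| over explained samples — absolute values so opposite
signs cannot cancel; signed per-sample contributions are retained in the
result object for sign-aware analyses. Percent contribution = overall /
Σ overall × 100.

KIF/KPF identification: attribution is run for the top 6 latent features by
overall contribution to PI; a gene/miRNA (or pathway node) counts once per
latent feature whose top-10 contributor list contains it, and is *key* when
its frequency is ≥ 2. Ties at the rank-10 boundary are broken
lexicographically and flagged in the report.

## Synthetic cohorts

The generator emulates the structure the pipeline assumes, not any real
cohort's marginals: K latent factors h ~ N(0, I) per patient; each pathway's
member genes share positive loadings (uniform in [0.5, 1]) on the pathway's
assigned factor, so GMT structure is real in the expression covariance;
gene expression = softplus(loadings·h + noise), keeping values nonnegative
and smooth with noise_sd 0.3 by default. miRNAs load only on the first
⌈shared_fraction·K⌉ factors (default half of K = 8), creating the
gene-miRNA information overlap that motivates joint encoding. Clinical
covariates: age ~ N(60, 10²), stage and race categorical. Survival is
exponential (Weibull shape configurable for stress tests) with log-hazard
0.8·(h₀+h₁+h₂) + 1.5·(age−60)/10 + 0.3·stage_iii + 0.6·stage_iv over a
baseline hazard of 1e−3/day; the age weight exceeds the combined factor
magnitude √3·0.8, making the clinical covariate dominant by construction —
no single latent combination of the factors can out-contribute it.
Censoring is an independent exponential whose rate is calibrated by
bisection (≤ 50 iterations, log-spaced) to hit the target censored fraction
(default 40%) within ±0.01. The truth record stores factors, loadings,
hazard weights, and true times for recovery tests.

What passing tests on these cohorts do **not** show: robustness to heavy-
tailed expression marginals, batch effects, missingness, non-proportional
hazards, or pathway annotations that are wrong — none of which the
generator produces.

## Problem sizes and numerical choices

The default synthetic study uses 500 patients (400 tuning / 100 test), 200
genes in 20 pathways of 15–25 genes, 50 miRNAs, 16 latent features, trunk
width 64, 120 VAE epochs and 400 survival-network epochs — sizes chosen so
a full entangle run completes in seconds on one CPU while leaving the
planted signal clearly recoverable (test C-index ≈ 0.82 against 0.83 for
the true log-hazard). Tie-breaks (grid order, lexicographic factor order),
clamps (BCE targets, log-variance inside exp), and degenerate-input
behaviors (constant features, zero events, empty pathway filters) are fixed
and tested rather than left to float behavior.

## Known limitations

- Mini-batch Cox training is not offered; cohorts must fit in memory for
  the full-batch partial likelihood (fine up to tens of thousands here).
- The rescale rule is the only attribution nonlinearity rule implemented
  (no RevealCancel).
- Joint (end-to-end) training of encoder and survival network is out of
  scope; the two stages are trained sequentially.
- Attribution explains μ means, not the posterior variances.
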