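# autosurv

Interpretable deep-learning survival analysis for multi-omics cancer cohorts:
a pathway-masked variational autoencoder (VAE) compresses gene and miRNA
expression into a small set of latent features, a Cox partial-likelihood
network turns those features plus clinical covariates into a per-patient
prognostic index, and DeepSHAP attribution explains which genes, miRNAs,
pathways, and clinical variables drive the predicted risk difference between
high- and low-risk patients.

The package is aimed at methodologists and computational biologists who want
a fully tested, numpy-based reference implementation of this architecture,
exercised end to end on synthetic cohorts with planted signal so that every
stage — feature extraction, risk prediction, attribution — can be validated
against ground truth.

## The model

**Pathway-masked VAE.** Gene expression `x_gene` feeds a *pathway layer*
through a sparse affine map: the weight from gene *g* to pathway node *p* is
constrained to zero unless *g* belongs to *p* (membership comes from a GMT
file; pathways with fewer than 15 or more than 300 in-universe member genes
are dropped). Pathway activations are concatenated with the miRNA layer and
propagated to the means μ and log-variances log σ² of a Gaussian posterior
q(z|x). The decoder reconstructs both omics blocks from ẑ = μ + σ·ε, the gene
head ending in the transposed mask. The loss is

    L = BCE(x_gene, x̂_gene) + BCE(x_miRNA, x̂_miRNA)
        + β·KL( N(μ, σ²) ‖ N(0, I) ) + λ₁‖θ₁‖²

with β following a cyclic annealing schedule (linear 0→1 ramp over the first
`cutting_ratio` of each cycle, then held at 1) to prevent posterior collapse.

**Survival network.** The latent means μ concatenated with encoded clinical
covariates pass through one tanh hidden layer to a bias-free linear output,
the prognostic index PI (an estimate of the log relative hazard). Training
minimizes the average negative log Cox partial likelihood

    l = −(1/n_E) Σ_{i: E_i=1} [ PI_i − log Σ_{j: T_j ≥ T_i} e^{PI_j} ] + λ₂‖θ₂‖²

**Attribution.** DeepSHAP (DeepLIFT with the rescale rule, averaged over a
reference cohort) assigns each input a contribution C that satisfies
summation-to-delta: contributions sum exactly to the output difference from
the reference. Patients below the tuning-set median PI serve as the low-risk
reference; a feature's *overall contribution* is its mean absolute
contribution over the explained high-risk samples, and *percent contribution*
normalizes these to 100%. Genes/miRNAs (or pathway nodes) appearing in the
top-10 contributor list of more than one of the top latent features are
flagged as Key Input Factors (KIFs) / Key Pathway Factors (KPFs).

## Worked example

The default configuration simulates a 500-patient cohort (200 genes in 20
pathways, 50 miRNAs, age/stage/race covariates, 40% censoring) in which
latent factors drive pathway-structured co-expression and the hazard loads on
three shared factors plus the clinical covariates, age dominant:

```python
from autosurv.pipeline import run_pipeline

manifest = run_pipeline({"seed": 0}, "runs/demo")
print(manifest["stages"]["evaluate"])
```

prints (400 tuning / 100 test patients, 16 latent features):

```
{'c_index_test': 0.8209121245828699,
 'pi_med_tuning': -0.8687020405147043,
 'n_high': 65, 'n_low': 35,
 'logrank_statistic': 43.26952930764346,
 'logrank_p': 4.76953421503038e-11}
```

The held-out concordance index 0.82 approaches the 0.83 achievable from the
true simulated log-hazard, and the median-PI risk split separates the test
Kaplan-Meier curves decisively (log-rank χ² = 43.3). The attribution table
`runs/demo/interpret/pi_contributions.csv` begins

```
feature,overall_contribution,percent_contribution
age,2.1636,32.28
mu_15,1.2443,18.56
mu_6,0.7713,11.51
```

— the planted dominant clinical covariate (age) tops the ranking, with the
survival-relevant latent features next, mirroring the qualitative pattern
reported for real tumor cohorts. KIF/KPF reports and per-latent contribution
matrices are written alongside.

The same pipeline is scriptable stage by stage:

```bash
autosurv simulate   --run-dir runs/demo
autosurv preprocess --run-dir runs/demo
autosurv train-vae  --run-dir runs/demo
autosurv train-surv --run-dir runs/demo
autosurv evaluate   --run-dir runs/demo
autosurv interpret  --run-dir runs/demo
autosurv tune       --run-dir runs/demo   # grid search over the 10 divisions
```

Cases `entangle` (default), `gene_only`, `mirna_only`, `concatenate`, and
`clinical_only` select how the omics blocks are integrated (`--case ...`).

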