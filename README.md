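# vada — generative auto-encoding analysis of longitudinal data

Longitudinal studies observe the same N subjects at L common time
points on an outcome and P covariates; the within-subject correlation
of the repeated measurements is what makes these data hard.  The
classical marginal-model approach fits population-averaged effects by
generalized estimating equations (GEE) under a "working" correlation
assumption, handles only linear effects, and struggles with
high-dimensional covariates.

`vada` implements a deep generative alternative: a variational
auto-encoding model whose latent space couples three ingredients,

* a **Gaussian-mixture prior** over per-measurement latent codes
  z_nl ∈ R^D — subjects belong to one of K latent clusters c_n ~ Cat(π),
  z_nl ~ N(μ_c, diag σ²_c);
* **cluster-specific linear marginal models** on latent "pure outcomes"
  u_nl ~ N(β_{c,0} + z_nl'β_c, σ²_{u,c}), conditionally independent
  across measurements given the cluster;
* a **Y-decoder** f_y that maps the whole vector u_n = (u_n1 … u_nL)'
  to the distribution of the observed outcomes y_n, inducing
  within-subject dependence without any working-correlation assumption
  (covariates are generated from z_nl by an X-decoder f_x).

Fitting is amortized variational inference (SGVB with the
reparameterization trick) with a mean-field family
q(u|y) q(Z|X) q(c|y,X), where the cluster posterior is derived from the
responsibility function h(u, Z, c; H) rather than parameterized.  One
fit yields jointly: outcome prediction for new subjects, two subject
clustering rules (with and without observed outcomes), low-dimensional
representations, and out-of-sample generation.

The package also ships the comparison stack (VaDE+MM, VAE+GMM+MM,
GMM+MM with MM0/MM1/MM2 working correlations), four synthetic benchmark
scenario generators with ground-truth labels, and MSE/ARI evaluation
over replicated experiment grids.  No external data are required.

There is no deep-learning framework dependency: the networks are small
dense nets trained through a self-contained reverse-mode autodiff
engine on numpy (`vada.autodiff`).

## Worked example

```python
import numpy as np
from vada import (ScenarioConfig, generate_scenario, TrainConfig,
                  split, standardize, train, predict_outcomes,
                  cluster_yx, mse, ari)

# scenario "00": covariates from a Gaussian mixture in feature space,
# outcomes linear in the informative coordinates per cluster
data, truth = generate_scenario(ScenarioConfig(code="00", seed=1))
train_set, test_set = split(data, 0.8, seed=1)          # 2000 / 500 subjects
train_std, stats = standardize(train_set)
test_std, _ = standardize(test_set, stats)

nets, params, history = train(train_std, TrainConfig(D=10, K=3, seed=1))

pred = predict_outcomes(nets, params, test_std.X, seed=1)
labels_yx, _ = cluster_yx(nets, params, test_std, seed=1)
print(f"test MSE (standardized): {mse(test_std.y, pred.y_hat):.3f}")
print(f"ARI, complete-data rule: {ari(test_std.c_true, labels_yx):.3f}")
print(f"ARI, covariates only:    {ari(test_std.c_true, pred.labels_x):.3f}")
```

Output (about four minutes on one CPU):

```
test MSE (standardized): 0.060
ARI, complete-data rule: 1.000
ARI, covariates only:    1.000
```

The MSE is measured on the standardized outcome scale, where the
generator's irreducible noise floor is ≈ 0.038; both clustering rules
recover the three generating clusters exactly on the 500 held-out
subjects.

The same workflow is available from the shell:

```bash
vada simulate --scenario 00 --n 2500 --seed 1 --out data.tsv --truth-out truth.tsv
vada train --data data.tsv --dim-d 10 --clusters 3 --seed 1 --out model.npz
vada predict --ckpt model.npz --data data.tsv --out predictions.tsv
vada cluster --ckpt model.npz --data data.tsv --rule yx --out clusters.tsv
vada baseline --method gmm-mm --working mm2 --data data.tsv --clusters 3 --out base.tsv
vada reproduce --table 1 --replicates 3 --seed 1 --out results/
```

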