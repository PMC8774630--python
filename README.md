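# csde — sparse mixture density estimation under measurement error

`csde` estimates an unknown univariate density as a **sparse, non-negative
mixture of known base densities** when the sample is contaminated by
measurement error.  It is aimed at settings common in biostatistics and
environmental statistics — multi-modal distributions (cell subpopulations,
counts with overdispersion, wind directions) modelled over a large
dictionary of candidate components, of which only a few are truly present.

## The estimator

Write the target density as h(z) = Σ_{j=1}^W β*_j h_j(z) with known
components {h_j} (Gaussian, Poisson, negative binomial or custom), weights
on the simplex, and possibly W ≫ n.  Instead of clean draws Z ~ h we
observe X = Z + ε.  With the empirical moments b_j = (1/n) Σ_i h_j(X_i) and
the Gram matrix Ψ_ij = ⟨h_i, h_j⟩, the corrected sparse density estimator
solves

    β̂ = argmin_{β ≥ 0}  −2 bᵀβ + βᵀΨβ + 2 Σ_j ω_j |β_j| + c Σ_j β_j² ,

a weighted Elastic-net on the empirical L2 distance: the per-component
weights ω_j = 2√2 L_j v(δ/2) + cB come from a bounded-differences
concentration inequality (L_j = ‖h_j‖_∞, v(δ) = √(log(W/δ)/n)) and the
ridge level c corrects for the error contamination.  Setting c = 0 and the
weights uniform recovers the Lasso / plain Elastic-net baselines; the
un-shifted scheme ω_j = 4 L_j λ1 gives the earlier weighted-l1-only sparse
density aggregation estimator.  The solver is cyclic coordinate descent
with exact first-order (KKT) verification; (λ1, c) can be tuned by
random-dichotomy cross-validation; an EM baseline for fixed-component
mixture weights is included.  See `docs/methods.md` for the full account.

## Worked example

Estimate the weights of a 7-component Gaussian mixture from 50 draws
(true weights: 0.1, 0.8, 0.1 on components 1, 4, 7):

```python
import numpy as np
from csde import SparseDensityModel, lowdim_scenarios

scen = lowdim_scenarios()[1]                      # W=7 study scenario
x = scen.sample(50, np.random.default_rng(7))     # observed sample
res = SparseDensityModel(x, scen.dict_true).fit(lam1=0.01, c=0.0)
print(res.summary())
```

```
Sparse mixture density fit
============================================
method:            csde
observations:      50
dictionary:        gaussian, W = 7
active components: 3
sum of weights:    0.955596
penalty:           lam1 = 0.01, c = 0
objective:         -1.882949
max KKT residual:  4.163e-17
sweeps:            2 (converged: True)
--------------------------------------------
active components (component, parameter, weight):
     1  a=0, sigma=0.3               0.1151
     4  a=3, sigma=0.1               0.8141
     7  a=6, sigma=0.3               0.0263
```

The fit recovers exactly the three true components; the weight estimates
(0.115, 0.814, 0.026) carry a coefficient l1 error of 0.103 against the
truth, and the near-zero KKT residual certifies the optimum.  `res.density(x)`
evaluates the fitted mixture, `res.diagnostics()` reports dictionary
coherence and the minimal Gram eigenvalue, and
`SparseDensityModel.fit_em` / `fit_cv` run the EM baseline and the
cross-validated fit.

A command-line interface mirrors the library:

```sh
csde fit --data samples.csv --dict examples/lowdim_scenario2_dict.yaml \
         --lam1 0.01 --mode csde
csde simulate --scenario gaussian_w81 --estimators lasso,csde --n-reps 20
```

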