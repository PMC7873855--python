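# srforest

Honest survival random forests for **heterogeneous restricted mean survival
time** (hRMST) with pointwise confidence intervals.

## The problem

For a survival time `T`, right-censored at `C` and observed as
`Z = min(T, C)` with event indicator `δ = 1{T ≤ C}`, the restricted mean
survival time at a clinically chosen horizon `L`,

```
μᴸ(x) = E[T ∧ L | X = x] = ∫₀ᴸ S(u | x) du ,
```

is an interpretable alternative to hazard ratios: the expected years (or
days) lived up to `L` for a patient with covariates `x`.  Existing
regression approaches either go through a proportional-hazards fit and
integrate the implied survival curve, or posit a parametric link
`g[μᴸ(x)] = β'x` solved by an inverse-probability-of-censoring-weighted
(IPCW) estimating equation.  Both are biased when their functional form is
wrong.

`srforest` estimates μᴸ(x) non-parametrically.  Each subject carries the
IPCW weight `ŵᵢ = δᵢᴸ / (1 − Ĝ(Zᵢᴸ | Xᵢ))`, with the censoring
distribution `G` fitted by a Cox model (Breslow baseline).  Honest trees —
split structure chosen on one subsample, leaves populated by a disjoint
one — are grown on estimating-equation pseudo-outcomes

```
ρᵢ = ŵᵢ (Zᵢᴸ − μ̂ₚ) / (Σ_{j∈P} ŵⱼ / |P|)
```

and the forest's adaptive neighborhood weights `αᵢ(x)` solve the local
estimating equation in closed form:

```
μ̂ᴸ(x) = Σᵢ αᵢ(x) ŵᵢ Zᵢᴸ / Σᵢ αᵢ(x) ŵᵢ .
```

Because trees are grown in small groups sharing a random half of the data,
the between-group spread of the per-tree estimating-function averages
yields a half-sampling ("little bags") estimate of `Var(μ̂ᴸ(x))` and
asymptotically valid normal confidence intervals.

## Worked example

```python
import numpy as np
from srforest import (SimulationConfig, ForestConfig, generate, fit_forest,
                      predict_with_interval, true_rmst)

cfg = SimulationConfig(model=1, link="identity", p=2, n=5000, L=5.4, seed=1)
train = generate(cfg)                      # ~66% uncensored
forest = fit_forest(train.restricted(),
                    ForestConfig(num_trees=500, seed=1))
Xq = np.array([[0.0, 0.0], [0.8, -0.5], [-0.6, 0.4]])
mu, sigma, lo, hi, _ = predict_with_interval(forest, Xq)
for i in range(3):
    print(f"x = {Xq[i]}  mu_hat = {mu[i]:.3f}  "
          f"95% CI = ({lo[i]:.3f}, {hi[i]:.3f})  true mu = {true_rmst(cfg, Xq)[i]:.3f}")
```

prints

```
x = [0. 0.]  mu_hat = 5.006  95% CI = (4.925, 5.087)  true mu = 4.999
x = [ 0.8 -0.5]  mu_hat = 5.046  95% CI = (4.983, 5.110)  true mu = 5.072
x = [-0.6  0.4]  mu_hat = 4.952  95% CI = (4.918, 4.986)  true mu = 4.950
```

`mu_hat` is the estimated restricted mean survival to `L = 5.4` time units
for a subject with those covariates; each 95% interval here covers the
closed-form truth of the generating model.

## Command line

```
srf simulate --model 2 --n 3000 --p 5 --seed 1 --out train.csv
srf fit      --input train.csv -L 5.3 --num-trees 500 --out forest.json
srf predict  --forest forest.json --input query.csv --out pred.csv
srf benchmark --config cell.json --seed 1 --out table.csv
srf coverage  --config cell.json --reps 5 --out coverage.json
```

CSV inputs need `time` and `event` (0/1) columns; every other numeric
column is a covariate.  `predict` writes `mu_hat`, `sigma_hat`, `ci_low`,
`ci_high` and a `variance_floored` flag.  Every command writes a JSON
sidecar with the resolved configuration and seed.

## Comparison estimators

`srf benchmark` scores seven estimators on one simulated design cell with
IPCW-weighted MAE/RMSE: the forest (`SRF`), Kaplan–Meier and Cox
plug-ins (`Naive.km`, `Naive.Cox`), and the identity/exp-link weighted
estimating-equation regressions with KM (`Lu.id`, `Lu.exp`) or
Cox-modeled (`Wang.id`, `Wang.exp`) censoring.

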