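# settlehealth

Composite health-index construction and interpretable machine-learning
analysis of settlement-environment panels.

Public-health and urban-studies researchers increasingly ask how the human
settlement environment (HSE) — ecology, living conditions, infrastructure,
public services, sustainability — relates to the *overall* health level of a
population at macro scale, where the relationship is nonlinear, has
thresholds, and mixes many interacting factors. `settlehealth` implements
that analysis for balanced province-year panels:

1. **Health Level Index (HLI).** Four health indicators (incidence and
   mortality of class A/B notifiable infectious diseases, human mortality,
   average life expectancy) are combined by entropy-weighted TOPSIS into a
   single score in [0, 1]: direction-aware min–max normalisation, weights
   w_j ∝ 1 − e_j from each indicator's Shannon entropy e_j, and closeness
   HLI_i = D_i⁻/(D_i⁺ + D_i⁻) to the ideal/anti-ideal points of the
   weighted matrix.
2. **Benchmark.** Six regressor families (XGBoost, GBDT, AdaBoost,
   LightGBM, random forest, L1-linear baseline) fitted on the identical
   80/20 split (seed 2025), scored by self-computed R², RMSE, MAE and
   5-fold CV; the primary boosted model pins the reproduction preset
   (learning rate 0.05, 200 trees, depth 3).
3. **Attribution.** Per-observation additive (Shapley) decompositions
   ŷ = φ₀ + Σ_j φ_j with the additivity identity validated row-wise;
   importance = mean |φ| shares.
4. **Thresholds.** LOWESS (span 0.3, locally linear, tricube) smoothing of
   attribution scatters; a threshold is where the smoothed curve crosses
   zero (the association changes sign), with bootstrap percentile 95%
   confidence intervals and plateau detection.
5. **Interactions.** One- and two-feature partial-dependence surfaces over
   quantile grids.

A seeded synthetic-panel generator with planted piecewise/plateau effects
makes every stage testable without external data; see `docs/methods.md` for
the models, defaults and their rationale.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from settlehealth import (SyntheticSpec, generate_health_indicators, build_hli,
                          run_benchmark, compute_attributions, importance_shares,
                          attribution_scatter, bootstrap_threshold,
                          DEFAULT_FEATURE_RANGES)

panel = generate_health_indicators(SyntheticSpec(seed=0))   # 341 rows
panel, report = build_hli(panel)
print(round(spearmanr(panel.latent_index, panel.HLI).statistic, 4))

features = list(DEFAULT_FEATURE_RANGES)
table, models, _ = run_benchmark(panel, features)
print(table[["model", "r2_train", "r2_test", "rmse_test"]]
      .round(3).to_string(index=False))

A = compute_attributions(models["xgboost"], panel[features])
print(importance_shares(A).head(6).round(2).to_string(index=False))

pairs = attribution_scatter(A, "UR")
est = bootstrap_threshold(pairs["x"].to_numpy(), pairs["phi"].to_numpy(),
                          span=0.3, n_boot=500, seed=0,
                          near=float(np.median(pairs["x"])))
print(round(est.point, 2), round(est.ci_low, 2), round(est.ci_high, 2),
      est.direction)
```

Output (seed 0):

```
0.9993                                  # HLI recovers the latent ranking
        model  r2_train  r2_test  rmse_test
      xgboost     0.997    0.945      0.038
     lightgbm     0.993    0.941      0.039
         gbdt     0.998    0.941      0.039
random_forest     0.975    0.771      0.077
     adaboost     0.881    0.759      0.079
        lasso     0.762    0.734      0.083
feature  mean_abs_phi  share_pct  rank
   MPPR          0.08      27.29     1
   NMIB          0.07      24.53     2
     UR          0.05      16.88     3
     PD          0.04      13.81     4
   RAPC          0.03      12.35     5
   UGPR          0.01       2.35     6
67.59 67.12 67.90 neg_to_pos
```

Reading it: the composite index reproduces the generator's latent health
ranking almost perfectly; every tree ensemble out-predicts the linear
baseline on the held-out rows because the planted effects are kinked and
plateaued; the six planted features occupy the top six importance shares;
and the urbanisation-rate attribution curve turns from negative to positive
near 67.6 — close to where the planted flat-then-rising effect passes its
population mean (the estimand of a crossing-based threshold; see the
methods note). The interval shown is the curve-level (pairs-resampling) CI;
`settlehealth.experiments.recover_threshold` provides the full-refit
bootstrap used for breakpoint-level uncertainty.

## Command line

```bash
settlehealth generate --seed 0 --out panel.csv
settlehealth all --config run.yaml      # index → benchmark → explain
                                        # → thresholds → interactions
```

`run.yaml` holds every protocol constant (split fraction and seed, CV folds,
search budget, span, bootstrap size, grids, seeds); identical configs
reproduce identical output bundles.

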