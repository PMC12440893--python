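# Methods

`settlehealth` implements a provincial health–settlement analysis pipeline:
a composite Health Level Index (HLI) is built from four health indicators by
entropy-weighted TOPSIS, six regressor families are benchmarked on 19
settlement-environment indicators against the HLI, and the best model is
interpreted through additive (Shapley) attributions, locally weighted
smoothing with zero-crossing threshold detection and bootstrap confidence
intervals, and two-feature partial-dependence surfaces. This note records
the models, the defaults, and the design choices made where the design was
genuinely open.

## Composite index (entropy-weighted TOPSIS)

Given m pooled province-year rows and four indicators x_ij with direction
attributes (incidence, mortality of class A/B notifiable infectious
diseases, and human mortality are negative — lower is healthier; average
life expectancy is positive), each column is min–max normalised with its
direction: positive columns map min→0, max→1; negative columns map max→0,
min→1. Entropy weights are

    r_ij = x'_ij / Σ_i x'_ij,
    e_j  = −(1/ln m) Σ_i r_ij ln r_ij   (0·ln 0 ≡ 0),
    d_j  = 1 − e_j,
    w_j  = d_j / Σ_k d_k,

and TOPSIS scores each row by closeness to the column-wise ideal point of
the weighted matrix v_ij = w_j x'_ij:

    HLI_i = D_i⁻ / (D_i⁺ + D_i⁻),  D_i± = Euclidean distance to the
    column-wise max (ideal) / min (anti-ideal) of V.

Properties guaranteed by construction and verified by tests: Σ w_j = 1 with
w_j ≥ 0; HLI ∈ [0, 1], attaining 1 (0) exactly at a row that is column-wise
ideal (anti-ideal); invariance under positive affine rescaling of any raw
column; and symmetry under negating a column while flipping its direction
tag.

Design choices:

- **Pooling.** The index is computed once over all province-year rows, not
  per year, so a single weight vector describes the whole panel. This is the
  only reading consistent with reporting one weight vector for an 11-year
  panel.
- **Degenerate (constant) columns** are normalised to 0 and forced to zero
  weight with a warning — a constant indicator carries no information, and
  its min–max map is undefined.
- **Interpolation** of interior gaps in yearly series (used for life
  expectancy in real panels) is per unit and strictly interior: a unit needs
  at least two observed anchor years, and gaps before the first or after the
  last anchor are refused rather than extrapolated.
- `EntropyTopsis.transform` scores new rows against the *fitted* min–max,
  weights and ideal points (clipped to [0, 1]), so the fitted sample's
  scores are reproduced exactly; out-of-sample use is a convenience, not
  part of the pooled-index definition.

## Benchmark protocol

Rows are split 80/20 with a fixed seed (default 2025), shuffled at the
province-year level; the test part receives ⌈0.2·n⌉ rows, so 341 rows
split 272 train / 69 test. Model selection uses 5-fold shuffled
cross-validation on the training rows, scored by mean fold R². Metrics are
computed from their defining formulas rather than library calls:
R² = 1 − SSE/SST, RMSE = √(SSE/n), MAE = mean |residual|.

Six families are benchmarked through a uniform fit/predict contract:
XGBoost (primary), sklearn gradient boosting (GBDT), AdaBoost, LightGBM,
random forest, and an L1-penalised linear baseline (standard-scaled Lasso,
default α = 10⁻³). The primary model's *reproduction preset* pins
learning rate 0.05, 200 estimators, max depth 3; other families run at
library defaults unless tuned. Tuning, when enabled, is seeded random
search over a configured space, maximising mean CV R² (the selection
criterion had to be chosen; mean fold R² is the simplest defensible one).
Boosting internals are deliberately delegated to xgboost/lightgbm/sklearn —
the contribution of this package is the protocol and its interpretation
stages, not a re-implementation of gradient boosting.

## Additive attributions

Each prediction is decomposed as ŷ_i = φ₀ + Σ_j φ_ij (local accuracy).
Engines, dispatched by model type:

- **xgboost / lightgbm native** tree contributions (TreeSHAP). Note that
  xgboost emits float32 contributions: the identity holds exactly inside
  the booster but each stored term is rounded, so validation for this
  engine uses 1e-5 relative tolerance (measured gaps ~1e-6 on panels of
  this size); all float64 engines validate at 1e-6.
- **Linear closed form** for (pipelines ending in) linear models:
  φ_ij = c_j (x_ij − mean of the background), the exact Shapley value of a
  linear model under an independent-feature background.
- **Permutation Shapley** for any other model (sklearn ensembles here):
  marginal contributions averaged over seeded antithetic feature orderings,
  with coalition values estimated as background-mean predictions. Whatever
  the number of orderings, the per-ordering sum telescopes to
  f(x) − mean f(background), so additivity is *exact* even when the Shapley
  estimate itself is noisy; more orderings only reduce attribution noise.
  Defaults: 10 orderings, background subsampled to 64 rows.
- **Exact enumeration** over all feature subsets, refused beyond d = 12,
  kept as the brute-force oracle the tests compare the other engines
  against (for d = 2, one antithetic pair of orderings *is* the exact
  value, which the tests exploit).

Importance shares are mean |φ| per feature, normalised to percentages; ranks
break ties alphabetically. Attributions default to the full sample (rather
than the train or test part) — the choice is exposed, and the full sample is
the least wasteful default for interpretation.

## Threshold analysis

The smoother is classical LOWESS with degree-1 local fits: at each of 200
equally spaced grid points over the observed range, the ⌈span·n⌉ nearest
points (span default 0.3) receive tricube weights on distance scaled by the
neighbourhood radius, and the exact weighted-least-squares solution supplies
the fitted value (solved in centred coordinates, so the estimate is the
local intercept). Locally linear fits reproduce affine data exactly for
every span — the zero crossing of y = a(x − t) is recovered at t to machine
precision. If all local weight falls on a single x value the fit falls back
to the weighted mean with a warning.

A *threshold* is a zero crossing of the smoothed attribution curve: the
feature value where the association with the outcome changes sign. Adjacent
grid values with opposite signs are interpolated linearly; exact grid zeros
are reported once. All crossings are returned; when several exist the
caller must select (by direction and/or proximity) — the library never
silently picks, and the pipeline's documented rule is the crossing nearest
the feature's median, recorded in its output.

Two statistical properties of this estimator matter and are documented
rather than hidden:

- **Estimand.** Attributions are centred at the expected model output, so
  the crossing estimates the point where the feature's effect equals its
  population mean — not, in general, the structural breakpoint. The
  generator exposes `implied_threshold()` (numerical solve of
  g(x) = E[g(X)]) as the ground truth for unbalanced effects, and
  `balanced_piecewise()` constructs effects whose implied threshold *is*
  the breakpoint (zero-mean, sign-changing association).
- **Kink bias.** A locally linear smoother is first-order biased at a slope
  discontinuity; the crossing shifts toward the shallow side by an amount
  growing with the slope change and the span. Measured on the urbanisation
  range with span 0.3: bias ≈ −2.4 units at slope ratio 0.31, −1.5 at
  0.56, −0.9 at 0.81. No bootstrap can repair bias, so nominal CI coverage
  is only attainable where the kink is moderate.

**Bootstrap.** `bootstrap_threshold` resamples the (x, φ) pairs with
replacement (default 1000 resamples), refits the smoother on the full-data
grid, records the crossing matching the point estimate (same direction,
nearest in x), and reports the percentile 95% interval; resamples without a
matching crossing are counted, and the estimate is flagged unstable when
they exceed half. This pairs-only mode is cheap but *freezes the fitted
model*, so it understates the dominant variance component (the boosted
fit's own variability) and badly undercovers as a CI for a planted
breakpoint. The recovery experiments therefore use the full-refit mode
(`experiments.recover_threshold`): each resample refits the booster before
re-smoothing. Measured on the package's recovery conditions (one balanced
piecewise effect on the urbanisation rate, breakpoint 58.0 at 53% of the
range, effect SD 0.065, noise SD 0.03, n = 341): point error ≤ ~5% of the
feature range and refit-CI coverage ~90%.

**Plateau detection** reports the earliest grid point after which the
absolute finite-difference slope stays below a tolerance through the end of
the grid; the pipeline sets the tolerance to 5% of the curve's mean secant
scale (range of fitted values over range of x).

## Partial dependence

Partial dependence at grid value g is the mean prediction over the full
sample with the swept feature(s) overwritten by g. Grids default to 20
empirical quantiles clipped at the 1st/99th percentiles — provincial
indicators are heavily skewed (population density spans three orders of
magnitude), and quantile grids avoid wasting resolution on empty tails.
The two-feature surface of an additive model equals the outer sum of its
1-D curves minus the global mean; `nonadditivity` measures the maximal
deviation from that reconstruction and is the package's interaction
statistic.

## Synthetic generator

The generator emulates a balanced 31-province × 11-year panel (341 rows).
Features are independent uniforms on realistic provincial ranges (an
equicorrelated Gaussian copula is available for dependence stress tests);
the latent outcome is a baseline of 0.60 plus additive effects of three
shapes — linear, continuous piecewise with a breakpoint, and
rise-then-plateau — with homoscedastic Gaussian noise (default SD 0.02).
The default effect set plants strongly nonlinear associations on six
features (medical-bed density with a falling sign change, urbanisation and
mobile-phone penetration flat-then-rising, road area and population density
rising-then-plateauing, gas penetration sharply rising past a high
breakpoint), with magnitudes (effect SDs ≈ 0.05, 0.037, 0.047, 0.029,
0.033, 0.011) chosen so the planted signal dominates noise (total SNR ≈ 4)
and importance concentrates on the planted features. The remaining 13
features carry no signal. Health indicators are monotone affine transforms
of the latent index plus small noise (1% of each indicator's span), the
simplest construction satisfying the direction attributes.

What the generator does *not* emulate — hence what passing tests do not
show about real data: the joint distribution of real provincial indicators
(features are independent by default), spatial or temporal autocorrelation
within provinces, heteroscedastic or non-Gaussian measurement error, and
any causal structure beyond additive effects. Recovery results on this
generator certify the estimation chain, not the substantive findings on any
real panel.

## Problem sizes and numerical choices

- Panels: 341 rows throughout (31 × 11).
- Coverage experiment: 100 Monte-Carlo repeats × 60 full-refit bootstrap
  resamples (single-run estimates use 200); sizes chosen to keep the full
  experiment at desk scale on one CPU.
- LOWESS grid: 200 points (config-exposed); dense distance matrices are
  used deliberately — panels here are hundreds of rows, not millions.
- Ties in TOPSIS extrema are harmless (max/min over duplicates); a row
  equidistant from both ideal points can only arise when every column is
  degenerate, which is rejected upstream.
- All stochastic stages (splits, folds, search, permutation orderings,
  bootstraps, generators) take explicit seeds; identical configuration
  reproduces identical output bytes.

## Known limitations

- The index weights depend on the pooled sample: adding rows changes
  normalisation extrema and therefore all scores (inherent to min–max
  TOPSIS, not a defect).
- Permutation attributions are exact in total but noisy per feature at few
  orderings; they are used where no native engine exists.
- The pairs-only bootstrap CI is honest about curve-fitting uncertainty
  only; breakpoint-level uncertainty requires the refit mode.
- Threshold estimates inherit the smoother's kink bias (quantified above);
  interpret crossings at strongly asymmetric kinks as method-biased.
- No panel econometrics: year effects, lags and fixed effects are out of
  scope.
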