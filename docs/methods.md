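# Methods

`vegsynth` estimates which social–ecological predictors best explain
long-term vegetation (NDVI) outcome trajectories, using synthetic-control
matching with placebo treatments. This note documents the model, the
estimation choices, the synthetic data-generating process, and the known
limitations.

## The estimator

For a treated unit with predictor vector `B1` (length N) and outcome
trajectory `Y1` (length T), and a donor pool with predictor matrix `B0`
(N × K) and outcome matrix `Y0` (T × K), the synthetic control is the
convex combination of donors defined by weights `W` on the probability
simplex. Two weight vectors are estimated jointly:

* **Inner problem (donor weights).** Given a diagonal nonnegative
  importance matrix `V`,

      W*(V) = argmin_{W ∈ simplex} (B1 − B0 W)' V (B1 − B0 W).

  The simplex constraint confines the synthetic unit to the convex hull of
  the donors — no extrapolation. For diagonal nonnegative `V` this is a
  convex quadratic program; it is solved by a primal active-set method
  with an exact KKT check (global optimum; SLSQP fallback if the active
  set stalls). Predictor columns are divided by their standard deviation
  over the treated unit and donors jointly before entering the problem, so
  importances are comparable across predictors measured in households,
  hectares, degrees, or index units. Columns that are constant up to float
  rounding carry no matching information and are dropped with a warning.

* **Degeneracy of the inner problem.** When the donor pool is larger than
  the effective predictor set, a whole face of the simplex attains the
  minimum. The Gram matrix receives a ridge of `1e-8 × mean(diag(G))`,
  selecting the minimum-norm (most dispersed) minimizer. This makes
  `W*(V)` a single-valued, continuous function of `V` while perturbing
  non-degenerate solutions only at the 1e-8 level.

* **Outer problem (predictor importances).**

      V* = argmin_V (Y1 − Y0 W*(V))' (Y1 − Y0 W*(V)),

  i.e. the importance vector whose implied synthetic unit best reproduces
  the treated unit's observed trajectory over the full matching window
  (the treatment is hypothetical and post-period, so all T observed years
  are pre-treatment). `V` is identified only up to positive scale
  (`W*(sV) = W*(V)`); internally it is normalized to sum 1 and reported
  either sum-normalized (the ranking-table convention, default) or with
  unit Euclidean norm (`v_normalization: euclidean`).

### Outer search and the weak-identification problem

The outer objective is non-convex, and — more importantly — weakly
identified whenever the donor pool is rich enough to reproduce the treated
trajectory under many different importance vectors: in that regime, MSPE
differences between candidate `V` are dominated by how well the implied
`W` happens to fit the treated unit's *noise*, not by predictive
structure. A plain global search over `V` then returns unstable,
concentrated importance vectors that change arbitrarily from run to run.

The search therefore works as follows:

1. **Regression-informed anchor.** Donor outcome trajectories are
   regressed on the scaled donor predictors (with intercept); the starting
   importance of predictor *i* is proportional to the squared L2 norm of
   its coefficient path across years. Predictors that actually explain
   outcome variation get large starting weight.
2. **Local refinement.** Nelder–Mead (derivative-free; the objective is
   piecewise smooth in `V` because the inner active set changes) refines
   the anchor in an unconstrained softmax parametrization of the simplex.
   This refinement is the canonical solution path and always replaces the
   unrefined anchor when it improves.
3. **Multistarts with a noise-aware acceptance band.** The equal-weights
   point and `n_multistarts` (default 10) Dirichlet-random points are also
   refined. An alternative basin replaces the incumbent only when it
   improves MSPE by more than `sqrt(2/T) · sqrt(2 ln M)` relative — the
   sampling error of an MSPE estimated from T squared gaps, widened by the
   usual extreme-value factor for selecting the best of M restarts.
   Improvements inside that band are statistically indistinguishable from
   fitting the treated unit's own noise and do not displace the anchored
   solution. Numerical ties (relative 1e-9) fall to lower inner loss, then
   to the lexicographically smallest importance vector.

All randomness (placebo sampling, Dirichlet starts) flows from the
configured seed; the per-unit multistart seed is derived from the seed and
the unit's *identity*, and donor pools are kept in sorted order, so
results are invariant to row order in the input files.

### MSPE convention

The outer loss is reported as a mean (sum of squared per-year gaps divided
by T), making thresholds independent of the window length; the raw sum is
stored alongside (`sspe`).

## Plausibility filtering and balance

A fit is accepted when (i) its MSPE is at or below the threshold and (ii)
its worst absolute standardized predictor difference — |treated −
synthetic| divided by the donor-pool SD — is at or below the balance cap.
With no absolute threshold configured, the relative rule `MSPE ≤ 0.1 ×
var(Y1)` applies: the synthetic trajectory must explain at least 90% of
the treated trajectory's variance. The default balance cap is 3 donor-pool
SDs: a single treated unit routinely sits 1–2 SDs from any convex donor
combination on low-importance predictors, so the cap flags only gross
extrapolation; tighten it in the config for stricter cohorts. Raising the
MSPE threshold can only enlarge the accepted set (monotonicity is tested).

## The study loop

1. Sample `n_placebo_sample` units without replacement (seeded); each
   sampled unit receives a hypothetical intervention dated after the last
   observed year, and every remaining unit forms its donor pool.
2. Fit the nested synthetic control per sampled unit.
3. Filter implausible fits; an empty accepted set raises an error rather
   than producing an empty table.
4. Average the sum-normalized per-fit importance vectors (each accepted
   unit contributes equally), renormalize to total 1, and rank: descending
   weight, ties broken alphabetically. Units are also binned by percent
   outcome change from the baseline to the final year — `(-∞, c1)` low,
   `[c1, c2)` medium, `[c2, ∞)` high, default cutpoints (10, 20) percent —
   and the averaging is repeated within each stratum over the already
   accepted fits (strata are not refitted).

## NDVI compositing

`NDVI = (NIR − Red)/(NIR + Red)` per pixel, bounded in [−1, +1]; valid
pixels with `NIR + Red = 0` are flagged missing with a warning. Seasonal
composites take the per-pixel maximum NDVI across same-season scenes
wherever a scene's validity mask is true (greenest-pixel mosaic; a pixel
is missing only when invalid everywhere). Annual unit means average valid
unit pixels within each of the five seasonal composites (winter, spring,
summer, monsoon, autumn) and then average the available seasons with equal
weight; season-then-year averaging is this package's fixed convention.
Scene admission (cloud-cover screening, sensor gap-filling) happens
upstream; per-pixel validity travels with each scene.

## Synthetic data-generating process

The generator emulates a district-scale panel of forest-management units:

    y[i, t] = base[i] + slope[i] · t + loading[i] · f[t] + ε[i, t],
    slope[i] = slope_base + slope_gain · Σ_j planted_j · z[i, j],

with `z` the standardized planted-driver predictors, `f` a shared smooth
year factor with `f[0] = f[T−1] = 0` (so total growth is exactly linear in
the drivers), and i.i.d. Gaussian noise. Outcomes are clipped to [−1, 1].
Predictors are drawn per SES subsystem — over-dispersed nonnegative
integers for counts, lognormal positives for areas, positive normals for
climate — and one predictor, `baseline_ndvi`, is set equal to the year-0
outcome, mirroring baseline vegetation condition. The planted importance
vector (geometric weights over `n_driving` randomly chosen non-baseline
predictors) is returned as ground truth.

Defaults and rationale:

| parameter | default | rationale |
| --- | --- | --- |
| `n_units` | 202 | scale of the motivating district panel |
| `n_years` | 14 | annual outcome window |
| `n_predictors` | 24 | indicator count nested in SES subsystems |
| `n_driving` | 3 | a small driver subset among mostly idle indicators |
| `baseline_range` | (0.30, 0.60) | plausible district spread of unit-mean NDVI |
| `slope_base` | 0.006 /yr | ~0.08 NDVI growth over the window, an overall greening trend |
| `slope_gain` | 0.008 /yr per SD | driver-induced growth spread ±0.1, spanning the <10% / >20% growth strata |
| `factor_amplitude`, `factor_loading_sd` | 0.01, 0.1 | shared inter-annual (climatic) swing and mild unit heterogeneity |
| `noise_sd` | 0.001 | calibrated once so ~90% of units are matchable under the default relative MSPE rule (measured 88% on 120-unit panels; residual failures are convex-hull and balance edge cases, which real cohorts also show) |

What the generator does **not** emulate: spatial autocorrelation between
neighbouring units, serially correlated disturbances, predictor
measurement error, and real-world correlation among predictors (indicators
are drawn independently, so e.g. households and literates are uncorrelated
here but strongly correlated in census data). Passing recovery tests
therefore show that the pipeline identifies planted drivers under the
model's own assumptions — not that importance rankings on real panels are
causal. The estimated importances are predictive, not causal, weights.

## Problem sizes in the test and acceptance runs

Experiments are scaled to desk size as the package's own test design:
recovery experiments use 30-unit panels with the default 24 predictors, a
single planted driver, and 8 placebo units per study over 20 generator
seeds (5 placebo units at zero noise, where the baseline range is
degenerate and factor loadings homogeneous so outcomes are driven entirely
by the planted driver); the planted-outlier cohort uses 30 units with 2
unmatchable units (each pushed 0.5 index units below the donor envelope
over its own block of late years) and an absolute MSPE threshold of
1e4 × noise variance, which sits several-fold above the worst matchable
unit's structural MSPE and several-fold below the planted outliers'
floor;
the acceptance script's headline study uses 60 units with 10 placebo
fits. Full-size (202 × 24) generation is exercised for shape and
determinism only.

## Numerical conventions

* Active-set QP: KKT tolerance 1e-10 (configurable), `lstsq`-based KKT
  solves so duplicated donors (singular systems) are handled; iteration
  cap `3K + 20` with SLSQP fallback.
* Nelder–Mead: `maxfev = 60 × dim` per start, `fatol 1e-11`,
  `xatol 1e-5` (all configurable through `StudyConfig`).
* Convex-hull and simplex assertions use absolute tolerances 1e-9/1e-6:
  the synthetic trajectory is an exact convex combination, so only float
  rounding can breach the bounds.
* Zero-variance predictors: dropped when the joint SD is below
  `1e-12 × max(1, column magnitude)`.
* Percent growth is undefined for a zero baseline outcome and raises.

## Known limitations

* Per-fit importance vectors remain weakly identified when donor pools
  are much larger than the predictor set; the regression-anchored search
  stabilizes them, but single-fit rankings should not be interpreted —
  only cohort averages.
* No inferential machinery (placebo-in-space permutation tests, conformal
  intervals) and no penalized or augmented synthetic-control variants.
* The stratified tables re-average existing accepted fits; strata are not
  refitted.
* Raster support covers plain CSV grids and 2–3-band TIFF stacks with a
  validity band; there is no geo-referencing, reprojection, or polygon
  rasterization.
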