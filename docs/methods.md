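# Methods

`fdmort` forecasts age-specific mortality surfaces — matrices of death
rates m_{x,t} over abridged age groups x (0, 1–4, 5–9, …, 80–84, 85+) and
calendar years t — with the log-bilinear Lee–Carter model, a functional
data (Hyndman–Ullah style) extension, and a subpopulation pipeline that
models child and adult age groups separately.  This note records the
models, the numerical conventions, and the design choices that were
genuinely open.

## Lee–Carter model

    log m_{x,t} = a_x + b_x k_t + ε_{x,t}

- `a_x` is the mean log rate of age x over the fitting years;
- `(b_x, k_t)` is the leading singular pair of the centered log-rate
  matrix, rescaled to the classical identification Σ b_x = 1, Σ k_t = 0;
- the joint sign is chosen so k_t correlates positively with the yearly
  mean of the centered log rates ("k falls ⇒ overall mortality falls"
  whenever most b_x > 0).  A fit can legitimately put negative loadings on
  most ages; the sign is reported, never silently flipped.
- No second-stage re-estimation of k_t against observed death counts is
  performed; the package works with rates only, so the original
  death-weighted adjustment has no inputs here.
- A surface with (numerically) zero time variance has no leading pair; the
  fit is flagged `degenerate` (uniform b, zero k) instead of failing, so
  pipelines over constant fixtures still run.  Forecasts from a degenerate
  fit are constant with a warning.

## Functional data model

    log m(x, t) = μ(x) + Σ_{k≤K} β_k(x) κ_{k,t} + ε(x, t)

μ is the pointwise mean curve; β_k are orthonormal functional principal
component loadings; κ_{k,t} are uncorrelated scores ordered by explained
variance.  The eigen-decomposition is computed via SVD of the centered
data matrix (numerically stabler than forming the covariance), with
eigenvalues λ_k = s_k²/(n_years − 1).  Loading signs are fixed to a
positive column sum so outputs are reproducible.

Pre-smoothing projects each year's log-rate curve onto a basis evaluated
at the age-group midpoints (0.5, 3, 7.5, …, 82.5, 90; the open 85+ group
is represented at 90).  Three parametric bases are available — cubic
B-splines, a Fourier basis on the age range rescaled to [0, 1], and a
natural cubic spline basis — alongside the default `data_driven` regime,
which skips smoothing and takes principal components of the raw curves.
The projection is unweighted least squares; penalized or weighted
smoothing variants are out of scope.  With `n_basis` equal to the number
of age points the projection is an interpolation and all regimes coincide;
because mortality curves are smooth over age, variance decompositions
agree closely across bases well below that limit (a Fourier design matrix
at full size is numerically rank-deficient, which is why the equivalence
is stated for smooth curves, not arbitrary matrices).

Default K = 3 components; configurable.

## Score forecasters

Five univariate methods share one interface and are all deterministic:

- **arima** — differencing order d ∈ {0, 1, 2} from a KPSS level-stationarity
  test at α = 0.05; (p, q) ∈ [0, 3]² by minimum AICc; drift (linear trend
  term) included when d = 1.  Estimation is Gaussian state-space MLE with
  concentrated innovation variance.  Two guards handle degenerate cases:
  a series whose d-th difference is numerically constant is a polynomial
  and is extrapolated exactly (an ARIMA with zero innovation variance
  degenerates to this, and its likelihood is ill-posed); and grid
  candidates whose fitted innovation variance collapses below 1e-8 of the
  differenced-series variance, or whose one-step forecast jumps by more
  than ten times the series range, are rejected as likelihood blow-ups —
  the standard pathology of high-order ARMA on short series.
- **ets** — additive-error exponential smoothing; trend spec
  (none / additive / damped additive) by AICc; no seasonal component, as
  the data are annual.
- **lr** — OLS on the time index 1..n.
- **lr_a** — OLS trend plus ARIMA(p, 0, q) on the trend residuals
  (differencing is forced off: the trend is already removed, and
  differencing a detrended series would double-count it); forecast = sum
  of both extrapolations.
- **gam** — a penalized cubic smoothing spline of the time index with
  GCV-selected smoothing, extrapolated linearly with the smooth's slope at
  the last observation.  Penalized splines have no natural extrapolation;
  the linear end-slope rule is an explicit convention, and it is why this
  method's long-horizon error grows monotonically on curved series.

Series are mean-centered internally before ARIMA/ETS/GAM estimation and
the mean is restored afterwards, which makes all methods shift-equivariant
(exactly for the closed-form methods; to optimizer tolerance, about 1e-5,
for the likelihood-based ones).  Model-selection ties go to the fit with
fewer parameters, then to the fixed order (arima, ets, lr, lr_a, gam).

## Score regression on exogenous factors

For each retained component the score series is regressed on yearly
covariates (e.g. GDP per capita, doctor density, population size):

    κ_{k,t} = α + γ₁ z_{1t} + … + γ_n z_{nt} + ε_t

by OLS, with t-test p-values, R² and the overall F p-value.  Per-factor
"contribution" percentages use the LMG relative-importance decomposition
(each factor's sequential R² increment averaged over all orderings of
entry, expressed as a share of the full R²): it is order-invariant, sums
to 100% of explained variance, and has a brute-force enumeration oracle,
which the tests exercise.  This is an interpretive choice — several
relative-importance measures exist — and is flagged as such.

Uncertainty comes from a case-resampling bootstrap (rows resampled with
replacement, size n, default B = 1000).  Replicate solves standardize the
factor columns internally — a pure reparametrization that keeps the normal
equations well-conditioned when factors differ in scale by orders of
magnitude — and rank-deficient replicates are redrawn (at most 10·B
attempts).  Percentile intervals are derived from the replicate matrix.
Whether a small-sample bootstrap is best read as inference or as "data
augmentation" is ambiguous in parts of the applied literature; this
package implements resampling-based inference.

Score forecasts from covariates are α + Σ γ_i z_{it} at explicitly
supplied future factor values; the package never extrapolates the factors
itself.

## Accuracy metrics and model selection

APE = |m − m̂|/m × 100; MAPE is the mean of APEs.  Per-age MAPEs average
over test years; the overall figure is the unweighted mean over age groups
(the "Mean" row of a standard accuracy table), not death-weighted.
Per-series model selection fits every candidate on the training window and
ranks by mean APE on the held-out window itself — mirroring how winners
are usually reported in validation tables; an honest inner split is
possible by passing a shorter training index but is not the default.

## Subpopulation pipeline

1. designated outlier years (e.g. pandemic years) are leveled by linear
   interpolation of log rates between the nearest non-replaced flanking
   years — on the log scale, consistent with the model's log-linearity,
   and exact for log-linear trends;
2. the surface splits into a child block (default 0, 1–4, 5–9, 10–14) and
   an adolescent–adult block (15–19 and older);
3. the adult block gets the functional model with ARIMA score forecasts
   (or covariate-regressed scores when enabled);
4. each child group is modeled separately, selecting among the five
   forecasters by held-out mean APE.  Child groups use the log-rate scale
   for LR/LR+A/GAM (their trends are log-linear) and the raw rate scale
   for ARIMA/ETS, as is standard practice; the scale per method is
   recorded in the run log, and raw-scale forecasts are floored at a tiny
   positive value so surfaces stay valid;
5. forecasts are merged, scored on the held-out frame, and (optionally)
   extended `horizon` years past the data after refitting on the full
   series.

Every stage is deterministic given the configuration seed; identical
config + seed gives byte-identical output CSVs.

## Synthetic data generator

The generator is the package's test bed: it reproduces the statistical
*structure* of a post-Soviet national mortality surface, not any real
series.

- **Log-bilinear surfaces** (`simulate_lc_surface`): log m = a_x + b_x k_t
  + ε with ε i.i.d. Gaussian on the log scale.  The error law is a choice
  made for testability; real vital-statistics noise is Poisson-like and
  heteroscedastic.  The realized k_t is centered to sum to zero so the
  truth carrier is identified exactly as an SVD fit would normalize it.
  Baseline a_x follows a plausible abridged schedule (infant rate ≈ 0.022,
  minimum at 10–14, near-Gompertz rise to 0.18 at 85+); default loadings
  peak in early childhood, young adulthood, late middle age and old age.
- **Period-index regimes**: linear; random walk with drift; or a
  piecewise-linear rise–plateau–decline path with two breakpoints
  (defaults 1998 and 2007).
- **Two-subpopulation scenario** (`study_scenario`): the child block
  declines log-linearly at 5.1%/year (year-on-year rate ratio 0.949),
  easing to 3.9%/year from 2013 when the slowdown is enabled; the adult
  block follows the piecewise index with per-year log slopes (+0.05,
  −0.005, −0.03) — a sharp 1990s rise, stagnation, then sustained decline,
  matching the documented adult log-range of roughly 0.4–0.5 over the
  era.  Log-noise defaults are 0.05 for child groups and 0.02 for adult
  groups: annual death counts of a few hundred in child groups and a few
  thousand in adult groups imply coefficients of variation of roughly
  5% and 2%.  These defaults were fixed once as the study condition.
- **Exogenous series**: GDP per capita with strong early growth and a
  late two-year dip-and-recovery; U-shaped population; near-constant
  doctor density (CV < 5%).
- **Outlier injection** multiplies whole year columns, emulating pandemic
  shocks; combined with the log-linear interpolation repair it is exactly
  invertible on noise-free log-linear trends.

What passing tests on this generator do *not* show: performance on real
registration data with Poisson noise, age-heterogeneous loadings within
blocks, cohort effects, or revisions; the generator has none of these.

## Why the split pipeline wins on the synthetic study condition

With a strongly trending low-variance child block stacked on a nonlinear
adult block, a joint FPCA blends the two sources into shared components
(scores must be orthogonal; loadings mix), so score extrapolation
misallocates dynamics between the blocks exactly where they diverge — the
held-out frame.  Modeling the blocks separately removes the blending, and
per-group selection lets each child series be matched by a method that
tracks its own pace.  The comparison harness
(`compare_whole_vs_subpop`) runs both pipelines on identical leveled data
and frames, so the reports are directly comparable.

## Problem sizes and numerical choices

Monte-Carlo checks use the study-scale panel (19 age groups × 33 years,
23 training + 10 test years) with 50–200 replicates depending on the
statistic, and B = 1000 bootstrap replicates; these sizes were chosen so
each property is measured with comfortable margin at interactive runtimes.
Degenerate-rank thresholds are 1e-12 of the leading singular value;
AICc tie-breaks prefer fewer parameters; APE selection treats mean APEs
within 1e-8 as tied.  Age-group midpoints are configurable; they matter
only for basis evaluation.

## Known limitations

- No Poisson-likelihood Lee–Carter variants, coherent multi-population
  models, or robust/weighted functional fits.
- No prediction intervals for surface forecasts beyond per-score
  intervals.
- Factor regressions are contemporaneous (no lags, no cointegration) and
  carry no causal interpretation.
- Selection on the held-out window is an oracle with respect to that
  window; accuracy reported there is an optimistic estimate for future
  data.
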