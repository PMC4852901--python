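# Methods

This note documents the models implemented in `paleoprod`, the conventions
adopted where the field leaves choices open, what the synthetic-data
generators do and do not emulate, and known limitations.

## ²¹⁰Pb chronologies (`paleoprod.dating`)

**Model.** The constant-rate-of-supply (CRS) model assumes the flux of
unsupported (atmospherically delivered) ²¹⁰Pb to the sediment surface is
constant through time. With λ = ln2/22.3 yr⁻¹ (²¹⁰Pb half-life 22.3 yr) and
A(x) the cumulative unsupported inventory beneath depth x,

    t(x) = λ⁻¹ ln(A(0)/A(x)),     r(x) = λ A(x)/C(x),

where C is unsupported activity (Bq/g) and r the dry-mass accumulation rate
(g/cm²/yr). Supported activity is estimated by ²²⁶Ra; unsupported = total −
supported, clipped at zero (flagged), with SDs combined in quadrature.

**Conventions.**

- Depths are cm below the sediment–water interface; intervals are half-open
  [top, bottom).
- Inventory quadrature treats activity as constant within an interval:
  boundary inventories are suffix sums of C·Δm, midpoint inventories linear
  interpolations in cumulative mass. The inventory sum runs over *every*
  interval with positive unsupported activity, including residual activity
  below the detected background; dates are assigned only above background.
  For a core whose residual unsupported activity at the bottom is ≲0.1% of
  the surface value, the resulting age bias stays below 1% throughout the
  dated range.
- **Background** is the shallowest depth from which unsupported activity is
  ≤ max(k·SD, floor) for that and all deeper intervals (k = 2, optional
  absolute floor for noise-free data). Cores that never reach background are
  flagged and dated over their full length with a warning — such
  chronologies are unreliable at depth and real surveys should core deeper.
- **Uncertainty** is 2 SD of the date distribution under Monte-Carlo
  resampling (default 1000 draws, seeded) of total and supported activities
  perturbed by their reported SDs. This captures the log nonlinearity near
  background that first-order propagation misses. Draws whose cumulative
  inventory goes non-positive at an interval are censored there.
- **Extrapolation below background** is linear in cumulative dry mass using
  the *median* CRS accumulation rate over the deepest third of dated
  intervals. The median rather than the mean, because point rates λA/C
  diverge as C → 0 just above background; the mean of those spiking rates is
  not a usable extrapolation slope.
- **Age-depth smoothing** fits year(d) = coring_year + Σ c_j d^j (the
  intercept pinned to the coring year at depth 0) for orders 2–4, weighted
  by the inverse variance of each interval's Monte-Carlo envelope so the
  precise recent dates dominate. "Lowest order with a reasonable fit" is
  operationalized as the lowest order whose fitted ages are monotone over
  the data range and which the next order does not significantly improve
  (nested partial-F test, α = 0.05). An adjusted-R² gap criterion was
  considered and rejected: age series spanning a century have R² ≈ 0.999 at
  every order, so any fixed R² gap degenerates to always choosing the
  lowest order. If no polynomial is monotone the model falls back to
  piecewise-linear interpolation with a warning.
- **¹³⁷Cs validation.** The 1963 fallout maximum (first/shallowest interval
  on ties) validates the chronology when 1963 lies within the peak
  interval's deposition span widened by the 2-SD envelope, i.e.
  |date − 1963| ≤ 2SD + Δm/(2r). The half-span term matters: an interval
  integrates several years of deposition, so its midpoint date can sit half
  a span from the true pulse year even under a perfect chronology; a
  midpoint-only rule would reject correct chronologies whenever interval
  resolution is coarser than the age uncertainty.

## Spectral chlorophyll-a (`paleoprod.spectral`)

Absorbance A = log₁₀(1/R). The trophic proxy is the area between the
absorbance curve and the chord joining its values at 650 and 700 nm
(negative residuals clipped), integrated by the trapezoidal rule; chord
subtraction makes the metric exactly invariant to any linear-in-wavelength
baseline, and a featureless spectrum has area zero. Concentration is a
linear function of peak area. The default slope 1 / intercept 0 are
placeholders — published calibrations are instrument-lineage specific and
must be supplied for physical units. Inferences below the detection limit
(default 0.01 mg/g dry weight) are reported at the limit with a censored
flag.

## Trend statistics (`paleoprod.trends`)

- **Enrichment factor**: mean concentration in the modern window (post-2000
  inclusive, through the most recent interval) divided by the mean in the
  pre-industrial baseline window (1955–1970, closed). Robustness variants
  replace one window by an interval count: the 2 or 3 most recent intervals,
  or the 2 or 3 intervals immediately preceding 1970. EF is scale-invariant
  by construction. A profile with no data in the baseline window (e.g. a DBT
  record that starts after industrialization) yields an inapplicable result,
  not a number.
- **Classification**: DBT EF < 2 → minimally enriched; > 2 → highly; exactly
  2 → minimally (documented tie-break); missing → undetermined.
- **Z scores** standardize each lake by its own full-series mean and sample
  SD (n−1), so multi-lake composites compare shapes, not magnitudes.
- **5-year bins** are anchored at calendar multiples of 5 ([5k, 5k+4]);
  observations are assigned by the age-model midpoint date of their interval
  and averaged unweighted across lakes within a group. Intervals
  representing more than 5 years stay in the bin of their midpoint year.
- **Breakpoint regression** fits the continuous two-segment model
  y = a + b₁t (t ≤ τ), y = a + b₁τ + b₂(t − τ) (t > τ): exact conditional
  OLS profiled over every interior observed year with at least `min_edge`
  (default 3) points per side — ties in RSS resolve to the earliest τ —
  followed by continuous refinement between the neighbouring candidates.
  SE(τ) is the Gauss-Newton (Jacobian) approximation at the optimum;
  significance is F = [(RSS₀ − RSS)/3]/[RSS/(n−4)] against an intercept-only
  null with p from F(3, n−4) (a single-line null with 2 numerator df is
  available). Applicability flags (no stable baseline, outlier-driven
  change, missing DBT EF) are caller-supplied study metadata, never
  auto-detected. Gauss-Newton Wald intervals for breakpoints are known to
  undercover in small samples near the detection limit: at an effect of
  4 noise-SD per decade coverage of the 2-SE interval is ~87%, recovering to
  92–96% at 8 SD per decade. The recovery simulations therefore use
  8 SD/decade (n = 30, 2-yr resolution) as the package's "clearly
  detectable change" condition — conservative relative to the ~60 SD/decade
  signal the default simulated chl-a histories carry.
- **Welch t-test** (unequal variances, Welch–Satterthwaite df) and
  **Pearson correlation** (two-sided p via the t transform) are implemented
  explicitly and cross-checked in the test suite against scipy and against
  permutation/closed-form oracles. Zero variance in both groups with equal
  means returns p = 1 by convention. No multiple-testing correction is
  applied anywhere.
- Seasons are meteorological: winter = Dec (prior year)–Feb, spring MAM,
  summer JJA, fall SON.
- The shipped 23-site fixture reproduces a published summary table
  (chl-a EF, DBT EF, post-2000 DBT concentration, breakpoint-eligibility
  flags). Its group Welch test is reported from the printed one-decimal EFs;
  tests assert only non-significance, since rounded inputs cannot reproduce
  a t computed from unrounded data.

## Deposition mapping (`paleoprod.deposition`)

- Loading (mg/m²) = concentration (mg/L) × SWE (mm), since 1 mm SWE is
  1 L/m².
- **Empirical variogram**: γ̂(h) = mean of ½(zᵢ−zⱼ)² in distance bins
  (default 15 lags to half the maximum pair distance).
- **Model fitting**: isotropic spherical/exponential/gaussian (default
  exponential; `range_m` is the e-folding scale for the exponential), by
  weighted least squares. Default weights are Cressie's relative weights
  N(h)/γ_model(h)²; raw pair-count weights are available but let the
  thousands of mutually correlated long-lag pairs swamp the few short-lag
  pairs that determine nugget and range (parameter errors of 50–150% in
  simulation), so they are not the default. A constant field returns a
  flagged pure-nugget model.
- **Estimator variance, not estimator bias, limits single-survey recovery.**
  One 300-site realization of a field with a 30-km exponential range cannot
  pin the range within 25% — ergodic fluctuation alone exceeds that. The
  recovery study therefore simulates ten independent 300-site surveys
  (a clustered design: widely spaced primaries for the sill, near-duplicate
  pairs for the nugget, log-spaced satellites for the range) and checks the
  *mean* fitted parameters, which land within ~5–15% of truth.
- **Ordinary kriging** solves the standard system with weights constrained
  to sum to 1 via a Lagrange multiplier, per grid-cell centre (default cell
  1 km). Duplicate site coordinates are averaged with a warning. With zero
  nugget the predictor is exact at data sites with zero variance.
  Coordinates are projected metres; geographic inputs must be projected
  first.
- **Cross validation** is leave-one-out re-prediction under the fixed
  fitted variogram.
- **Radial integration**: tonnes = Σ loading × cell area × 10⁻⁹ over cells
  whose centre falls in the disc (no partial-cell weighting — the
  discretization error vanishes with cell size and is <0.1% at 1-km cells
  for a 50-km disc). Negative predictions are clipped to zero (loadings are
  physical masses) and counted. **Day normalization** rescales a tonnage by
  the ratio of accumulation-day counts, assuming constant daily deposition.

## Synthetic data (`paleoprod.synthetic`)

The generators produce data with exactly the structure the analysis
assumes, with ground truth stored for recovery tests.

- **Cores**: constant (or piecewise-constant) dry-mass accumulation;
  unsupported ²¹⁰Pb C(m) = f/r·exp(−λ t(m)); a Gaussian ¹³⁷Cs pulse in age
  (SD 3 yr) centred on 1963; chl-a flat at a baseline then rising linearly
  after a breakpoint year; DBT at background before an onset year (default
  1967) and background × enrichment ratio after; reflectance spectra built
  as a 0.5-absorbance baseline plus a triangular 650–700 nm peak whose area
  inverts the configured calibration (any shape with the correct
  chord-subtracted area is equivalent for the metric; the triangle sampled
  on a grid containing 650/675/700 nm integrates exactly).
- **Noise**: multiplicative Gaussian with a counting-error CV on activities
  (counting-statistics approximation), additive Gaussian on chl-a (optional
  AR(1), default off) and on snow loadings; everything is clipped at
  physical zero; every generator takes an explicit seed and no global random
  state is touched.
- **Defaults as study conditions**: 80 × 0.5 cm intervals at 0.15 g/cm² each
  (12 g/cm² cumulative, ~240 yr — deep enough that unsupported ²¹⁰Pb
  reliably reaches radiometric background, a precondition of CRS dating);
  flux 0.1 Bq/cm²/yr; accumulation 0.05 g/cm²/yr; supported activity
  0.05 Bq/g; counting CV 8%; ¹³⁷Cs peak 0.25 Bq/g; chl-a baseline 0.02 mg/g,
  post-1980 slope 0.002 mg/g/yr, noise 0.005 mg/g — values typical of small
  boreal lakes.
- **Snow surveys**: quasi-regular jittered grids with loading = background +
  amplitude·exp(−d/decay) + nugget noise around a configurable source, SWE
  drawn per site, concentration back-computed as loading/SWE.
- **Climate**: annual plus four seasonal temperature series sharing one
  linear trend (seasonal offsets are fixed boreal-continental constants),
  precipitation as trendless noise.

**What passing tests do and do not show.** The generators omit sediment
focusing, bioturbation, compaction beyond the supplied dry-mass profile,
multi-source or anisotropic plumes, non-monotone production histories, and
autocorrelated climate noise. Recovery of configured parameters on these
synthetics demonstrates that the estimators are implemented correctly and
are well calibrated under their own assumptions — not that real cores or
surveys satisfy those assumptions.

## Problem sizes used in the recovery studies

Monte-Carlo envelope coverage: 200 cores × 500 draws (observed ~92%
coverage of 2-SD envelopes, nominal 95%). ¹³⁷Cs validation: 100 cores
(~98%). Breakpoint recovery: 200 series of 30 points (~92–96%). Variogram
recovery: 10 surveys × 300 sites. Kriging and integration checks run on
121×121 grids at 1-km cells. The full default test suite and the acceptance
script each complete in well under a minute.

## Known limitations

- CRS dates more than ~120 yr old carry large and skewed uncertainties;
  the 2-SD envelopes slightly undercover there (the dominant contributor to
  overall coverage sitting at ~92% rather than 95%).
- SE(τ) from the Gauss-Newton approximation understates breakpoint
  uncertainty for weak effects (see above); treat 2-SE intervals near the
  detection limit as optimistic.
- EFs computed against a 1955–1970 baseline are attenuated whenever the
  forcing begins inside the baseline window (as with a 1967 industrial
  onset): observed EFs preserve rank order across a gradient but understate
  the underlying enrichment ratios.
- Kriging assumes isotropic second-order stationarity; no co-kriging,
  anisotropy, or trend (universal) kriging is implemented.
- The chronology's contribution to breakpoint-timing uncertainty is not
  folded into SE(τ); pipeline tests allow a few years of slack for it.
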