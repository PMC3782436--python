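# Methods

This note documents the models, numerical choices, and synthetic-data design
behind `seasonfire`, and states what the test suite does and does not show.

## Season characterization from cumulative rainfall anomalies

The CRA at day *t* is Σ≤t (rain − r̄), with the reference rate r̄ defaulting to
the record's long-term mean daily rainfall (configurable; a fixed positive
rate may be supplied). The CRA is a waveform: it falls through the dry season
and rises through the wet season, so the wet-season onset is taken as the day
after the CRA minimum inside a search window (default March 1 – July 31) and
cessation as the day of the CRA maximum inside a second window (August 1 –
December 31). Those windows bracket the site's mean boundary dates (late May
and the start of October) with wide margins. The dry season is the
complement — it begins the day after wet cessation, spans New Year, and is
labeled by the calendar year of its onset, so a record's final year has no
complete dry season.

Decisions worth making explicit:

- **Duration counts both endpoints.** May 21 → Oct 1 is 134 days and
  Oct 2 → May 20 is 231; these anchors fix the convention everywhere
  (season rainfall, ENSO weighting).
- **No smoothing by default.** An optional centered moving average on the CRA
  exists but is off. We prototyped a global least-squares piecewise-linear
  breakpoint detector as an alternative; it performed *worse* than the
  windowed argmin because CRA noise is an integrated (random-walk) process,
  which global least squares handles badly. The local extremum is the right
  estimator here.
- **Turning-point failures are flagged, not guessed.** A year is flagged when
  the windowed CRA is flat (constant rainfall) or when its extremum falls on
  the first or last day of the window — in the latter case the anomaly was
  still falling/rising when the window closed, so no turning point exists
  inside it. Flagged years carry NaN descriptors and are excluded downstream
  with a logged count. Edge-flagging matters in long simulations: roughly one
  year in several hundred at default noise, but a single unflagged edge year
  can place a "dry onset" on January 1 and, after the log10 transform,
  dominate a correlation.
- **Trend consistency** is the R² of an OLS line through the CRA within the
  season (≥ 3 days; zero-variance segments return NaN). Feb 29 stays in the
  daily grid and day-of-year is computed on the real calendar.

## Season-weighted Niño 3.4

Seasons start and end mid-month, so the seasonal index is a weighted mean of
monthly values, each month weighted by the inclusive count of season days it
contains; weights therefore sum exactly to the season duration. Both the NOAA
wide table layout (year + 12 monthly columns) and long `year,month,value`
CSVs are read. Each seasonal model uses the index averaged over the span of
the season being modeled; the fire model uses the dry-season span.

## Transforms

Fixed per-variable assignments (sqrt for fire counts and area; natural log
for wet duration and rainfall; log10 for dry onset day; squaring for wet
onset and dry duration; y = |ln(1 − x)| for trend consistency in both
seasons). The reflect-log formula is the sign-free collapse of
reflect → log → re-reflect and is strictly increasing on [0, 1). No offset
constants are introduced: sqrt accepts zero counts, and the log transforms
are applied only to strictly positive variables. Domain violations are
collected across the whole table and reported with row identities.

## The SEM engine

Covariance structure only — no mean structure. A `PathModel` is a recursive
(acyclic) system over observed variables: free or fixed edge coefficients,
one free error variance per endogenous variable, free variances for exogenous
variables, and exogenous covariances **fixed at zero unless declared**. That
default is deliberate: it reproduces the degrees of freedom of every model
this package catalogs (e.g. the five-variable dry starting model has
q = 4 + 2 + 3 = 9 free parameters and df = 15 − 9 = 6).

Estimation minimizes F_ML(θ) = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − p with
Σ(θ) = (I−A)⁻¹Ω(I−A)⁻ᵀ, S the n−1-denominator sample covariance, and
χ² = (n−1)·F at the optimum. Numerics:

- **Parameterization:** raw coefficients and covariances; log variances
  (variances stay positive along the whole optimization path; internal
  log-values are clipped at ±40 before exponentiation so line-search
  overshoot cannot overflow).
- **Gradient:** analytic, via dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) dΣ]; BFGS with
  gtol 1e-8, at most 500 iterations.
- **Starts:** an equation-wise least-squares warm start (exact ML when the
  exogenous block is saturated) plus four deterministic seeded perturbations;
  the best converged optimum wins. Fits are deterministic given inputs.
- **Standard errors:** finite-difference Hessian of F at the optimum,
  acov = (2/(n−1))H⁻¹, delta method back from log-variance coordinates;
  two-sided z-tests per free coefficient feed the significance tiers
  (dashed > 0.10 ≥ gray > 0.05 ≥ thin > 0.01 ≥ medium > 0.001 ≥ thick).
- **Heywood handling:** the log parameterization cannot produce negative
  variances; solutions pinned at the variance floor are flagged `heywood`
  and excluded from search rankings by default.
- **Saturated models** (df = 0) report χ² ≈ 0 and no p-value rather than
  p = 1.

Standardized coefficients multiply each raw coefficient by the implied SD of
its source over the implied SD of its target; R² for an endogenous variable
is 1 − error variance / implied variance. Effect decomposition uses the
standardized coefficient matrix: totals are (I−A)⁻¹ − I, directs are A,
indirects the difference (equal to the sum over all ≥2-edge directed paths of
their coefficient products, verified against exhaustive path enumeration).

BCC = χ² + 2q(n−1)/(n−p−2) (single-group covariance form) and AIC = χ² + 2q;
the BCC per-parameter penalty 2(n−1)/(n−p−2) exceeds 2 for every admissible
n, hence the stronger lean against complex models. Published BCC values from
the software used in the original study are not reproducible from this
documented formula and are not treated as targets.

## Specification search

All 2^k subsets of a framework's optional edges are enumerated in
lexicographic mask order (guardrail k ≤ 20) and fitted; candidates skip the
standard-error Hessian and extra starts (the warm start is near-exact for
these recursive candidates), and the top ten are refit in full. Ranking is
ascending BCC with ties broken by fewer free parameters, then smaller mask —
a deterministic total order independent of evaluation order. Non-converged
and Heywood fits are listed separately; unidentified candidates (df < 0) are
skipped with a logged reason. The shipped saturated frameworks encode a
forward variable ordering (ENSO upstream, then onset, duration, rainfall,
trend consistency; for fire: ENSO, previous wet-season trend consistency,
dry rainfall, fire count, area) — an encoding assumption noted in the spec
files themselves.

## Model catalog

Every named model ships as a human-readable `.sem` file (edge list with
`free`/`fixed=` markers). Fitted models carry their published standardized
coefficients; coefficients that appear only in figure graphics are stored
with a `placeholder` marker and implementer-chosen simulation defaults
(dry best: ENSO→trend-consistency −0.25, described as significant but weak;
wet best: ENSO→duration +0.30 and ENSO→trend-consistency −0.45). Placeholders
are used for data generation only and are never asserted as ground truth in
tests. Whether the preferred fire model includes a residual covariance
between fire count and area beyond the directed edge is not documented; none
is included.

## Synthetic data

Two generation levels, by design:

1. **Descriptor level.** Exact multivariate-normal draws from a fully fixed
   path model under the unit-variance convention (exogenous variances 1,
   error variances 1 − explained), so the stored coefficients are
   simultaneously raw and standardized and the population covariance equals
   the implied covariance. This tests the SEM engine with no season-detection
   noise.
2. **Daily level.** A mechanistic climate generator with stored ground
   truth. Per year, wet-season boundaries are drawn around May 21 / Oct 1
   with 30-day jitter (clipped at ±60 days to stay inside the detection
   windows). Daily rainfall is a Bernoulli–gamma storm process whose rate
   switches between regimes calibrated to the site's totals (dry ≈ 42,
   wet ≈ 89 cm per season); event probabilities 0.95 (wet) / 0.60 (dry) and
   gamma shape 3 describe frequent light-to-moderate convective events.
   Interannual lognormal rate multipliers (σ 0.15 wet, 0.12 dry residual)
   plus an ENSO coupling of 0.20 on the log dry-season rate are log-clipped
   at ±2 SD so the wettest simulated dry season stays clearly below the
   annual-mean rate — beyond that limit the CRA loses its turning point, and
   observed dry-season totals never approach it. The monthly ENSO index is
   AR(1) with coefficient 0.92 and marginal SD 0.9 °C. Much of the
   interannual rainfall SD comes from duration jitter, which is why the rate
   multipliers can stay modest while season totals reproduce the reported
   spread (measured ≈ 41 ± 10 dry, 89 ± 31 wet cm across seeds).
3. **Fire records.** Annual counts and area burned driven by the preferred
   fire model's coefficients on the standardized sqrt scale, with noise SDs
   chosen to match the published R² values (0.27 for counts, 0.63 for area),
   back-transformed around √counts ≈ 3.5 and √area ≈ 40 (≈ 13 fires and
   1600 ha in a typical year), counts rounded, and negatives truncated at
   zero with a logged count (the truncation mildly perturbs the Gaussian
   assumption; recovery tolerances absorb it).

What the generator does **not** emulate: spatial structure, hurricanes,
temperature, autocorrelation between consecutive seasons beyond ENSO
persistence, and any nonlinear rainfall–fire response. Passing recovery tests
therefore demonstrate correctness of the estimation chain under the stated
generating process, not real-data performance.

Trend consistency has no published distributional form; at the daily level it
emerges from the CRA, and at the descriptor level it is sampled on the
reflect-log-transformed scale like every other variable.

## Pipeline

The orchestrator runs inputs → descriptors → season-weighted ENSO →
transforms → starting-model fits → specification searches → effect tables,
writing TSV/JSON/DOT artifacts plus a manifest carrying the seed, a
configuration hash (analysis parameters only — the output directory is
excluded), package version, and stage log. The fire analysis couples fire
year *t* to the dry season labeled *t−1* (October *t−1* – May *t*, the fuel
conditions preceding that year's fires) and to wet season *t−1*; the one-year
shift drops the first fire year and is logged. Reruns with the same
configuration are byte-identical.

## Problem sizes in the test suite

The suite fits these sizes: oracle equivalence over 20 random 3–5-variable
models at n = 300; coefficient recovery at n = 5000 and sign recovery over
100 replicates at the study's n = 58 / n = 30; χ² calibration over 500
simulated 58-year datasets (rejection rate must fall in [0.02, 0.10] at
α = 0.05); search sanity over 50 replicates of a 32-candidate framework at
n = 5000; CRA recovery pooled over three 58-year generator runs; and the
end-to-end daily→SEM check over 25 replicates at 58 years plus two pooled
~2000-year runs (chunked, since a contiguous multi-millennium daily index
would overflow nanosecond datetimes).

## Known limitations

- Observed variables only: no latent variables, means/intercepts, multiple
  groups, GLS/WLS/robust estimators, or missing-data FIML.
- The exhaustive search is exponential in the optional edge count by design;
  the guardrail stops at 2²⁰ candidates.
- The closed-form oracle used for cross-checking covers recursive models
  with saturated exogenous blocks; models with fixed-zero exogenous
  covariances are validated instead through calibration and recovery tests.
- Printed p-values in the source material are reproduced analytically except
  one Pearson example (r = 0.29, n = 30, printed p = 0.30) that is
  inconsistent with the standard t-based computation (≈ 0.12); the package
  implements the standard formula and does not reproduce that value.
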