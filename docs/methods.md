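# Methods

## Extreme-temperature indices

A day is judged against its own city's climatology for that calendar
day. For city *i*, day-of-year *d*, the warm standard `Max_q(i, d)` is
the empirical `q_upper` quantile (default 0.95) of the daily maxima
observed on day *d* across the reference years (default 20); the cold
standard `Min_q` is the `q_lower` quantile (default 0.05) of the
minima. The indices are signed gaps:

    EHT = MAXT − Max_q        ELT = Min_q − MINT

so positive values mean "beyond the extreme standard" on both sides.
Apparent (wind-adjusted) variants subtract `sqrt(WS)` from the index;
day-over-day variants apply the same construction to the signed change
`MAXTD_t = MAXT_t − MAXT_{t−1}` (and likewise for minima), with the
first day of any contiguous run, and any day after a date gap, left
missing. WDI/CNI count strict exceedances (`MAXT > Max_q`,
`MINT < Min_q`) over a year; ties at the standard are not extreme.

Numerical choices:

- **Quantile estimator**: linear interpolation between order statistics
  (position `1 + (n−1)q`), pinned for reproducibility.
- **Calendar cells**: Feb 29 maps into the Feb 28 cell; an optional
  ±k-day pooling window (with wraparound) trades calendar resolution
  for threshold variance — at the default window 0, a 20-year
  reference gives 20 observations per cell, and the resulting
  threshold sampling noise (≈1.4 °C sd at the 95th percentile of a
  3 °C-sd anomaly) is a real feature of percentile indices at this
  scale. It inflates measured exceedance rates above the nominal 5%
  and is why the packaged WDI/CNI means sit near 30–44 days rather
  than ≈18.
- **Sparse cells**: a cell with fewer than two temperature
  observations is an error (named in the message). The *change*
  thresholds are the exception: reference data that is not
  day-contiguous has no defined diffs, so those cells yield missing
  change thresholds with a logged warning rather than rejecting the
  whole table.
- **Clamping**: the default index is continuous (signed); clamp mode
  floors every index variant at zero after construction, so the
  clamped value is exactly `max(0, continuous)` elementwise. The
  continuous default keeps the index defined on non-extreme days,
  matching an estimation panel that spans the whole year.

## Sentiment index

Post scores live on [0, 100]. Within a city, posts with identical
whitespace-normalized text (case preserved) are duplicates — spam is
re-posted verbatim into city feeds — and only the earliest by
(date, post id) is kept; deduplication across cities is optional. The
city-day index is the median of the remaining scores (midpoint
convention for even counts); city-days without posts are missing, not
zero. The median is used instead of the mean because single extreme
scores (0 or 100) otherwise move thin city-days substantially. A
pluggable scorer interface accepts any text→score backend; the packaged
lexicon scorer is a deterministic stub for tests and simulation only.

## Panel estimators

The structural model is

    Sentiment_it = β₀ + β₁ EHT_it + β₂ ELT_it + β′X_it + T_t + γ_i + ε_it

with controls X (PM2.5, wind, precipitation, cumulative COVID-19
cases), time effects T (day-of-week dummies by default; the 24 solar
terms or ISO week-of-year as alternatives) and city effects γ. City
effects are absorbed by within-demeaning, which equals explicit
city-dummy OLS (Frisch–Waugh); the suite asserts that equivalence to
1e−8. Reported "standardized" coefficients z-score the temperature
regressors only, leaving the outcome in score units, so a coefficient
is the score change per one SD of the index; full raw-scale fits are
available and the two are consistent (z-fit = raw-fit × sd).

Inference is CR1 cluster-robust by city:
`V = c (X′X)⁻¹ [Σ_g X_g′u_g u_g′X_g] (X′X)⁻¹` with
`c = G/(G−1)·(N−1)/(N−k)`, where k counts slope columns plus absorbed
fixed-effect levels (so demeaned and dummy fits give identical SEs),
and p-values use a t distribution with G−1 degrees of freedom — a
conservative cluster-count-based choice. Fits require ≥2 clusters and
a full-rank design; collinear columns are named in the error. Because
per-capita income is time-invariant, specifications with a PCDI main
effect must drop the city fixed effect (`fe_city=False`, which adds an
intercept); PCDI can always enter through interactions.

**2SLS.** Endogenous indices are instrumented by the altitude-corrected
neighbor means (below). Stage one regresses each endogenous regressor
on the instruments plus all exogenous terms (same absorbed effects);
stage two replaces it with its fitted value. The clustered covariance
evaluates structural residuals at the *original* regressors. Both
stages' coefficient tables are returned. Diagnostics, computed on
variables partialled of the exogenous block: per-endogenous first-stage
F for the excluded instruments, the Cragg–Donald minimum-eigenvalue
statistic (equal to that F in the just-identified single-endogenous
case — asserted numerically), and the Anderson canonical-correlation
LM statistic, `N·r²_min` against χ² with (#instruments − #endogenous
+ 1) degrees of freedom, for under-identification. The 2SLS R² is the
conventional one computed from structural residuals; it can be small
or negative and is reported as-is.

## Neighbor instruments

`NEHT_it` is the equal-weight mean over city *i*'s bordering cities *j*
of `EHT_jt − 0.6·(Al_j − Al_i)/100`, the environmental-lapse-rate
correction putting neighbor *j*'s value at *i*'s altitude; `NELT`
likewise. Adjacency is supplied as a symmetric edge list (the
"bordering" relation is administrative, not geometric); a city with no
neighbors is a configuration error, and a city-day with no reporting
neighbor yields a missing instrument. The altitude term shifts each
directed pair by a constant, so it moves instrument *levels* (absorbed
by city fixed effects) rather than within-city variation; instrument
relevance should therefore be judged within-city, as the first stage
does.

## Synthetic study generator

The generator emulates the study's data at its native scale — 49
cities, a 20-year reference climatology, a 366-day study year, 3
stations per city, 1–50 posts per city-day — with every output a pure
function of (scenario, seed):

- **Temperature**: city daily maxima are a seasonal cosine (amplitude
  12 °C, peak near day 200, north cities 6 °C cooler than south) plus
  an AR(1) anomaly (persistence 0.7, stationary sd 3 °C) that loads
  √0.95 on a shared regional factor and √0.05 on a city-specific
  factor, giving ≈0.95 anomaly correlation between any two cities —
  the source of instrument strength. Minima are maxima minus a
  gamma-distributed diurnal range (mean 9 °C, sd 1.5 °C); stations add
  0.5 °C observation noise.
- **Covariates**: wind gamma(2, 1.65) (mean 3.3 m/s, the heterogeneity
  threshold), precipitation a 30% wet-day mixture, PM2.5 lognormal
  with median 15 µg/m³ (likewise the threshold), and one Poisson
  outbreak window per city cumulated into CCD.
- **Sentiment**: the latent city-day mean follows the structural model
  above with β_EHT = −0.16 and β_ELT = −0.27 per °C applied to the
  *pipeline's own* computed indices (the generator never reimplements
  the index formulas), city effects N(0, 2), a +1 weekend effect, and
  control coefficients of realistic sign and size. Posts are the
  latent mean plus N(0, 10) noise truncated to [0, 100]; scenarios are
  validated to keep latent means interior (a warning fires if >1% of
  city-days leave [5, 95]) so truncation cannot bias recovery.
  Optional spam duplicates earlier posts' text at a configured rate.
- **Confounding**: an optional heat-island shock enters sentiment with
  scale 4 score-points and correlates (ρ) with the city's *own
  idiosyncratic* anomaly. This biases OLS while leaving the neighbor
  instrument valid, because neighbors share only the regional factor.
  A deliberate "broken-IV" variant correlates the shock with the
  *shared* anomaly instead, contaminating the instrument — included to
  demonstrate what failure looks like, and expected to fail recovery.

What the generator does **not** emulate: real posting-volume dynamics
(diurnal cycles, event bursts), spatially heterogeneous climate change
trends, humidity (the apparent index uses only √wind), measurement
drift in stations, or any text semantics. Passing recovery tests
therefore show the estimators are correct for the assumed linear DGP
at the study's scale — not that the substantive coefficients would
transfer to real Weibo/NOAA data.

## Monte-Carlo design

Recovery experiments fix one world and reference climatology, then
redraw the study year, covariates and posts per replicate; truth is
conditional on that fixed climatology. With 200 replicates at 49 × 366,
clean-scenario estimates are unbiased within Monte-Carlo error and
cluster-robust 95% CIs cover near nominally; under ρ = 0.5 confounding
the OLS bias is tens of MC SEs while 2SLS remains within noise of
truth with first-stage F in the tens of thousands. Replicate seeds
derive from one SeedSequence, so runs are reproducible and replicates
independent.

## Known limitations

- Threshold sampling noise at window 0 attenuates the plain
  EHT/instrument correlation; within-city (FE) relevance is the
  meaningful measure and is what the diagnostics report.
- The cold-side instrument is weaker than the warm side because the
  diurnal range adds independent noise to minima; it remains far above
  weak-instrument thresholds at the packaged settings.
- The solar-term table uses fixed approximate Gregorian start dates
  (drift ≤1 day across recent decades); exact astronomical boundaries
  can be supplied by the caller.
- CR1 with 49 clusters is standard but not exact; no wild-cluster
  bootstrap is provided.
- No GMM/LIML, spatial-error models, or Driscoll–Kraay SEs; the
  identification argument for neighbor instruments is taken as given
  rather than tested against spatial spillovers.
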