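# thermosent

Panel econometrics for linking **extreme temperatures** to **city-day
social-media sentiment**.

City residents post constantly; each post can be scored 0–100 for how
positive it reads. Collapsing those scores to a per-city-day median
yields a daily mood index for dozens of cities at once — and asks a
classic environmental-epidemiology question: *do extremely hot days and
extremely cold nights measurably depress urban mood, and for whom most?*
`thermosent` implements the full inference chain for that question, for
researchers in environmental epidemiology and applied climate
econometrics:

1. **Climatology** — aggregate weather stations to city-days and build
   per-city, per-calendar-day percentile standards from a 20-year
   reference period. The extreme indices are signed gaps:

   `EHT_it = MAXT_it − Max_95%` (extreme high temperature),
   `ELT_it = Min_5% − MINT_it` (extreme low temperature),

   with apparent variants `EHAT = EHT − √WS`, `ELAT = ELT − √WS`,
   day-over-day change variants `EHTD/ELTD`, and annual Warm-Day /
   Cold-Night counts (WDI/CNI).
2. **Sentiment** — deduplicate posts (spam repeats verbatim) and take
   the per-city-day **median** score, which resists extreme-score
   contamination.
3. **Fixed-effects panel regression** —

   `Sentiment_it = β₀ + β₁·EHT_it + β₂·ELT_it + β′X_it + T_t + γ_i + ε_it`

   with city fixed effects, day-of-week (or 24-solar-term) time
   effects, CR1 standard errors clustered by city, and z-scored
   temperature regressors so coefficients read "score change per one
   SD of the index".
4. **Instrumental variables** — unobserved city-day shocks (urban heat
   islands) can move temperature and mood together. Each city's
   indices are instrumented by the mean of its *bordering cities'*
   indices, harmonized by the 0.6 °C / 100 m lapse rate
   (`NEHT_it = mean_j [EHT_jt − 0.6(Al_j − Al_i)/100]`), with
   first-stage F, Cragg–Donald and Anderson LM diagnostics.
5. **Heterogeneity** — refit on sample splits: PM2.5 at 15 µg/m³, wind
   at 3.3 m/s, weekday/weekend, new COVID-19 cases, north/south of the
   Qinling–Huai line, and city income at the median.
6. **Synthetic study generator** — a seeded world of 49 cities with
   spatially correlated daily weather, covariates and post-level
   sentiment produced by a known linear model (optionally confounded),
   so every stage is testable end to end with no data download and
   recovery can be checked against stored truth.

## Worked example

```bash
python examples/03_fixed_effects_panel.py
```

```
      estimate  se_cluster  p_value
term
EHT    -0.5100      0.0393      0.0
ELT    -0.9168      0.0381      0.0
PM25    0.0162      0.0030      0.0
WS      0.1572      0.0109      0.0
N = 17934, cities = 49, within R2 = 0.0868
```

One standard deviation of extra extreme heat lowers the median
sentiment score by 0.51 points on this simulated study; extreme cold by
0.92. The cold coefficient exceeding the heat coefficient mirrors the
generating model (`β_ELT = −0.27` vs `β_EHT = −0.16` per °C, times each
index's SD). `examples/04_instrumental_variables.py` adds a heat-island
confounder and shows OLS sliding toward zero on EHT while 2SLS stays on
the generating values; `examples/01`, `02`, `05` demonstrate the index
construction, the median sentiment index, and the split battery.

A thin CLI chains the stages (`simulate`, `indices`, `sentiment`, `iv`,
`fit`, `heterogeneity`, `all`); `thermosent all --seed 7 --out results/`
runs the packaged scenario end to end and writes deterministic
coefficient tables plus a JSON run manifest.

## Layout

- `src/thermosent/` — library (`climatology`, `sentiment`,
  `instruments`, `panel`, `heterogeneity`, `simulate`, `montecarlo`,
  `pipeline`, `io`, `config`, `calendars`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — model, assumptions, numerical choices, limitations
- `tests/` — pytest suite, including the end-to-end acceptance checks
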