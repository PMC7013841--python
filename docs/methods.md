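# Methods

This note records the statistical models the package implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## AQI conversion

The Air Quality Index for a pollutant concentration `C_p` is computed by
piecewise-linear interpolation between tabulated breakpoints,

    I_p = (I_high − I_low) / (C_high − C_low) · (C_p − C_low) + I_low,

using the breakpoint row whose concentration range contains `C_p`.  The
bundled table is the Kuwait AQI: six categories (Good … Hazardous) per
pollutant, PM10 in µg/m³ and gaseous pollutants in ppm, with 8-h
averaging windows for O3 and CO and 24-h windows otherwise.

Three conventions are fixed here because published tables are
discretized and bounded:

- **Gap rule.** Consecutive rows abut with small gaps (e.g. PM10
  90 / 90.1 µg/m³).  A concentration strictly inside a gap resolves to
  the row with the nearest lower bound above it.  This keeps the
  conversion monotone; the alternative (nearest row below) would too,
  but the chosen reading matches how rounded table bounds are normally
  interpreted: a value that has outgrown a category belongs to the next.
- **Clipping.** Concentrations above the top breakpoint return the top
  index (500) with a `clipped` flag rather than extrapolating; the index
  is only defined to 500.
- **No truncation by default.** Raw concentrations are used for lookup.
  Regulatory practice sometimes truncates to fixed decimals first;
  `usepa_truncation=True` enables that, but silent precision loss is not
  a default.

An ideal-gas ppm ↔ µg/m³ converter (default 25 °C, 101.325 kPa) is
provided for unit reconciliation; it is not applied implicitly.

## Daily aggregation and the completeness rule

PM10, NO2 and SO2 use the calendar-day 24-h mean; O3 and CO use an 8-h
time average.  The 8-h daily metric is the **maximum** over the 24
rolling 8-h windows anchored in the day (the usual regulatory reading of
an 8-h standard); a plain mean over valid windows is available via
`eight_hour_reduce="mean"`.  Windows may cross midnight by default and a
switch truncates them at the date boundary.

The 75% completeness rule is applied per averaging window: a 24-h mean
requires ≥ 18 present hours, an 8-h window ≥ 6 present hours, and a day
with no valid 8-h window has a missing metric.  Completeness is reported
as present/expected hours for 24-h pollutants and as the best window
completeness for 8-h pollutants, so a reported value always implies
completeness ≥ 0.75.  Averaging is always performed on concentrations
and the AQI conversion applied to the aggregate — AQI values are never
averaged.

## Multiple imputation

Missing daily AQI values are filled by chained equations.  Per chain:
missing cells are initialized by draws from each column's observed
empirical distribution; then, for a fixed number of sweeps, each
incomplete column in turn is regressed (ordinary least squares) on the
other pollutant columns plus calendar covariates, and its missing cells
are replaced by the linear prediction plus a normal residual draw with
the fitted residual standard deviation.  Columns are modelled on the log
scale by default because pollutant series are positively skewed;
non-positive values under the log are shifted by 1e-6 with a warning.
Predictive-mean matching (`method="pmm"`, 5 donors) is available where
normal draws are unsuitable.

Defaults are the conventional m = 5 imputations and 10 sweeps.  Chains
run independently with seeds spawned from one master seed, so identical
configuration yields bit-identical output.  Imputation is per
governorate series (one monitor each), with two annual harmonics and a
weekend indicator as auxiliary predictors.

For the downstream analysis the default combination is the mean of the
m completed exposure values feeding a single analysis dataset, matching
an analysis that works with one merged dataset.  Rubin's rules over
per-dataset fits (`pool_fits`) are provided as the statistically
orthodox alternative; with m completed datasets the pooled variance is
W + (1 + 1/m)·B.

## Disease-activity indices

The DAS-28 calculator evaluates the linear form

    DAS-28 = 0.56·TJC28 + 0.28·SJC28 + 0.70·ln(marker) + 0.014·GH

with TJC28/SJC28 the 28-joint tender/swollen counts, the marker either
ESR (mm/h) or CRP (mg/L) — same coefficients for either — and GH the
patient global health on 0–100.  This is deliberately the *as-written
linear* form rather than the canonical published DAS-28 (which uses
√TJC28 and √SJC28 and different CRP coefficients); the canonical root
form is available with `sqrt_counts=True`.  Consequence: linear-form
scores run higher than canonical DAS-28 values and the familiar clinical
cutoffs do not transfer automatically.  A marker of 0 is an error (the
log is undefined and no offset convention is adopted).

CDAI is the exact sum TJC28 + SJC28 + PaGH + PrGH (range 0–76) with both
global assessments on 0–10.

Activity banding (remission/low/moderate/high) ships with the
conventional literature cutoffs (DAS-28: 2.6/3.2/5.1; CDAI: 2.8/10/22)
as configurable defaults; they are external conventions, not derived
quantities.

## Linkage

Visits join exposure on exact (date, governorate) — the patient's home
governorate, each served by one monitoring station.  There is no
nearest-day fallback.  Exposure rows that are entirely missing after
imputation are treated as absent.  Dropped visits are counted with
reasons in a `LinkageReport`; duplicate exposure keys are an error
because the match would be ambiguous.

## Correlation screen and model ladder

The Pearson screen uses pairwise-complete observations with two-sided
p-values and star codes at p < 0.1 / 0.05 / 0.01 / 0.001 (strict
inequalities at the band edges).  No multiplicity correction is applied
by default; a Bonferroni adjustment can be made externally from the
reported p-values.

The ladder fits, per response (DAS-28 or CDAI):

- **M1** gender, disease duration, nationality, governorate, comorbidity;
- **M2** M1 + treatment class, swollen and tender counts, RF, ACPA,
  patient and physician global assessments, ESR, CRP;
- **M3** the five pollutant AQI series;
- **M4** pollutants + swollen count, RF, ACPA, ESR, CRP.

Fits are ordinary least squares with listwise deletion (deleted rows are
counted), fixed governorate dummies with Ahmadi as the reference level,
and reference levels female / Kuwaiti / no comorbidity / biologics /
seronegative for the other categoricals.  Intervals are normal-theory
Wald 95% CIs.  Deviance is −2·log-likelihood under normal errors, so
nested fits on identical rows admit a likelihood-ratio test (reported
with its degrees of freedom); non-nested comparisons report the deviance
difference only.  A random governorate intercept (REML) is available
behind a flag but the fixed-dummy ladder is the default because that is
what the staged specification expresses.  Predictors enter on the raw
AQI scale by default; log-scale predictors are a caller-side transform
rather than a hidden flag, since mixing scales silently would change the
meaning of "per AQI unit" effects.

## Synthetic generator

### Exposure

Daily AQI values per (day, governorate) are drawn from a multivariate
lognormal specified entirely by declared calibration targets:

- marginal daily-AQI mean/SD per pollutant, default
  PM10 144.87 ± 100.64, NO2 43.74 ± 23.13, SO2 14.26 ± 15.42,
  O3 17.19 ± 9.90, CO 1.39 ± 0.66 (the observed exposure distribution
  the generator emulates);
- pairwise daily-AQI Pearson correlations, default the observed
  pollutant correlation block (NO2–SO2 0.51, NO2–CO 0.22, NO2–O3 −0.12,
  …);
- per-pollutant daily missing fractions, default 5.8% (PM10), 1.6%
  (NO2), 48.4% (SO2), 5.3% (O3), 6.5% (CO).

Latent log-scale parameters are derived in closed form: lognormal
moment matching for the marginals, and for each pair the
bivariate-lognormal identity

    corr(X_i, X_j) = (exp(ρ_ij σ_i σ_j) − 1) / √((e^{σ_i²}−1)(e^{σ_j²}−1))

inverted for the latent correlation ρ_ij (with a nearest-PD projection
as a safety net; the default targets are already positive definite).  A
4-million-draw check puts the realized NO2–SO2 daily correlation at
0.510 after the breakpoint round trip.

Drawn index values are realized as concentrations through the inverse
breakpoint conversion and expanded to 24 hourly readings, flat by
default (`diurnal_amplitude=0`), optionally shaped by a cosine diurnal
cycle normalized so the daily metric of the shape is exactly 1.
Missingness is masked completely at random as whole-day outages; for the
8-h pollutants an outage extends 7 hours into the next day so that
cross-midnight windows cannot resurrect a masked day.  With the flat
profile, aggregation reproduces the drawn daily values exactly for the
24-h pollutants.  For O3/CO the cross-midnight maximum-window metric can
exceed the drawn level when the following day is higher — a genuine
property of max-window metrics — so experiments that need exact daily
values use `simulate_daily_exposure`, which is the same draw without the
hourly detour.

### Registry

Patients (default 1,651) receive demographics by Bernoulli draws at the
study marginals (female 60.8%, Kuwaiti 58.6%, RF+ 74.6%, ACPA+ 60.5%,
comorbidity 54.6%, biologics 52.8%), a home governorate at the observed
visit shares, and a geometric number of visits truncated to 1–49
(p = 0.167, mean ≈ 6, so ≈ 9,875 visits at the default size).  Clinical
components are drawn from skewed distributions: lognormal ESR
(27.19 ± 21.79 mm/h) and CRP (6.32 ± 4.85 mg/L), zero-inflated geometric
swollen counts (mean 0.7), zero-inflated exponential global assessments.

Outcomes are generated by a linear structural model — the minimal
generative structure under which the M1–M4 ladder is well-specified:

    response = intercept + Σ_k β_k · x_k + ε,   ε ~ N(0, σ²)

with default β set to the observed M4 coefficient columns (DAS-28: NO2
0.003, SO2 0.003, O3 0.003, CO −0.001, PM10 0.00003, swollen 0.226, ESR
0.035, CRP 0.001, RF 0.004, ACPA 0.007; CDAI: NO2 0.048, SO2 0.044, O3
0.039, CO 0.185, PM10 0.0004, swollen 3.035, ESR 0.085, CRP −0.171, RF
−0.066, ACPA −0.594).  Because the indices are deterministic functions
of their components, the planted model is realized by *solving the index
equation* for the tender-joint count: for DAS-28,
TJC28 = (y − 0.28·SJC28 − 0.70·ln ESR − 0.014·GH)/0.56 plus an
independent gamma baseline; for CDAI the target total is allocated
exactly across TJC28 + PaGH + PrGH, whose combined 0–48 range absorbs
the integer rounding of the count.

Three deliberate compromises follow from this construction:

- **One planted response per dataset.** DAS-28 and CDAI share
  components, so planting both linear models exactly in one registry is
  overdetermined; `planted_response` selects which index carries the
  exact structure (the other remains computable but unstructured).
- **Tender-joint baseline.** The gamma baseline (mean 7, SD 2) keeps the
  solved counts inside 0–28 with probability > 99.5%; clipping would
  otherwise attenuate the planted slopes.  The cost is that synthetic
  tender counts and index levels run higher than the emulated registry's
  means — the published marginals and the published effect sizes cannot
  all hold simultaneously under an exact structural model, and the
  effect sizes are what the recovery experiments measure.
- **Noise scale.** σ defaults to 0.9 DAS-28 units and 2.0 CDAI units,
  chosen so the structural solve stays in range; the planted coefficient
  vector, not the error variance, is the recovery target.

### What the generator does not emulate

No spatial field (one independent series per governorate), no
autocorrelation or seasonality in exposure beyond the optional diurnal
cycle, no within-patient trajectory in the clinical components, and
missingness is MCAR only.  Passing recovery tests therefore show that
the estimation chain is correct and unbiased under the assumed data
model — not that the assumed model captures every feature of real
monitor streams or registries (in particular, MNAR missingness and
exposure autocorrelation could bias real-data estimates in ways these
tests do not probe).

## Validation experiments and problem sizes

The replicated experiments (`aqra.experiments`) use five years of daily
exposure across six governorates and registries of ≈ 9,875 visits — the
emulated study's own scale: 50 replicates for coefficient recovery
(asserted within 3 Monte-Carlo standard errors of the planted value),
500 replicates of ≈ 2,000 visits for null CI coverage (95% ± 2%), and
10,000 days for the correlation calibration (± 0.03).  Recovery
experiments draw exposure without outages so they measure the estimator
rather than compounding it with imputation error; imputation quality has
its own test battery (observed-cell preservation, MCAR unbiasedness,
between-imputation variance behaviour).

## Numerical conventions

Degenerate inputs fail loudly: negative or non-finite concentrations,
markers ≤ 0, out-of-range joint counts, duplicate exposure keys,
rank-deficient designs (with the aliased columns named) and constant
columns in the correlation screen all raise with specific messages.
Ties at breakpoint boundaries belong to the lower row (both ends of a
segment are inclusive, checked exhaustively).  All randomness flows from
`numpy` `SeedSequence` spawns of a single seed per component, so every
table the pipeline writes is a pure function of (inputs, config, seed);
reruns are byte-identical.
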