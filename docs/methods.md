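# Methods

This note documents the models, parameter choices, and numerical
decisions behind `aerodyn`, and what the synthetic tests do and do not
establish about real monitoring data.

## Absolute abundance

Sequencing gives compositions; qPCR gives totals.  The bacterial fraction
of a library is `reads_bacterial / total_reads` (chloroplast,
mitochondrial and other non-bacterial amplicons in the denominator), and
absolute abundance is `log10(total_copies × fraction)`.  A zero fraction
is flagged missing rather than mapped to −∞.  Samples are binned into ISO
calendar weeks and averaged **on the log10 scale**, matching the
log-transformation applied before all downstream statistics; whether
duplicate same-week samples should instead be averaged on the linear
scale is unknowable from summary data, and the log choice keeps weekly
values consistent with the fitted quantities.

Gap filling distinguishes gap length.  Runs of ≥ 3 missing weeks (a
seasonal interruption such as a monsoon) are filled with the mean of the
same ISO week in the other observed years — this only makes sense when
the seasonal cycle repeats across years, which the harmonic analysis
itself assumes.  Shorter gaps are linearly interpolated.  Every filled
point carries a provenance tag (`measured`, `seasonal_average`,
`linear_interpolated`), so downstream users can exclude imputed points.

## Weekly imputation and outlier correction

Remaining weekly gaps are filled by the causal weighted moving average

    x_t = (1/6) x_{t−3} + (1/3) x_{t−2} + (1/2) x_{t−1},

swept forward so earlier imputations feed later ones.  The weights sum to
one (constant series are fixed points); on a linear ramp the fill equals
`t − 5/3`.  Leading missing values are back-filled from the first
observation — the sweep needs a starting state and any constant
extrapolation is as defensible as another for at most a few points.

Outliers are points deviating from a centred rolling median (window 9) by
more than `k = 4` robust standard deviations (1.4826 × rolling MAD; the
local MAD is floored at the series-wide MAD because it collapses to zero
near smooth extrema).  Flagged points are replaced by the same WMA
formula.  Window, `k`, and the detection rule are package choices — only
the replacement formula is inherited from the imputation scheme.

## Annual harmonic model

`Y = a·sin(2πt) + b·cos(2πt) + c` with `t` in years (52.18 weeks/year).
An intercept is always included even though the textbook form omits it:
abundance and PM10 series have large positive means, and fitting without
an intercept would fold the mean into the harmonic coefficients and
corrupt both amplitude and phase.  R² is reported against the mean-only
model and the p-value is the F-test of the two harmonic terms.  The fit
is applied to the raw imputed weekly series rather than to a
decomposition component; the decomposition is kept as a diagnostic.

Phase lag between two fits is `Δφ = φ_y − φ_x` wrapped to (−π, π], scaled
to weeks.  Because the fitted maximum of `A·sin(2πt + φ)` occurs at
`t = (π/2 − φ)/2π`, a positive value means the **first** series peaks
later in the annual cycle: `phase_lag(local, desert) > 0` ⇔ the local
cycle trails the desert cycle.  Identical fits give 0; sine vs cosine
gives a quarter period (≈13.0 weeks).  The phase is undefined (error)
when either amplitude is below tolerance.

The single-harmonic phase difference has a sampling SD of
`√((1−R²)/(n·R²))` radians per series; at R² ≈ 0.3 and n ≈ 157 weekly
points that is ≈1 week per series, so a two-series lag estimate carries
±1.5 weeks of noise.  The pipeline therefore also reports a
**cross-correlation lag**: the integer weekly shift maximising the
Pearson correlation between the desert and local series.  It exploits the
episodic dust spikes, which travel with the same delay, and recovers a
configured 4-week delay essentially deterministically at realistic noise.

Spectra are discrete Fourier periodograms (mean removed, density
scaling, frequencies in cycles/year); decomposition is the classical
additive scheme (centred moving-average trend, re-centred
period-position seasonal means, residual remainder).

## Dust events

Boundary semantics are strict on both axes: exceedance is `> threshold`
and duration is *more than* `min_hours` (an exactly-two-hour exceedance
of 150 µg·m⁻³ is not an event).  Exceedance runs separated by less than
12 h merge into one episode before the duration test — fragmented
exceedances of one synoptic event should not count twice.  Spikes are
strict daily exceedances of 45.0 µg·m⁻³ restricted to desert-origin
(pathway A) days, with official-event days excluded so the two effect
estimates partition the episodes.

Event effects are `during/before × 100` on **linear** abundance.  The
printed aggregate for ratios 5.2/9.1/2.7/4.8 is 545%, i.e. mean ratio ×
100, *not* (ratio − 1) × 100 — the wording "increased by 545%" would
suggest otherwise, but only the former reproduces the arithmetic, so that
is what `effect_summary_from_ratios` implements.  Windows are
configurable (default: 7 days before/after, during = event span widened
to ≥ `min_during_days` when sampling is sparser than the event).  The
before-vs-during test is a two-sided paired t on per-event log10 window
means (Wilcoxon optional); identical vectors return p = 1.

A caveat the synthetic experiments make explicit: the mean of per-event
ratios is a ratio of noisy window means, and when the non-event
variability between adjacent windows is large on the log scale the
aggregate mean inflates (a lognormal-mean effect).  Recovery tests
therefore run at reduced background noise, where the estimator is
calibrated; at full noise the per-event scatter is large — of the same
order as the huge spread that real spike effects exhibit.

## Dust-immigration index

AQI → PM10 inversion interpolates linearly through the flattened
breakpoint nodes of a table shipped as editable YAML data (default: US
EPA PM10 breakpoints, since the exact conversion table used by any given
study is configuration, not code).  The unit gaps between integer-bounded
rows are bridged linearly so the map is continuous and exactly invertible
across the whole span.  Daily pathway-A frequency is the fraction of that
day's (typically 12, 2-hourly) trajectory labels equal to A.  The index
is `desert PM10 × frequency`, smoothed with a **trailing** 4-day moving
average — causal, because the index feeds same-day model indicators; a
centred option exists.  Three desert regions each yield one indicator
(`rd_horqin`, `rd_gobi`, `rd_taklimakan`).

## Correlation network

Monthly aggregation, pairwise-complete Spearman ρ with average ranks and
t-approximation p-values (≥ 4 complete pairs required; constant variables
undefined).  Collinearity pruning is a greedy scan in column order at
|ρ| > 0.8 applied to the *environmental* variables only — the focal
population/PM variables always enter the network, mirroring how
multicollinearity screening is applied to candidate covariates rather
than to the variables under study.  Edges are kept at raw P < 0.05 with
no multiple-testing correction (deliberate: the network is exploratory
and the original filtering rule is preserved); module detection is greedy
modularity maximisation on the positive-|ρ|-weighted subgraph (negative
edges kept for display), deterministic under sorted node order.  The ego
subnetwork keeps focal nodes plus direct neighbours and removes
environment–environment edges.

## Structural equation model

RAM formulation over 8 observed + 3 latent variables.  Identification:
exogenous latent variances fixed at 1 and the endogenous disturbance
variance fixed at 1 (rather than marker loadings), so every loading and
path is free and the standardized solution follows by rescaling with the
model-implied variances.  Free parameters: 8 loadings, 2 paths, 1 latent
covariance, 8 residual variances → df = 36 − 19 = 17.

Estimation minimises the Wishart ML discrepancy with L-BFGS-B from
documented start values (loadings 0.5 × expected sign, paths 0.3,
covariance 0.2, residuals = half the sample variances), 5 jittered
restarts seeded from the config, residuals bounded below at 1e-6 (a
solution at the floor is flagged as a Heywood case, not rejected), and
the latent covariance bounded in (−1, 1) since the exogenous latents have
unit variance.  χ² = (n−1)·F_min.  TLI and RMSEA use the diagonal-Σ
independence baseline and the (n−1) RMSEA denominator (conventions
differ; this one is stated so results are comparable).  SRMR averages
squared sample-vs-implied residuals in the correlation metric over the
p(p+1)/2 unique elements, diagonal included.  TLI may exceed 1 when
χ² < df; the TLI = 1 limit corresponds to χ² = df exactly.  Missing rows
are dropped listwise.

In the pipeline, the immigration indicators are shifted by the estimated
transport lag before fitting (they are measured at the source; the model
pairs them with the week the dust arrives), and weeks inside detected
official dust episodes — from the arrival week back through the lagged
desert-side window — are excluded, implementing outlier removal before
structural modelling.  Without this exclusion the multiplicative event
spikes, which bypass the linear latent structure, inflate the dispersal
path.

## Synthetic world

Latents are unit-variance sums of an annual harmonic and AR(1) noise on a
daily grid: local generation LG peaks mid-January (seasonal share 0.15 —
a modest U-shape riding on synoptic variability), regional dispersal RD
peaks mid-April (share 0.45, sized so desert PM10 shows a seasonal
variance fraction near 0.38).  Weekly noise autocorrelation is 0.3
(synoptic weather decorrelates in days).  The aerosol latent is
`LA ∝ 0.51·LG + 0.35·RD(t − lag) + 0.62·ζ` with lag = 4 weeks; the LG
noise is correlated with the *lagged* RD noise so the configured LG↔RD
covariance (0.64) describes local conditions and dust as it arrives —
this is what lets a contemporaneous latent covariance coexist with a
transport delay.  Indicators are linear in their latent with independent
Gaussian noise; measurement loadings follow the standardized aerosol
model (humidity −0.99, pressure 0.59, cloud −0.55; immigration 0.92–0.95)
except the two LA indicators (0.95, 0.80): the published outcome loadings
(0.45, 0.43) would leave the generated abundance with ≈2% seasonal
variance, incompatible with the ~33% seasonal fit the same data display,
so the generator favours a signal-bearing outcome and treats the low
published loadings as attenuation it does not reproduce.  The related
incompatibility — a winter LG harmonic of full strength would drag the
abundance phase weeks away from the observed 4-week desert lag — is why
phase-calibration tests use the `abundance_seasonal_share` override, in
which abundance is mean + `√share`·(lagged transport harmonic) +
`√(1−share)`·noise, with the share defined on the weekly-aggregated
series.

Events: Poisson (1.5/yr) days in Feb–May boost desert PM10 ×5 on the
emission day and local PM10/abundance ×5 over a 3-day arrival window 4
weeks later; the hourly stream (which exists solely for official-event
detection) carries the exceedance episode on the arrival day.
Compositions are multinomial (20 000 reads) with a Gaussian-bump
chloroplast fraction peaking mid-April at 0.75, reproducing the spring
collapse of the bacterial read share (~20–25%).  Missingness: 1% random
sequencing dropouts plus a monsoon block (30 May–11 Aug of year one),
together ≈22 of ≈315 samples.  Pathway-A probability is a winter-peaking
cosine (0.05–0.45, July minimum).  All randomness flows from one seeded
generator; identical configs give bit-identical worlds.

What the generator does **not** emulate: heavy-tailed PM10 distributions,
autocorrelated measurement error, drifting baselines (e.g. multi-year
emission trends), trajectory geometry, or sequence-level features.
Passing recovery tests therefore demonstrates estimator correctness and
calibration under the assumed structure, not performance guarantees on
real monitoring data.

## Problem sizes and reproducibility

Tests and the acceptance script run on 3-year worlds (≈157 weekly bins,
≈313 samples, 26 304 hourly points); Monte-Carlo suites use 15–100 worlds
or 50–500 simulated SEM data sets at n = 500–5000 — sizes chosen so the
whole suite completes in a few minutes on one CPU while keeping binomial
error on ≥90%-of-seeds assertions small.  Every stochastic component
takes an explicit integer seed; `scripts/acceptance.py --seed N` and the
pipeline are byte-reproducible given the seed.

## Known limitations

- γ (structural path) recovery from 3 years of weekly data is attenuated
  by immigration-indicator distortion (the multiplicative pathway
  frequency) and event-week exclusion; orderings are recovered reliably,
  magnitudes are conservative for RD.
- The harmonic phase lag is a low-precision estimator at realistic
  seasonal shares; prefer the cross-correlation lag when episodic
  structure exists.
- The SEM assumes linear-Gaussian measurement and listwise-complete rows;
  no robust or missing-data estimators are provided.
- No multiple-testing correction in the network stage, by design.
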