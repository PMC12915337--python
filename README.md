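# aerodyn

Tools for analysing multi-year time series of **airborne bacterial
abundance** and untangling where the bacteria come from: local surfaces
(soils, water, vegetation) or long-range dust transport from remote
deserts.  The package is written for microbial ecologists and atmospheric
scientists who have qPCR + amplicon monitoring data (or want to prototype
such an analysis on realistic synthetic data).

## What it computes

**Absolute abundance.**  Universal 16S rRNA primers co-amplify chloroplast
and mitochondrial sequences, so sequencing alone gives only composition.
Each sample's absolute bacterial abundance is

&nbsp;&nbsp;&nbsp;&nbsp;log₁₀( qPCR total copies·m⁻³ × bacterial read fraction )

with missing compositions recovered by same-calendar-week seasonal
averages (long gaps) or linear interpolation (isolated gaps).

**Seasonality and transport lag.**  Weekly series are imputed with the
weighted moving average x_t = ⅙·x_{t−3} + ⅓·x_{t−2} + ½·x_{t−1}, outlier
corrected, and fitted to the annual harmonic

&nbsp;&nbsp;&nbsp;&nbsp;Y = a·sin(2πt) + b·cos(2πt) + c,&nbsp;&nbsp; t in years,

with amplitude √(a²+b²) and phase atan2(b, a).  Phase differences between
fitted cycles, and a cross-correlation scan that also uses episodic dust
spikes, estimate how many weeks the local aerosol trails desert dust
production.  A periodogram and classical additive decomposition verify
the annual periodicity.

**Dust events.**  Official Asian-dust events (hourly PM10 > 150 µg·m⁻³
for more than two consecutive hours) and desert-origin PM10 spikes
(daily PM10 > 45.0 µg·m⁻³ on back-trajectory pathway A) are detected, and
each event's effect is the ratio of mean linear abundance during vs
before the event, ×100 (an unchanged population reads 100%).

**Dust immigration.**  Desert-station AQI values invert to PM10 through a
piecewise-linear breakpoint table; PM10 × daily pathway-A frequency,
smoothed with a 4-day moving average, gives one dust-immigration
indicator per desert region (Horqin, Gobi, Taklimakan).

**Correlation network.**  Spearman correlations of monthly aggregates
(pairwise complete, |ρ| > 0.8 collinearity pruning among environmental
variables, edges kept at P < 0.05) with greedy-modularity communities and
a focal subnetwork around abundance / local PM10 / desert PM10;
Cytoscape-compatible SIF/GraphML export.

**Structural equation model.**  A from-scratch maximum-likelihood SEM
implements **LA = LG + RD**: the local-aerosol latent (indicators: log
abundance, local PM10) regressed on local generation (humidity, pressure,
cloud cover) and regional dispersal (three immigration indices), with a
free LG↔RD covariance.  The implied covariance uses the RAM form
Σ(θ) = F(I−A)⁻¹S(I−A)⁻ᵀFᵀ, the fit minimises
F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p, χ² = (n−1)·F_min, and TLI, RMSEA and
SRMR summarise fit.  Estimates are reported as the standardized solution.

A seeded **synthetic-world generator** reproduces the statistical
structure of such a campaign (winter-peaking local generation,
spring-peaking desert dispersal with a configurable ~4-week transport
delay, multiplicative dust events, spring chloroplast surge, monsoon
missingness) with full ground truth, so every stage is testable without
any downloads.

## Worked example

```bash
python examples/07_full_pipeline.py
```

prints (seed 1):

```
abundance: 4.56 +/- 0.73 log10 copies/m^3
transport lag (cross-correlation): 4 weeks
harmonic R2: abundance 0.16, desert_pm10 0.62, local_pm10 0.16
network: 9 edges; focal trio in one module: True
events: 6 official, 55 spikes
SEM: LA<-LG 0.71, LA<-RD 0.13; indices {'tli': 1.000073845475155, 'rmsea': 0.0, 'srmr': 0.023536873309708106}
```

The 4-week cross-correlation lag recovers the generator's configured
desert→local transport delay; the focal trio (abundance, local PM10,
desert PM10) sharing one network module shows the dust-transport coupling;
and the positive LA←LG > LA←RD ordering matches the configured structural
paths.  `examples/04_dust_events.py` additionally reproduces the worked
event arithmetic: per-event during/before ratios 5.2, 9.1, 2.7, 4.8
aggregate to **545% ± 267%** (range 270–910%).

Other examples cover each capability separately (world simulation,
absolute abundance, seasonality/lag, events, immigration, SEM).  A thin
CLI wraps the pipeline: `aerodyn simulate`, `aerodyn run`, `aerodyn sem`.

## Layout

```
src/aerodyn/      abundance, timeseries, network, events, immigration,
                  sem, synthetic, pipeline, cli
examples/         one narrative script per capability
tests/            pytest suite incl. acceptance tests
docs/methods.md   models, parameters, design choices, limitations
```
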