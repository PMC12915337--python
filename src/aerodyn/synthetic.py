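"""Seeded synthetic "world" generator for the airborne-abundance analysis.

The generator builds a multi-year coastal monitoring record with the
statistical structure the analysis pipeline assumes, together with the
ground truth needed for recovery tests:

* a *local generation* latent (LG): a winter-peaking annual harmonic plus
  autocorrelated synoptic noise, expressed through meteorological
  indicators (relative humidity loading negatively, pressure positively,
  cloud cover negatively);
* a *regional dispersal* latent (RD): a spring-peaking annual harmonic
  plus autocorrelated noise, expressed through desert-station PM10 and a
  seasonally varying desert-pathway (A) trajectory frequency, and
  punctuated by springtime dust events;
* a *local aerosol* outcome: bacterial log10 abundance and local PM10 are
  indicators of a latent combining LG and RD, with RD acting through a
  configurable transport delay (default four weeks) - dust leaves the
  desert and arrives downwind a month later, episodic spikes included;
* sequencing compositions whose chloroplast share surges in April-May,
  depressing the bacterial read fraction exactly when total 16S counts
  peak; and
* realistic missingness: a random fraction of samples lack sequencing,
  plus a contiguous monsoon interruption in the first summer.

Everything is drawn from one :class:`numpy.random.Generator` seeded by the
config, so a fixed seed reproduces the world bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .abundance import SampleRecord
from .timeseries import TimeSeries

__all__ = [
    "SemTruth",
    "WorldConfig",
    "SyntheticWorld",
    "RealizedEvent",
    "generate_world",
    "generate_event_episode",
    "write_world_csv",
]

DAYS_PER_YEAR = 365.25
PATHWAYS = ("A", "B", "C", "D", "E")
DESERT_REGIONS = ("horqin", "gobi", "taklimakan")


@dataclass
class SemTruth:
    """Ground-truth measurement and structural coefficients.

    Loadings follow the standardized estimates of the fitted aerosol model:
    humidity/pressure/cloud on LG, three dust-immigration indicators on RD.
    The outcome indicators (abundance, local PM10) use high loadings so the
    generated world carries a clear aerosol signal; the structural paths
    keep local generation dominant (gamma_lg > gamma_rd) with a positive
    LG-RD covariance.
    """

    loadings_lg: tuple[float, float, float] = (-0.99, 0.59, -0.55)
    loadings_rd: tuple[float, float, float] = (0.92, 0.93, 0.95)
    loadings_la: tuple[float, float] = (0.95, 0.80)
    gamma_lg: float = 0.51
    gamma_rd: float = 0.35
    latent_cov: float = 0.64
    disturbance_sd: float = 0.62   # sd of the LA structural disturbance


@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults mirror the study conditions.

    Seasonal structure: LG peaks in mid-January (its U-shape bottoms out in
    summer) and carries ``lg_seasonal_share`` of the latent variance; RD
    peaks in mid-April with a stronger annual cycle, sized so the derived
    desert PM10 series has a seasonal variance fraction near 0.38.  The
    desert-to-local transfer delay is ``lag_weeks``.  ``noise_scale``
    multiplies every stochastic component (1 = nominal, 0 = deterministic
    harmonics), and ``abundance_seasonal_share``, when set, pins the exact
    fraction of weekly abundance variance carried by the lagged transport
    harmonic - the configuration used for seasonal-fit calibration tests.
    """

    n_years: int = 3
    start: str = "2019-01-01"
    seed: int = 0

    # latent seasonal structure
    lg_seasonal_share: float = 0.15
    rd_seasonal_share: float = 0.45
    lg_peak: float = 0.04           # fraction of year, mid-January
    rd_peak: float = 0.288          # mid-April
    lag_weeks: float = 4.0
    ar_rho_weekly: float = 0.3      # weekly autocorrelation of latent noise

    sem_truth: SemTruth = field(default_factory=SemTruth)

    # events
    event_rate: float = 1.5         # expected events/year, drawn in Feb-May
    event_magnitude: float = 5.0    # multiplicative PM10/abundance boost
    event_duration_hours: tuple[int, int] = (4, 9)

    # channels
    abundance_mean: float = 4.6     # log10 copies/m^3
    abundance_sd: float = 0.8
    local_pm10_mean: float = 34.0
    local_pm10_sd: float = 9.0
    desert_pm10_mean: float = 60.0
    desert_pm10_sd: float = 35.0
    humidity_mean: float = 65.0
    humidity_sd: float = 15.0
    pressure_mean: float = 1015.0
    pressure_sd: float = 6.0
    cloud_mean: float = 5.0
    cloud_sd: float = 2.5
    temperature_mean: float = 15.6
    temperature_sd: float = 8.0
    temperature_peak: float = 0.56  # late July

    # compositions
    total_reads: int = 20000
    chloroplast_base: float = 0.05
    chloroplast_peak_frac: float = 0.75
    chloroplast_peak_doy: float = 105.0   # mid-April
    chloroplast_peak_width: float = 30.0  # days

    # sampling and missingness
    sample_interval_days: float = 3.5
    missing_frac: float = 0.01
    monsoon_gap: tuple[str, str] | None = ("2019-05-30", "2019-08-11")
    event_local_days: int = 3      # days the arriving dust stays aloft

    # overrides
    noise_scale: float = 1.0
    abundance_seasonal_share: float | None = None

    def validate(self) -> None:
        if self.n_years < 2:
            raise ValueError("span shorter than 2 full years: annual "
                             "fitting is undefined")
        for frac in (self.lg_seasonal_share, self.rd_seasonal_share,
                     self.missing_frac, self.chloroplast_base,
                     self.chloroplast_peak_frac):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.abundance_seasonal_share is not None and not (
                0 <= self.abundance_seasonal_share <= 1):
            raise ValueError("abundance_seasonal_share must lie in [0, 1]")
        if self.lag_weeks < 0:
            raise ValueError("lag_weeks must be non-negative")
        if self.noise_scale < 0 or self.event_magnitude <= 0:
            raise ValueError("noise_scale >= 0 and event_magnitude > 0 required")


@dataclass
class RealizedEvent:
    """One realized dust episode: desert emission and lagged local arrival."""

    desert_day: pd.Timestamp
    local_start: pd.Timestamp
    local_end: pd.Timestamp
    magnitude: float
    duration_hours: int


@dataclass
class WorldTruth:
    """Config echo plus the realized latent series and events."""

    config: WorldConfig
    dates_daily: pd.DatetimeIndex
    lg_daily: np.ndarray
    rd_daily: np.ndarray
    rd_lagged_daily: np.ndarray
    la_daily: np.ndarray
    events: list[RealizedEvent]


@dataclass
class SyntheticWorld:
    samples: list[SampleRecord]
    hourly_pm10: TimeSeries
    local_pm10_daily: TimeSeries
    desert_pm10: dict[str, TimeSeries]
    meteorology: dict[str, TimeSeries]
    pathway_labels: pd.Series          # 2-hourly trajectory labels
    truth: WorldTruth
    seed: int


def _ar1(n: int, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) noise."""
    innov_sd = np.sqrt(max(1.0 - rho ** 2, 1e-12))
    x = np.empty(n)
    x[0] = rng.normal()
    eps = rng.normal(size=n - 1) * innov_sd
    for t in range(1, n):
        x[t] = rho * x[t - 1] + eps[t - 1]
    return x


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def generate_event_episode(base_pm10: float, magnitude: float,
                           duration_hours: int, decay_hours: int = 6,
                           decay_rate: float = 1.0) -> np.ndarray:
    """Hourly PM10 segment of a dust episode.

    ``duration_hours`` core hours sit at ``base * magnitude``, then the
    concentration relaxes exponentially back toward the base level.  With
    magnitude 1 the segment equals the base throughout.
    """
    if duration_hours < 1:
        raise ValueError("duration must be at least one hour")
    peak = base_pm10 * magnitude
    core = np.full(duration_hours, peak)
    tail = base_pm10 + (peak - base_pm10) * np.exp(
        -decay_rate * np.arange(1, decay_hours + 1))
    return np.concatenate([core, tail])


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a seeded synthetic monitoring record.

    See the module docstring for the generative model.  The same config
    (including seed) always yields a bit-identical world.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ns = config.noise_scale
    truth_sem = config.sem_truth

    start = pd.Timestamp(config.start)
    n_days = int(round(config.n_years * DAYS_PER_YEAR))
    lag_days = int(round(config.lag_weeks * 7))
    dates = pd.date_range(start, periods=n_days, freq="D")
    # extended grid so the lagged latent is defined from day 0
    t_ext = (np.arange(-lag_days, n_days)) / DAYS_PER_YEAR
    rho_daily = config.ar_rho_weekly ** (1.0 / 7.0)

    def latent(share: float, peak: float, noise: np.ndarray) -> np.ndarray:
        seasonal = np.sqrt(2.0 * share) * np.cos(2 * np.pi * (t_ext - peak))
        return seasonal + np.sqrt(max(1.0 - share, 0.0)) * ns * noise

    # Correlated latent noises.  Local generation covaries with regional
    # dispersal *as it arrives* (the dust that left the desert lag_weeks
    # earlier), so the LG noise is correlated with the lagged RD noise;
    # the correlation is sized so the realized LG / lagged-RD covariance
    # approaches the configured latent covariance once the near-orthogonal
    # seasonal parts are added.
    denom = np.sqrt((1 - config.lg_seasonal_share)
                    * (1 - config.rd_seasonal_share))
    rho_noise = np.clip(truth_sem.latent_cov / max(denom, 1e-9), -0.98, 0.98)
    xi = _ar1(len(t_ext), rho_daily, rng)
    rd_ext = latent(config.rd_seasonal_share, config.rd_peak, xi)
    rd = rd_ext[lag_days:]
    rd_lagged = rd_ext[:n_days]         # rd evaluated at t - lag
    xi_lagged = xi[:n_days]

    eta_ind = _ar1(n_days, rho_daily, rng)
    eta = rho_noise * xi_lagged + np.sqrt(1 - rho_noise ** 2) * eta_ind
    t_yr_local = t_ext[lag_days:]
    lg = (np.sqrt(2.0 * config.lg_seasonal_share)
          * np.cos(2 * np.pi * (t_yr_local - config.lg_peak))
          + np.sqrt(max(1.0 - config.lg_seasonal_share, 0.0)) * ns * eta)
    zeta = _ar1(n_days, rho_daily, rng)

    la_raw = (truth_sem.gamma_lg * lg + truth_sem.gamma_rd * rd_lagged
              + truth_sem.disturbance_sd * ns * zeta)
    la_sd = la_raw.std()
    la = la_raw / la_sd if la_sd > 0 else la_raw

    # --- events: drawn in Feb-May each year, felt locally lag_days later
    events: list[RealizedEvent] = []
    for year in range(config.n_years):
        n_ev = rng.poisson(config.event_rate)
        for _ in range(n_ev):
            year_start = start + pd.Timedelta(days=int(round(year * DAYS_PER_YEAR)))
            feb1 = pd.Timestamp(year=year_start.year, month=2, day=1)
            may31 = pd.Timestamp(year=year_start.year, month=5, day=31)
            offset = int(rng.integers(0, (may31 - feb1).days + 1))
            desert_day = feb1 + pd.Timedelta(days=offset)
            dur = int(rng.integers(config.event_duration_hours[0],
                                   config.event_duration_hours[1] + 1))
            local_start = desert_day + pd.Timedelta(days=lag_days)
            events.append(RealizedEvent(
                desert_day=desert_day, local_start=local_start,
                local_end=local_start
                + pd.Timedelta(days=config.event_local_days - 1),
                magnitude=config.event_magnitude, duration_hours=dur))
    events.sort(key=lambda e: e.desert_day)
    desert_event = np.zeros(n_days, dtype=bool)
    local_event = np.zeros(n_days, dtype=bool)
    day_index = pd.Series(np.arange(n_days), index=dates)
    for ev in events:
        if ev.desert_day in day_index.index:
            desert_event[day_index[ev.desert_day]] = True
        for k in range(config.event_local_days):
            day = ev.local_start + pd.Timedelta(days=k)
            if day in day_index.index:
                local_event[day_index[day]] = True

    def indicator(latent_series, loading, mean, sd, clip_low=None):
        noise = np.sqrt(max(1 - loading ** 2, 0.0)) * ns * rng.normal(size=n_days)
        x = mean + sd * (loading * latent_series + noise)
        if clip_low is not None:
            x = np.maximum(x, clip_low)
        return x

    # --- meteorology (LG indicators plus context variables)
    lam_h, lam_p, lam_c = truth_sem.loadings_lg
    met = {
        "humidity": indicator(lg, lam_h, config.humidity_mean,
                              config.humidity_sd, clip_low=5.0),
        "pressure": indicator(lg, lam_p, config.pressure_mean,
                              config.pressure_sd),
        "cloud": indicator(lg, lam_c, config.cloud_mean, config.cloud_sd,
                           clip_low=0.0),
    }
    t_yr = t_ext[lag_days:]
    temp_season = np.cos(2 * np.pi * (t_yr - config.temperature_peak))
    met["temperature"] = (config.temperature_mean
                          + config.temperature_sd * temp_season
                          + 2.5 * ns * rng.normal(size=n_days))
    met["precipitation"] = np.maximum(
        0.0, rng.exponential(3.0, size=n_days)
        * (1.0 + 1.5 * np.clip(temp_season, 0, None)) - 2.0) * ns

    # --- desert PM10 per region (RD indicators at the source)
    desert = {}
    for region, lam in zip(DESERT_REGIONS, truth_sem.loadings_rd):
        x = indicator(rd, lam, config.desert_pm10_mean,
                      config.desert_pm10_sd, clip_low=2.0)
        x = np.where(desert_event, x * config.event_magnitude, x)
        desert[region] = x

    # --- local PM10 (LA indicator), daily then hourly
    lam_ab, lam_pm = truth_sem.loadings_la
    local_pm = indicator(la, lam_pm, config.local_pm10_mean,
                         config.local_pm10_sd, clip_low=2.0)
    local_pm_event = np.where(local_event, local_pm * config.event_magnitude,
                              local_pm)

    hourly = np.repeat(local_pm, 24) + 3.0 * ns * rng.normal(size=n_days * 24)
    hourly = np.maximum(hourly, 1.0)
    for ev in events:
        if ev.local_start not in day_index.index:
            continue
        d = int(day_index[ev.local_start])
        base = max(local_pm[d], 1.0)
        segment = generate_event_episode(base, ev.magnitude, ev.duration_hours)
        h0 = d * 24 + int(rng.integers(8, 15))
        h1 = min(h0 + len(segment), n_days * 24)
        hourly[h0:h1] = segment[:h1 - h0]

    # --- trajectory pathway labels, 12 per day at 2-h intervals
    p_a = np.clip(0.25 + 0.20 * np.cos(2 * np.pi * (t_yr - config.lg_peak)),
                  0.02, 0.95)
    p_a = np.where(local_event | desert_event, 0.9, p_a)
    label_times = pd.date_range(start, periods=n_days * 12, freq="2h")
    p_rep = np.repeat(p_a, 12)
    is_a = rng.random(n_days * 12) < p_rep
    others = rng.choice(np.array(PATHWAYS[1:]), size=n_days * 12)
    labels = pd.Series(np.where(is_a, "A", others), index=label_times,
                       name="pathway")

    # --- abundance samples every sample_interval_days
    offsets = np.unique(np.round(np.arange(0, n_days - 0.5,
                                           config.sample_interval_days))
                        .astype(int))
    sample_days = offsets[offsets < n_days]
    if config.abundance_seasonal_share is not None:
        # the share is defined on the weekly-aggregated series the analysis
        # fits, so per-sample noise is inflated by the number of samples a
        # week averages over
        sh = config.abundance_seasonal_share
        rd_seas_lag = np.cos(2 * np.pi * (t_ext[:n_days] - config.rd_peak))
        seas = _standardize(rd_seas_lag[sample_days])
        per_week = max(7.0 / config.sample_interval_days, 1.0)
        noise = rng.normal(size=len(sample_days)) * np.sqrt(per_week)
        log_bact = (config.abundance_mean + config.abundance_sd
                    * (np.sqrt(sh) * seas + np.sqrt(1 - sh) * noise))
    else:
        noise = np.sqrt(max(1 - lam_ab ** 2, 0.0)) * ns \
            * rng.normal(size=len(sample_days))
        log_bact = (config.abundance_mean + config.abundance_sd
                    * (lam_ab * la[sample_days] + noise))
    boost = local_event[sample_days]
    log_bact = log_bact + np.log10(config.event_magnitude) * boost

    doy = dates.dayofyear.to_numpy()[sample_days].astype(float)
    bump = np.exp(-((doy - config.chloroplast_peak_doy)
                    / config.chloroplast_peak_width) ** 2)
    frac_chl = config.chloroplast_base + (config.chloroplast_peak_frac
                                          - config.chloroplast_base) * bump
    frac_other = 0.02
    frac_bact = np.clip(1.0 - frac_chl - frac_other, 0.01, 1.0)

    # sequencing missingness: random plus the monsoon block
    no_seq = rng.random(len(sample_days)) < config.missing_frac
    if config.monsoon_gap is not None:
        g_lo, g_hi = (pd.Timestamp(config.monsoon_gap[0]),
                      pd.Timestamp(config.monsoon_gap[1]))
        sdates = dates[sample_days]
        no_seq |= np.asarray((sdates >= g_lo) & (sdates <= g_hi))

    samples = []
    for k, d in enumerate(sample_days):
        total = 10.0 ** log_bact[k] / frac_bact[k]
        if no_seq[k]:
            samples.append(SampleRecord(
                date=dates[d], total_copies=total, has_sequencing=False))
            continue
        probs = np.array([frac_bact[k], frac_chl[k], frac_other / 2,
                          frac_other / 2])
        reads = rng.multinomial(config.total_reads, probs / probs.sum())
        samples.append(SampleRecord(
            date=dates[d], total_copies=total,
            reads_bacterial=int(reads[0]), reads_chloroplast=int(reads[1]),
            reads_mito=int(reads[2]), reads_other=int(reads[3])))

    ts = lambda arr, name, units="": TimeSeries(start, 1.0, arr, name=name,
                                                units=units)
    truth = WorldTruth(config=config, dates_daily=dates, lg_daily=lg,
                       rd_daily=rd, rd_lagged_daily=rd_lagged, la_daily=la,
                       events=events)
    return SyntheticWorld(
        samples=samples,
        hourly_pm10=TimeSeries(start, 1.0 / 24.0, hourly,
                               name="local_pm10_hourly", units="ug/m^3"),
        local_pm10_daily=ts(local_pm_event, "local_pm10", "ug/m^3"),
        desert_pm10={r: ts(v, f"desert_pm10_{r}", "ug/m^3")
                     for r, v in desert.items()},
        meteorology={k: ts(v, k) for k, v in met.items()},
        pathway_labels=labels,
        truth=truth,
        seed=config.seed,
    )


def write_world_csv(world: SyntheticWorld, outdir) -> None:
    """Dump every generated table as CSV, with the truth as YAML alongside."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "date": s.date, "total_copies": s.total_copies,
        "reads_bacterial": s.reads_bacterial,
        "reads_chloroplast": s.reads_chloroplast,
        "reads_mito": s.reads_mito, "reads_other": s.reads_other,
        "has_sequencing": s.has_sequencing,
    } for s in world.samples]).to_csv(outdir / "samples.csv", index=False)

    daily = pd.DataFrame({"date": world.truth.dates_daily})
    daily["local_pm10"] = world.local_pm10_daily.values
    for region, s in world.desert_pm10.items():
        daily[f"desert_pm10_{region}"] = s.values
    for name, s in world.meteorology.items():
        daily[name] = s.values
    daily.to_csv(outdir / "daily.csv", index=False)

    world.hourly_pm10.to_pandas().rename("pm10").rename_axis("time") \
        .to_csv(outdir / "hourly_pm10.csv")
    world.pathway_labels.rename_axis("time") \
        .to_csv(outdir / "pathway_labels.csv")

    truth = {
        "seed": world.seed,
        "config": _config_dict(world.truth.config),
        "events": [{
            "desert_day": str(ev.desert_day.date()),
            "local_start": str(ev.local_start.date()),
            "magnitude": ev.magnitude,
            "duration_hours": ev.duration_hours,
        } for ev in world.truth.events],
    }
    with open(outdir / "truth.yaml", "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=False)
    pd.DataFrame({
        "date": world.truth.dates_daily,
        "lg": world.truth.lg_daily,
        "rd": world.truth.rd_daily,
        "rd_lagged": world.truth.rd_lagged_daily,
        "la": world.truth.la_daily,
    }).to_csv(outdir / "truth_latents.csv", index=False)


def _config_dict(config: WorldConfig) -> dict:
    d = asdict(config)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d
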