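"""End-to-end orchestration of the airborne-abundance analysis.

``run_full_analysis`` chains the stages in their natural order - absolute
abundance assembly, weekly imputation, harmonic/spectral seasonality,
monthly correlation network, dust-event effects, dust-immigration
construction, and the structural equation model - on either a generated
synthetic world or CSV inputs, and emits one JSON report plus CSV/SIF/
GraphML side files.  Every stochastic choice descends from the config
seed, so a fixed config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import abundance as ab
from . import events as ev
from . import immigration as im
from . import network as nw
from . import sem as sm
from . import timeseries as tsm
from .synthetic import WorldConfig, SyntheticWorld, generate_world
from .timeseries import TimeSeries

log = logging.getLogger("aerodyn")

__all__ = ["AnalysisConfig", "run_full_analysis", "report_to_json"]

FOCAL_VARIABLES = ["abundance", "local_pm10", "desert_pm10"]

NODE_CLASSES = {
    "abundance": "population",
    "local_pm10": "PM",
    "desert_pm10": "PM",
    "temperature": "meteorology",
    "humidity": "meteorology",
    "pressure": "meteorology",
    "cloud": "meteorology",
    "precipitation": "meteorology",
    **{f"pathway_{p}": "pathway" for p in "ABCDE"},
}


@dataclass
class AnalysisConfig:
    """All analysis constants in one place (defaults = study settings)."""

    world: WorldConfig = field(default_factory=WorldConfig)
    alpha: float = 0.05
    collinearity_threshold: float = 0.8
    event_threshold: float = 150.0      # ug/m^3 hourly
    spike_threshold: float = 45.0       # ug/m^3 daily
    window_days: int = 7
    smooth_days: int = 4
    gap_threshold_weeks: int = 3
    outlier_k: float = 4.0
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        for thr in (self.event_threshold, self.spike_threshold,
                    self.smooth_days, self.window_days):
            if thr <= 0:
                raise ValueError("thresholds and windows must be positive")
        self.world.seed = self.seed

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _weekly_mean(ts: TimeSeries, name: str,
                 grid: pd.DatetimeIndex | None = None) -> TimeSeries:
    """Bin a series into ISO calendar weeks (Monday anchored).

    Supplying ``grid`` aligns the result to an existing weekly grid so all
    weekly series in the analysis share one calendar.
    """
    s = ts.to_pandas()
    monday = s.index - pd.to_timedelta(s.index.dayofweek, unit="D")
    weekly = s.groupby(monday.floor("D")).mean()
    if grid is None:
        grid = pd.date_range(weekly.index.min(), weekly.index.max(), freq="7D")
    weekly = weekly.reindex(grid)
    return TimeSeries(grid[0], 7.0, weekly.to_numpy(), name=name,
                      units=ts.units)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage=%s elapsed=%.2fs", name, time.perf_counter() - t0)
            return out
        return inner
    return wrap


@_stage("abundance")
def _abundance_stage(world: SyntheticWorld, config: AnalysisConfig):
    weekly = ab.aggregate_weekly(world.samples)
    filled = ab.fill_missing_composition(
        weekly, gap_threshold=config.gap_threshold_weeks)
    ts = filled.to_timeseries("log10_bacterial")
    ts = tsm.impute_wma(ts)
    ts.name = "abundance"
    return filled, ts


@_stage("seasonality")
def _seasonality_stage(abund_ts, desert_weekly, local_weekly, config):
    series = {"abundance": abund_ts, "desert_pm10": desert_weekly,
              "local_pm10": local_weekly}
    fits, monthly = {}, {}
    for name, ts in series.items():
        ts_f = tsm.impute_wma(ts)
        ts_f, _ = tsm.correct_outliers(ts_f, k=config.outlier_k)
        fits[name] = tsm.fit_harmonic(ts_f)
        monthly[name] = tsm.aggregate_monthly(ts_f)
        series[name] = ts_f
    lags = {
        "abundance_vs_desert": tsm.phase_lag(fits["abundance"],
                                             fits["desert_pm10"]),
        "local_pm10_vs_desert": tsm.phase_lag(fits["local_pm10"],
                                              fits["desert_pm10"]),
    }
    tau_ab, r_ab = tsm.cross_correlation_lag(series["desert_pm10"],
                                             series["abundance"])
    tau_pm, r_pm = tsm.cross_correlation_lag(series["desert_pm10"],
                                             series["local_pm10"])
    transport = {
        "abundance_lag_weeks": tau_ab, "abundance_lag_corr": r_ab,
        "local_pm10_lag_weeks": tau_pm, "local_pm10_lag_corr": r_pm,
    }
    spectrum = tsm.periodogram(series["abundance"])
    trend, seasonal, resid = tsm.decompose(series["abundance"], period=52)
    decomp_summary = {
        "seasonal_amplitude": float(np.nanmax(seasonal.values)
                                    - np.nanmin(seasonal.values)),
        "residual_sd": float(np.nanstd(resid.values)),
    }
    return series, fits, lags, transport, monthly, spectrum, decomp_summary


@_stage("network")
def _network_stage(world, abund_ts, desert_daily_mean, config):
    frames = {"abundance": abund_ts.to_pandas()}
    frames["local_pm10"] = world.local_pm10_daily.to_pandas()
    frames["desert_pm10"] = desert_daily_mean.to_pandas()
    for name, ts in world.meteorology.items():
        frames[name] = ts.to_pandas()
    for p in "ABCDE":
        frames[f"pathway_{p}"] = im.pathway_frequency(
            world.pathway_labels, pathway=p).to_pandas()
    monthly = pd.DataFrame({
        name: s.resample("MS").mean() for name, s in frames.items()})
    # collinearity pruning applies to the environmental variables; the
    # focal population/PM variables always enter the network
    focal = [f for f in FOCAL_VARIABLES if f in monthly.columns]
    env = monthly.drop(columns=focal)
    kept_env, dropped = nw.prune_collinear(env, config.collinearity_threshold)
    kept = focal + kept_env
    rho, p = nw.spearman_matrix(monthly[kept])
    net = nw.build_network(rho, p, alpha=config.alpha,
                           node_classes=NODE_CLASSES)
    modules = nw.find_modules(net)
    focal = [f for f in FOCAL_VARIABLES if f in net]
    ego = nw.ego_subnetwork(net, focal)
    return monthly, kept, dropped, rho, p, net, modules, ego


@_stage("events")
def _events_stage(world, config):
    official = ev.detect_official_events(world.hourly_pm10,
                                         threshold=config.event_threshold)
    daily_paths = world.pathway_labels.groupby(
        world.pathway_labels.index.floor("D")).agg(
            lambda s: s.mode().iloc[0])
    spikes = ev.detect_spikes(world.local_pm10_daily, daily_paths,
                              threshold=config.spike_threshold,
                              official_events=official)
    # effects are evaluated on the per-sample abundance record (events are
    # day-scale; the weekly series is too coarse)
    sample_series = pd.Series({
        s.date: ab.adjust_abundance(s.total_copies, ab.bacterial_fraction(s))
        for s in world.samples
        if s.has_sequencing and s.total_copies > 0 and s.reads_bacterial > 0
    }).sort_index()
    effects = {}
    for kind, evs in (("official", official), ("spike", spikes)):
        if evs:
            try:
                effects[kind] = ev.event_effect(
                    sample_series, evs, window_days=config.window_days,
                    min_during_days=3).to_dict()
            except ValueError:
                effects[kind] = None
        else:
            effects[kind] = None
    return official, spikes, effects


@_stage("immigration")
def _immigration_stage(world, config):
    freq_a = im.pathway_frequency(world.pathway_labels, pathway="A")
    indices = {}
    for region, pm in world.desert_pm10.items():
        indices[f"rd_{region}"] = im.immigration_index(
            pm, freq_a, smooth_days=config.smooth_days)
    return freq_a, indices


@_stage("sem")
def _sem_stage(world, abund_ts, immigration_indices, config,
               transport_lag_weeks: int = 0, official_events=()):
    """Fit the latent LA = LG + RD model on weekly indicator rows.

    Weekly series are gap-imputed and outlier-corrected, dust-immigration
    indicators are shifted by the estimated transport delay so they
    describe the dust arriving in the week they are paired with, and weeks
    inside detected official dust episodes (arrival week back through the
    lagged desert-side window) are excluded: the structural model targets
    the smooth covariation of the processes, and the episodic spikes -
    analysed separately by the event statistics - would otherwise dominate
    the covariances.
    """
    spec = sm.default_spec()
    grid = abund_ts.dates

    def clean(ts):
        return tsm.correct_outliers(tsm.impute_wma(ts), k=config.outlier_k)[0]

    shift = int(np.clip(transport_lag_weeks, 0, 13))
    table = {"abundance": clean(abund_ts).to_pandas(),
             "local_pm10": clean(_weekly_mean(world.local_pm10_daily,
                                              "local_pm10", grid)).to_pandas()}
    for name in ("humidity", "pressure", "cloud"):
        table[name] = clean(_weekly_mean(world.meteorology[name], name,
                                         grid)).to_pandas()
    for name, ts in immigration_indices.items():
        table[name] = clean(_weekly_mean(ts, name, grid)) \
            .to_pandas().shift(shift)
    df = pd.DataFrame(table)
    drop = pd.Series(False, index=df.index)
    for event in official_events:
        lo = (event.start - pd.Timedelta(days=int(event.start.dayofweek))
              ).floor("D") - pd.Timedelta(days=7 * shift)
        hi = (event.end - pd.Timedelta(days=int(event.end.dayofweek))
              ).floor("D")
        drop |= (df.index >= lo) & (df.index <= hi)
    df = df[~drop.to_numpy()]
    fit = sm.fit_sem(df, spec, seed=config.seed)
    std = sm.standardize(fit)
    indices = sm.fit_indices(fit)
    return fit, std, indices, df.dropna().shape[0]


def run_full_analysis(config: AnalysisConfig,
                      world: SyntheticWorld | None = None) -> dict:
    """Run every stage and return the analysis report as a plain dict."""
    if world is None:
        world = generate_world(config.world)

    filled, abund_ts = _abundance_stage(world, config)
    desert_daily = TimeSeries(
        world.local_pm10_daily.start, 1.0,
        np.mean([s.values for s in world.desert_pm10.values()], axis=0),
        name="desert_pm10", units="ug/m^3")
    desert_weekly = _weekly_mean(desert_daily, "desert_pm10", abund_ts.dates)
    local_weekly = _weekly_mean(world.local_pm10_daily, "local_pm10",
                                abund_ts.dates)

    (series, fits, lags, transport, monthly_prof, spectrum,
     decomp) = _seasonality_stage(abund_ts, desert_weekly, local_weekly,
                                  config)
    (monthly_table, kept, dropped, rho, p, net, modules,
     ego) = _network_stage(world, abund_ts, desert_daily, config)
    official, spikes, effects = _events_stage(world, config)
    freq_a, imm = _immigration_stage(world, config)
    sem_fit, sem_std, sem_idx, sem_n = _sem_stage(
        world, abund_ts, imm, config,
        transport_lag_weeks=transport["abundance_lag_weeks"],
        official_events=official)

    vals = abund_ts.values[~np.isnan(abund_ts.values)]
    report = {
        "meta": {"seed": config.seed, "config_hash": config.hash(),
                 "n_samples": len(world.samples),
                 "n_weeks": len(abund_ts)},
        "abundance": {
            "mean_log10": float(vals.mean()),
            "sd_log10": float(vals.std(ddof=1)),
            "range_log10": [float(vals.min()), float(vals.max())],
            "provenance_counts": pd.Series(filled.provenance)
                .value_counts().to_dict(),
        },
        "monthly_profiles": {name: prof["mean"].round(4).tolist()
                             for name, prof in monthly_prof.items()},
        "harmonic_fits": {name: fit.to_dict() for name, fit in fits.items()},
        "phase_lags_weeks": lags,
        "transport_lag": transport,
        "spectrum": spectrum.to_dict(),
        "decomposition": decomp,
        "network": {
            "kept_variables": kept,
            "dropped_variables": dropped,
            "n_edges": net.number_of_edges(),
            "modules": {k: int(v) for k, v in modules.items()},
            "ego_nodes": sorted(ego.nodes),
            "focal_comodule": len({modules[f] for f in FOCAL_VARIABLES
                                   if f in modules}) == 1,
        },
        "events": {
            "n_official": len(official),
            "n_spikes": len(spikes),
            "effects": effects,
        },
        "sem": {
            "n": sem_n,
            "chi2": sem_fit.chi2,
            "df": sem_fit.df,
            "converged": sem_fit.converged,
            "standardized": sem_std.to_dict(),
            "fit_indices": sem_idx,
        },
    }

    if config.output_dir:
        outdir = pathlib.Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        filled.to_csv(outdir / "abundance_weekly.csv")
        monthly_table.to_csv(outdir / "monthly_table.csv")
        nw.write_sif(net, outdir / "network.sif")
        nw.write_graphml(net, outdir / "network.graphml")
        nw.write_edge_csv(net, outdir / "network_edges.csv")
        report_to_json(report, outdir / "report.json")
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
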