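"""Regular-cadence time-series tools for atmospheric monitoring data.

This module provides the temporal machinery the rest of the package builds
on: a light regular-grid :class:`TimeSeries` container, the weighted
moving-average (WMA) gap imputation used for weekly monitoring series,
robust outlier correction, annual sine/cosine (harmonic) regression with
phase-lag estimation between series, a discrete Fourier periodogram, and
classical additive decomposition.

The annual harmonic model is

    Y(t) = a * sin(2*pi*t) + b * cos(2*pi*t) + c

with ``t`` in years, so a single term captures one cycle per year.  The
fitted amplitude is ``sqrt(a**2 + b**2)`` and the phase ``atan2(b, a)``;
differences of phases between two series, expressed in weeks, estimate how
far one seasonal cycle trails the other.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.signal
import statsmodels.api as sm
from statsmodels.tsa.seasonal import seasonal_decompose

#: Mean number of ISO weeks per year used to convert phase angles to weeks.
WEEKS_PER_YEAR = 52.18

#: WMA imputation weights for lags (t-3, t-2, t-1); they sum to one so a
#: constant series is left invariant.
WMA_WEIGHTS = (1.0 / 6.0, 1.0 / 3.0, 1.0 / 2.0)

__all__ = [
    "TimeSeries",
    "HarmonicFit",
    "Spectrum",
    "WEEKS_PER_YEAR",
    "impute_wma",
    "correct_outliers",
    "fit_harmonic",
    "phase_lag",
    "periodogram",
    "decompose",
    "aggregate_monthly",
    "cross_correlation_lag",
]


@dataclass
class TimeSeries:
    """Values on a regular calendar grid, with NaN marking missing points.

    Parameters
    ----------
    start : timestamp-like
        Date (or datetime) of the first grid point.
    cadence_days : float
        Grid spacing in days (``7`` weekly, ``1`` daily, ``1/24`` hourly).
    values : array of float
        Observations; ``NaN`` encodes a missing point.
    name, units : str
        Free-text metadata carried through derived series.
    """

    start: pd.Timestamp
    cadence_days: float
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self):
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("TimeSeries values must be one-dimensional")
        if self.cadence_days <= 0:
            raise ValueError("cadence_days must be positive")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        offsets = pd.to_timedelta(
            self.cadence_days * np.arange(len(self.values)), unit="D")
        return pd.DatetimeIndex(self.start + offsets)

    @property
    def t_years(self) -> np.ndarray:
        """Time axis in (Julian) years since the series start."""
        return self.cadence_days * np.arange(len(self.values)) / 365.25

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask, True where the value is missing."""
        return np.isnan(self.values)

    @property
    def span_years(self) -> float:
        return (len(self.values) - 1) * self.cadence_days / 365.25

    def to_pandas(self) -> pd.Series:
        return pd.Series(self.values, index=self.dates, name=self.name or None)

    @classmethod
    def from_pandas(cls, s: pd.Series, cadence_days: float | None = None,
                    name: str = "", units: str = "") -> "TimeSeries":
        if cadence_days is None:
            deltas = np.diff(s.index.values).astype("timedelta64[s]").astype(float)
            if len(deltas) == 0:
                raise ValueError("cannot infer cadence from a single point")
            cadence_days = float(np.median(deltas)) / 86400.0
        return cls(s.index[0], cadence_days, s.to_numpy(dtype=float),
                   name=name or (s.name or ""), units=units)

    def copy_with(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class HarmonicFit:
    """Least-squares annual sine/cosine fit of one series."""

    a: float            # sine coefficient
    b: float            # cosine coefficient
    c: float            # intercept, in series units
    r2: float           # fraction of variance explained vs the mean-only model
    pvalue: float       # F-test of the two harmonic regressors
    n: int = 0

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.a, self.b))

    @property
    def phase_rad(self) -> float:
        """Phase angle ``atan2(b, a)`` of the fitted annual cycle."""
        return float(np.arctan2(self.b, self.a))

    @property
    def peak_time_years(self) -> float:
        """Time (fraction of a year past Jan 1 of the series clock) of the
        fitted annual maximum."""
        return float(((np.pi / 2 - self.phase_rad) / (2 * np.pi)) % 1.0)

    def to_dict(self) -> dict:
        return {
            "a": self.a, "b": self.b, "c": self.c,
            "amplitude": self.amplitude, "phase_rad": self.phase_rad,
            "r2": self.r2, "p": self.pvalue, "n": self.n,
        }


@dataclass
class Spectrum:
    """Discrete Fourier periodogram of a regular series."""

    frequencies: np.ndarray   # cycles per year
    power: np.ndarray
    dominant_period: float    # years

    def to_dict(self) -> dict:
        return {
            "dominant_period_years": float(self.dominant_period),
            "peak_frequency_cpy": float(self.frequencies[np.argmax(self.power)]),
        }


def impute_wma(ts: TimeSeries) -> TimeSeries:
    """Fill missing points with the weighted moving average of the three
    preceding points: x_t = (1/6) x_{t-3} + (1/3) x_{t-2} + (1/2) x_{t-1}.

    The sweep runs forward in time so earlier imputations feed later ones.
    Leading missing values (before the first observation) are back-filled
    from the first observed value so the sweep has a starting state.

    Raises
    ------
    ValueError
        If a missing point still lacks one of its three predecessors after
        the sweep (e.g. a gap within the first three points of the series).
    """
    x = ts.values.copy()
    finite = np.flatnonzero(~np.isnan(x))
    if len(finite) == 0:
        raise ValueError("cannot impute an entirely missing series")
    first = finite[0]
    x[:first] = x[first]
    w3, w2, w1 = WMA_WEIGHTS
    for t in np.flatnonzero(np.isnan(x)):
        if t < 3 or np.isnan(x[t - 3:t]).any():
            raise ValueError(
                f"missing value at index {t} has unavailable predecessors; "
                "cannot apply the 3-point weighted moving average")
        x[t] = w3 * x[t - 3] + w2 * x[t - 2] + w1 * x[t - 1]
    return ts.copy_with(x)


def correct_outliers(ts: TimeSeries, k: float = 4.0,
                     window: int = 9) -> tuple[TimeSeries, list[int]]:
    """Flag points deviating from a rolling median by more than ``k`` rolling
    MADs and replace them by the WMA of their predecessors.

    Returns the corrected series and the list of replaced indices.  With a
    clean series no point is touched.  The rolling MAD is scaled by the
    normal-consistency constant and floored at the series-wide MAD, so
    smooth stretches (where the local MAD collapses) are not over-flagged.
    """
    if len(ts) < 12:
        raise ValueError("outlier correction needs at least 12 points")
    s = pd.Series(ts.values)
    med = s.rolling(window, center=True, min_periods=1).median()
    absdev = (s - med).abs()
    mad = absdev.rolling(window, center=True, min_periods=1).median()
    # local MAD collapses to ~0 near smooth extrema; floor it at the
    # series-wide MAD so modest deviations are not flagged there
    global_mad = float(absdev.median())
    mad = np.maximum(mad, global_mad)
    sigma = 1.4826 * mad  # MAD consistency constant for a normal scale
    with np.errstate(invalid="ignore"):
        flag = (absdev > k * sigma) & sigma.gt(0) & s.notna()
    # the first three points have no WMA predecessors; leave them in place
    replaced = [int(i) for i in np.flatnonzero(flag.to_numpy()) if i >= 3]
    if not replaced:
        return ts.copy_with(ts.values.copy()), []
    x = ts.values.copy()
    x[replaced] = np.nan
    corrected = impute_wma(ts.copy_with(x))
    return corrected, replaced


def fit_harmonic(ts: TimeSeries) -> HarmonicFit:
    """Fit Y = a sin(2 pi t) + b cos(2 pi t) + c by ordinary least squares.

    ``t`` is in years so the single harmonic has an annual period.  An
    intercept is always included (environmental series have large positive
    means); R^2 is reported against the intercept-only model and the p-value
    is the F-test of the two harmonic terms.

    Requires a gap-free series (impute first) spanning at least two years.
    """
    if np.isnan(ts.values).any():
        raise ValueError("fit_harmonic requires a gap-free series; impute first")
    if ts.span_years < 2.0:
        raise ValueError("harmonic fitting requires a span of at least 2 years")
    t = ts.t_years
    if np.allclose(t, t[0]):
        raise ValueError("degenerate time axis: all time points identical")
    X = np.column_stack([np.sin(2 * np.pi * t), np.cos(2 * np.pi * t)])
    model = sm.OLS(ts.values, sm.add_constant(X, prepend=False)).fit()
    a, b, c = model.params
    return HarmonicFit(a=float(a), b=float(b), c=float(c),
                       r2=float(model.rsquared), pvalue=float(model.f_pvalue),
                       n=len(ts))


def phase_lag(fit_x: HarmonicFit, fit_y: HarmonicFit,
              amplitude_tol: float = 1e-12) -> float:
    """Phase difference between two annual harmonic fits, in weeks.

    Computes ``dphi = phase(y) - phase(x)`` wrapped to (-pi, pi] and scales
    by one year (52.18 weeks).  Because the fitted maximum occurs where
    ``2 pi t + phase = pi/2``, a *positive* value means the second series'
    cycle is phase-advanced, i.e. the first series reaches its annual peak
    ``lag`` weeks *after* the second; ``phase_lag(local, desert)`` therefore
    returns a positive number of weeks when the local cycle trails the
    desert cycle.  Identical fits give 0; a pure sine against a pure cosine
    gives a quarter period (about 13.0 weeks).
    """
    for f in (fit_x, fit_y):
        if f.amplitude < amplitude_tol:
            raise ValueError("phase undefined: harmonic amplitude below tolerance")
    dphi = fit_y.phase_rad - fit_x.phase_rad
    dphi = (dphi + np.pi) % (2 * np.pi) - np.pi
    if dphi == -np.pi:  # wrap to (-pi, pi]
        dphi = np.pi
    return float(dphi / (2 * np.pi) * WEEKS_PER_YEAR)


def periodogram(ts: TimeSeries) -> Spectrum:
    """Discrete Fourier periodogram after mean removal.

    Frequencies are in cycles per year; the dominant period is the inverse
    of the frequency with the largest power (the zero frequency excluded).
    """
    if np.isnan(ts.values).any():
        raise ValueError("periodogram requires a gap-free series")
    if ts.span_years < 2.0:
        raise ValueError("periodogram requires a span of at least 2 years")
    fs = 365.25 / ts.cadence_days  # samples per year
    freqs, power = scipy.signal.periodogram(ts.values, fs=fs, detrend="constant")
    keep = freqs > 0
    freqs, power = freqs[keep], power[keep]
    dominant = 1.0 / freqs[int(np.argmax(power))]
    return Spectrum(frequencies=freqs, power=power, dominant_period=float(dominant))


def decompose(ts: TimeSeries, period: int):
    """Classical additive decomposition into trend, seasonal, and residual.

    Trend is a centred moving average over one period; the seasonal
    component is the period-position mean of the detrended series,
    re-centred to sum to zero over one period; the residual is the
    remainder.  Trend and residual are undefined (NaN) within half a period
    of the ends.
    """
    if np.isnan(ts.values).any():
        raise ValueError("decompose requires a gap-free series")
    if len(ts) < 2 * period:
        raise ValueError("decompose requires at least two full periods")
    res = seasonal_decompose(ts.values, model="additive", period=period,
                             two_sided=True, extrapolate_trend=0)
    return (ts.copy_with(res.trend), ts.copy_with(res.seasonal),
            ts.copy_with(res.resid))


def aggregate_monthly(ts: TimeSeries) -> pd.DataFrame:
    """Pool a series by calendar month across years.

    Returns a 12-row frame indexed by month (1-12) with columns ``mean``,
    ``sd`` and ``n``; months never observed carry NaN.
    """
    if ts.span_years < 1.0:
        raise ValueError("monthly aggregation requires at least one year")
    s = ts.to_pandas().dropna()
    grouped = s.groupby(s.index.month)
    out = pd.DataFrame({
        "mean": grouped.mean(),
        "sd": grouped.std(ddof=1),
        "n": grouped.size(),
    })
    return out.reindex(range(1, 13))


def cross_correlation_lag(x: TimeSeries, y: TimeSeries,
                          max_lag: int = 13) -> tuple[int, float]:
    """Lag (in grid steps) at which ``y`` best trails ``x``.

    Scans integer shifts ``tau`` in ``[-max_lag, max_lag]`` and returns the
    shift maximising the Pearson correlation between ``x(t)`` and
    ``y(t + tau)`` over pairwise-complete points, together with that
    correlation.  A positive lag means ``y`` follows ``x``.  Unlike the
    single-harmonic phase difference this uses the full signal - including
    episodic spikes that travel from source to receptor - so it is the
    preferred estimator of a transport delay.
    """
    if abs(x.cadence_days - y.cadence_days) > 1e-9:
        raise ValueError("series must share a cadence")
    xv, yv = x.values, y.values
    n = min(len(xv), len(yv))
    xv, yv = xv[:n], yv[:n]
    best_tau, best_r = 0, -np.inf
    for tau in range(-max_lag, max_lag + 1):
        if tau >= 0:
            a, b = xv[:n - tau] if tau else xv, yv[tau:]
        else:
            a, b = xv[-tau:], yv[:n + tau]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 8:
            continue
        r = float(np.corrcoef(a[ok], b[ok])[0, 1])
        if r > best_r:
            best_tau, best_r = tau, r
    if not np.isfinite(best_r):
        raise ValueError("insufficient overlapping data for lag estimation")
    return best_tau, best_r
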