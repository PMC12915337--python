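"""Absolute bacterial abundance from qPCR totals and amplicon compositions.

Universal 16S primers amplify chloroplast and mitochondrial sequences along
with genuine bacterial reads, so the sequenced composition of each air
sample is used to down-scale the qPCR total: the bacterial fraction of the
library multiplied by the total 16S copy number per cubic metre gives an
absolute bacterial abundance, analysed on the log10 scale throughout.

Samples without sequencing data are recovered after weekly aggregation:
long contiguous gaps (a monsoon interruption, for instance) are filled with
the mean of the same calendar week in the other sampled years, and isolated
gaps by linear interpolation; every filled point carries a provenance tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "SampleRecord",
    "AbundanceSeries",
    "bacterial_fraction",
    "adjust_abundance",
    "aggregate_weekly",
    "fill_missing_composition",
]

PROVENANCE_MEASURED = "measured"
PROVENANCE_SEASONAL = "seasonal_average"
PROVENANCE_LINEAR = "linear_interpolated"
PROVENANCE_MISSING = "missing"


@dataclass
class SampleRecord:
    """One air sample: a qPCR total and the sequenced read composition."""

    date: pd.Timestamp
    total_copies: float          # 16S rRNA gene copies per m^3, linear scale
    reads_bacterial: int = 0
    reads_chloroplast: int = 0
    reads_mito: int = 0
    reads_other: int = 0
    has_sequencing: bool = True

    def __post_init__(self):
        self.date = pd.Timestamp(self.date)
        if self.total_copies < 0:
            raise ValueError("total_copies must be non-negative")
        for r in (self.reads_bacterial, self.reads_chloroplast,
                  self.reads_mito, self.reads_other):
            if r < 0:
                raise ValueError("read counts must be non-negative")
        if self.has_sequencing and self.total_reads == 0:
            raise ValueError("a sequenced sample must have at least one read")

    @property
    def total_reads(self) -> int:
        return (self.reads_bacterial + self.reads_chloroplast
                + self.reads_mito + self.reads_other)


@dataclass
class AbundanceSeries:
    """Weekly bacterial abundance with per-point provenance.

    All arrays are aligned to ``dates`` (Mondays of consecutive ISO weeks).
    ``log10_bacterial`` is the adjusted abundance; ``provenance`` records
    whether each point was measured, seasonally averaged, linearly
    interpolated, or left missing.
    """

    dates: pd.DatetimeIndex
    log10_total: np.ndarray
    bacterial_fraction: np.ndarray
    log10_bacterial: np.ndarray
    provenance: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.dates)
        for name in ("log10_total", "bacterial_fraction", "log10_bacterial"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        if self.provenance is None:
            self.provenance = np.where(np.isnan(self.log10_bacterial),
                                       PROVENANCE_MISSING, PROVENANCE_MEASURED)
        self.provenance = np.asarray(self.provenance, dtype=object)

    def __len__(self) -> int:
        return len(self.dates)

    def to_timeseries(self, field_name: str = "log10_bacterial") -> TimeSeries:
        return TimeSeries(self.dates[0], 7.0, getattr(self, field_name),
                          name=field_name,
                          units="log10 copies/m^3" if "log10" in field_name else "")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "date": self.dates,
            "log10_total": self.log10_total,
            "bacterial_fraction": self.bacterial_fraction,
            "log10_bacterial": self.log10_bacterial,
            "provenance": self.provenance,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def bacterial_fraction(rec: SampleRecord) -> float:
    """Fraction of the sample's reads that are bacterial.

    Chloroplast, mitochondrial and other non-bacterial amplicons are part of
    the denominator, so the fraction is the share of the library retained
    after excluding them.
    """
    if not rec.has_sequencing or rec.total_reads == 0:
        raise ValueError("bacterial fraction undefined without sequencing reads")
    return rec.reads_bacterial / rec.total_reads


def adjust_abundance(total_copies: float, fraction: float) -> float:
    """Absolute bacterial abundance, log10(total qPCR copies x bacterial
    fraction).

    A zero fraction is flagged as missing (NaN) rather than propagating
    ``-inf`` into downstream statistics.
    """
    if total_copies <= 0:
        raise ValueError("total_copies must be positive")
    if fraction < 0 or fraction > 1:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 0:
        return float("nan")
    return float(np.log10(total_copies * fraction))


def _week_start(dates: pd.DatetimeIndex) -> pd.DatetimeIndex:
    """Monday of the ISO week of each date."""
    return dates - pd.to_timedelta(dates.dayofweek, unit="D")


def aggregate_weekly(samples: list[SampleRecord]) -> AbundanceSeries:
    """Bin samples into calendar (ISO) weeks and average on the log10 scale.

    Weekly binning follows the convention of analysing log-transformed
    abundance: duplicate samples within a week are averaged after the log
    transform.  Weeks without any sample (or without any sequenced sample)
    are flagged missing; the weekly grid is contiguous from the first to
    the last sampled week.
    """
    if not samples:
        raise ValueError("no samples to aggregate")
    rows = []
    for rec in samples:
        if rec.has_sequencing and rec.total_reads > 0 and rec.total_copies > 0:
            frac = bacterial_fraction(rec)
            logb = adjust_abundance(rec.total_copies, frac) if frac > 0 else np.nan
        else:
            frac, logb = np.nan, np.nan
        logt = np.log10(rec.total_copies) if rec.total_copies > 0 else np.nan
        rows.append((rec.date, logt, frac, logb))
    df = pd.DataFrame(rows, columns=["date", "log10_total", "fraction",
                                     "log10_bacterial"])
    df["week"] = _week_start(pd.DatetimeIndex(df["date"]))
    grouped = df.groupby("week")[["log10_total", "fraction", "log10_bacterial"]].mean()
    grid = pd.date_range(grouped.index.min(), grouped.index.max(), freq="7D")
    grouped = grouped.reindex(grid)
    return AbundanceSeries(
        dates=grid,
        log10_total=grouped["log10_total"].to_numpy(),
        bacterial_fraction=grouped["fraction"].to_numpy(),
        log10_bacterial=grouped["log10_bacterial"].to_numpy(),
    )


def fill_missing_composition(series: AbundanceSeries,
                             history: AbundanceSeries | None = None,
                             gap_threshold: int = 3) -> AbundanceSeries:
    """Fill missing weekly abundance values.

    Contiguous gaps of at least ``gap_threshold`` weeks are filled with the
    mean of the same ISO calendar week in the other years of ``history``
    (by default the series itself), mirroring the treatment of a seasonal
    sampling interruption; shorter, isolated gaps are linearly
    interpolated.  Provenance is recorded per filled point.  A long-gap
    week with no same-week donor in any other year is left missing with a
    warning.
    """
    if history is None:
        history = series
    x = series.log10_bacterial.copy()
    prov = series.provenance.copy()
    isna = np.isnan(x)
    if not isna.any():
        return AbundanceSeries(series.dates, series.log10_total.copy(),
                               series.bacterial_fraction.copy(), x, prov)

    # donor table: measured values of `history` keyed by ISO week number
    hist_dates = history.dates
    hist_vals = history.log10_bacterial
    hist_ok = ~np.isnan(hist_vals)
    iso = hist_dates.isocalendar()
    donors = pd.DataFrame({
        "week": np.asarray(iso.week)[hist_ok],
        "year": np.asarray(iso.year)[hist_ok],
        "value": hist_vals[hist_ok],
    })

    # contiguous runs of missing weeks
    runs = []
    i = 0
    while i < len(x):
        if isna[i]:
            j = i
            while j + 1 < len(x) and isna[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1

    series_iso = series.dates.isocalendar()
    week_no = np.asarray(series_iso.week)
    year_no = np.asarray(series_iso.year)

    for lo, hi in runs:
        length = hi - lo + 1
        if length >= gap_threshold:
            for k in range(lo, hi + 1):
                pool = donors[(donors["week"] == week_no[k])
                              & (donors["year"] != year_no[k])]["value"]
                if len(pool) == 0:
                    warnings.warn(
                        f"no same-week donor for ISO week {week_no[k]} of "
                        f"{year_no[k]}; left missing", stacklevel=2)
                    continue
                x[k] = float(pool.mean())
                prov[k] = PROVENANCE_SEASONAL
        else:
            left = lo - 1
            right = hi + 1
            if left < 0 or right >= len(x) or np.isnan(x[left]) or np.isnan(x[right]):
                warnings.warn(
                    f"short gap at weeks {lo}-{hi} lacks both neighbours; "
                    "left missing", stacklevel=2)
                continue
            for k in range(lo, hi + 1):
                frac = (k - left) / (right - left)
                x[k] = x[left] + frac * (x[right] - x[left])
                prov[k] = PROVENANCE_LINEAR
    return AbundanceSeries(series.dates, series.log10_total.copy(),
                           series.bacterial_fraction.copy(), x, prov)
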