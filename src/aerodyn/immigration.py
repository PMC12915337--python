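"""Desert dust-immigration index.

Desert-station air-quality indices (AQI) are inverted to PM10 mass
concentrations through a piecewise-linear breakpoint table; the daily
frequency of desert-origin back-trajectories (pathway A) weights those
concentrations; and a short trailing moving average smooths the product
into a per-region "dust immigration" series used as the regional-dispersal
indicators of the structural equation model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .timeseries import TimeSeries

__all__ = [
    "AqiBreakpointTable",
    "us_epa_pm10_table",
    "aqi_to_pm10",
    "pm10_to_aqi",
    "pathway_frequency",
    "immigration_index",
]


@dataclass
class AqiBreakpointTable:
    """Ordered (aqi_lo, aqi_hi, conc_lo, conc_hi) breakpoint rows.

    AQI ranges must be non-overlapping and ascending, and concentrations
    non-decreasing, so the piecewise-linear map is invertible.
    """

    rows: list[tuple[float, float, float, float]]

    def __post_init__(self):
        if not self.rows:
            raise ValueError("breakpoint table is empty")
        self.rows = [tuple(float(v) for v in r) for r in self.rows]
        prev_hi = -np.inf
        prev_chi = -np.inf
        for aqi_lo, aqi_hi, c_lo, c_hi in self.rows:
            if aqi_hi <= aqi_lo or c_hi < c_lo:
                raise ValueError("breakpoint row bounds must be ascending")
            if aqi_lo <= prev_hi or c_lo < prev_chi:
                raise ValueError("breakpoint rows must be ordered and disjoint")
            prev_hi, prev_chi = aqi_hi, c_hi

    @property
    def aqi_span(self) -> tuple[float, float]:
        return self.rows[0][0], self.rows[-1][1]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"rows": [list(r) for r in self.rows]}, fh)

    @classmethod
    def from_yaml(cls, path) -> "AqiBreakpointTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(rows=[tuple(r) for r in data["rows"]])


def us_epa_pm10_table() -> AqiBreakpointTable:
    """US EPA PM10 AQI breakpoints (24-h average, ug/m^3)."""
    return AqiBreakpointTable(rows=[
        (0, 50, 0, 54),
        (51, 100, 55, 154),
        (101, 150, 155, 254),
        (151, 200, 255, 354),
        (201, 300, 355, 424),
        (301, 400, 425, 504),
        (401, 500, 505, 604),
    ])


def _nodes(table: AqiBreakpointTable):
    aqi_nodes, conc_nodes = [], []
    for aqi_lo, aqi_hi, c_lo, c_hi in table.rows:
        aqi_nodes += [aqi_lo, aqi_hi]
        conc_nodes += [c_lo, c_hi]
    return np.asarray(aqi_nodes, float), np.asarray(conc_nodes, float)


def aqi_to_pm10(aqi: float, table: AqiBreakpointTable | None = None) -> float:
    """Invert an AQI value to a PM10 mass concentration (ug/m^3).

    Linear interpolation within the bracketing breakpoint row,
    ``conc = conc_lo + (aqi - aqi_lo) * (conc_hi - conc_lo) / (aqi_hi - aqi_lo)``;
    the unit gaps between integer-bounded rows are bridged linearly so the
    map is continuous and exactly invertible over the whole span.
    """
    table = table or us_epa_pm10_table()
    lo, hi = table.aqi_span
    if not lo <= float(aqi) <= hi:
        raise ValueError(f"AQI {aqi} outside table span [{lo}, {hi}]")
    aqi_nodes, conc_nodes = _nodes(table)
    return float(np.interp(float(aqi), aqi_nodes, conc_nodes))


def pm10_to_aqi(conc: float, table: AqiBreakpointTable | None = None) -> float:
    """Forward AQI map (the inverse of :func:`aqi_to_pm10`)."""
    table = table or us_epa_pm10_table()
    aqi_nodes, conc_nodes = _nodes(table)
    if not conc_nodes[0] <= float(conc) <= conc_nodes[-1]:
        raise ValueError(f"concentration {conc} outside table span")
    return float(np.interp(float(conc), conc_nodes, aqi_nodes))


def pathway_frequency(labels: pd.Series, pathway: str = "A") -> TimeSeries:
    """Daily frequency of a back-trajectory pathway label.

    ``labels`` is indexed by trajectory timestamps (typically 12 per day at
    2-hour intervals); the result is the daily fraction of labels equal to
    ``pathway``, NaN for days without any trajectory.
    """
    if labels.empty:
        raise ValueError("no trajectory labels supplied")
    daily = (labels == pathway).groupby(labels.index.floor("D")).mean()
    counts = labels.groupby(labels.index.floor("D")).size()
    daily = daily.where(counts > 0)
    grid = pd.date_range(daily.index.min(), daily.index.max(), freq="D")
    daily = daily.reindex(grid)
    return TimeSeries(grid[0], 1.0, daily.to_numpy(),
                      name=f"pathway_{pathway}_frequency", units="fraction")


def immigration_index(desert_pm10: TimeSeries, freq_a: TimeSeries,
                      smooth_days: int = 4, centered: bool = False) -> TimeSeries:
    """Dust-immigration index: desert PM10 weighted by pathway-A frequency.

    The pointwise product is smoothed with a ``smooth_days`` moving average,
    trailing (causal) by default so the index can serve as a same-day model
    indicator.  Both inputs must share a daily calendar.
    """
    if (abs(desert_pm10.cadence_days - 1.0) > 1e-9
            or abs(freq_a.cadence_days - 1.0) > 1e-9):
        raise ValueError("immigration index expects daily series")
    if desert_pm10.start != freq_a.start or len(desert_pm10) != len(freq_a):
        raise ValueError("desert PM10 and pathway frequency calendars differ")
    product = desert_pm10.values * freq_a.values
    smoothed = (pd.Series(product)
                .rolling(smooth_days, min_periods=1, center=centered)
                .mean().to_numpy())
    return TimeSeries(desert_pm10.start, 1.0, smoothed,
                      name=f"immigration_{desert_pm10.name or 'desert'}",
                      units="ug/m^3 (frequency-weighted)")
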