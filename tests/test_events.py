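"""Dust-event detection boundaries and before/during/after statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from aerodyn.events import (DustEvent, detect_official_events, detect_spikes,
                            effect_summary_from_ratios, event_effect,
                            event_test)
from aerodyn.synthetic import generate_event_episode
from aerodyn.timeseries import TimeSeries


def hourly(values, start="2019-04-01"):
    return TimeSeries(start, 1.0 / 24.0, np.asarray(values, dtype=float),
                      name="pm10", units="ug/m^3")


def daily(values, start="2019-04-01"):
    return TimeSeries(start, 1.0, np.asarray(values, dtype=float))


class TestDetectOfficialEvents:
    def test_never_above_threshold(self):
        assert detect_official_events(hourly(np.full(96, 120.0))) == []

    def test_exactly_two_hours_is_not_an_event(self):
        x = np.full(96, 100.0)
        x[40:42] = 200.0  # "more than two consecutive hours" is strict
        assert detect_official_events(hourly(x)) == []

    def test_three_hours_is_an_event(self):
        x = np.full(96, 100.0)
        x[40:43] = 200.0
        events = detect_official_events(hourly(x))
        assert len(events) == 1

    def test_exceedance_is_strict(self):
        x = np.full(96, 100.0)
        x[40:50] = 150.0  # equal to threshold never exceeds it
        assert detect_official_events(hourly(x)) == []

    def test_constructed_episode_bounds(self):
        x = np.full(240, 60.0)
        x[100:106] = 160.0
        events = detect_official_events(hourly(x))
        assert len(events) == 1
        ev = events[0]
        dates = hourly(x).dates
        assert ev.start == dates[100]
        assert ev.end == dates[105]
        assert ev.peak_pm10 == pytest.approx(160.0)

    def test_nearby_runs_merged(self):
        x = np.full(240, 60.0)
        x[100:104] = 180.0
        x[108:112] = 170.0  # 4-hour dip < merge gap
        events = detect_official_events(hourly(x))
        assert len(events) == 1

    def test_masked_series_idempotent(self):
        x = np.full(240, 60.0)
        x[100:110] = 200.0
        ts = hourly(x)
        events = detect_official_events(ts)
        masked = x.copy()
        for ev in events:
            sel = (ts.dates >= ev.start) & (ts.dates <= ev.end)
            masked[np.asarray(sel)] = 60.0
        assert detect_official_events(hourly(masked)) == []

    def test_non_hourly_rejected(self):
        with pytest.raises(ValueError):
            detect_official_events(daily(np.full(30, 200.0)))


class TestDetectSpikes:
    def _paths(self, dates, letter="A"):
        return pd.Series([letter] * len(dates), index=dates)

    def test_wrong_pathway_not_a_spike(self):
        ts = daily([30, 50, 30])
        spikes = detect_spikes(ts, self._paths(ts.dates, "C"))
        assert spikes == []

    def test_boundary_is_strict(self):
        ts = daily([30, 44.9, 30, 45.0, 30])
        assert detect_spikes(ts, self._paths(ts.dates)) == []

    def test_injected_exceedances_counted(self):
        r = np.random.default_rng(4)
        x = np.full(400, 30.0)
        spike_days = np.sort(r.choice(np.arange(5, 395, 10), 14,
                                      replace=False))
        x[spike_days] = 55.0
        ts = daily(x)
        spikes = detect_spikes(ts, self._paths(ts.dates))
        assert len(spikes) == 14

    def test_official_event_days_excluded(self):
        ts = daily([30, 60, 60, 30])
        official = [DustEvent("official", ts.dates[1], ts.dates[1])]
        spikes = detect_spikes(ts, self._paths(ts.dates),
                               official_events=official)
        assert len(spikes) == 1
        assert spikes[0].start == ts.dates[2]


def sampled_series(log_values, start="2019-04-01"):
    dates = pd.date_range(start, periods=len(log_values), freq="D")
    return pd.Series(np.asarray(log_values, dtype=float), index=dates)


class TestEventEffect:
    def test_null_effect_is_100_percent(self):
        s = sampled_series(np.full(30, 4.0))
        ev = DustEvent("official", s.index[14], s.index[16])
        eff = event_effect(s, [ev])
        assert eff.ratios_percent[0] == pytest.approx(100.0)
        assert eff.post_drop_percent[0] == pytest.approx(0.0)

    def test_printed_ratios_aggregate(self):
        eff = effect_summary_from_ratios([5.2, 9.1, 2.7, 4.8])
        assert eff.mean_percent == pytest.approx(545.0)
        assert eff.min_percent == pytest.approx(270.0)
        assert eff.max_percent == pytest.approx(910.0)

    def test_scale_equivariance(self):
        r = np.random.default_rng(9)
        base = 4 + 0.2 * r.normal(size=40)
        base[20:23] += 0.8
        s = sampled_series(base)
        ev = DustEvent("official", s.index[20], s.index[22])
        e1 = event_effect(s, [ev])
        e2 = event_effect(s + 2.0, [ev])  # x1000 on the linear scale
        assert e1.ratios_percent[0] == pytest.approx(e2.ratios_percent[0],
                                                     rel=1e-9)

    def test_known_boost_recovered(self):
        base = np.full(40, 4.0)
        base[20:23] += np.log10(5.0)
        s = sampled_series(base)
        ev = DustEvent("official", s.index[20], s.index[22])
        eff = event_effect(s, [ev], window_days=7)
        assert eff.ratios_percent[0] == pytest.approx(500.0)

    def test_empty_window_skipped_with_warning(self):
        s = sampled_series(np.full(10, 4.0))
        events = [DustEvent("official", s.index[5], s.index[5]),
                  DustEvent("official", "2020-01-01", "2020-01-02")]
        with pytest.warns(UserWarning, match="skipped"):
            eff = event_effect(s, events)
        assert eff.n_events == 1


class TestEventTest:
    def test_identical_vectors_p_one(self):
        x = np.array([4.0, 4.5, 5.0, 4.2])
        assert event_test(x, x) == 1.0

    def test_power_on_clear_shift(self):
        r = np.random.default_rng(21)
        before = 4 + 0.05 * r.normal(size=10)
        during = before + 0.7
        assert event_test(before, during) < 0.01

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            event_test(np.array([1.0, 2.0]), np.array([2.0, 3.0]))

    def test_agrees_with_exact_permutation_oracle(self):
        """Paired t p-value tracks the exact sign-flip permutation p."""
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            before = 4 + 0.3 * r.normal(size=10)
            during = before + 0.35 + 0.3 * r.normal(size=10)
            diffs = during - before
            t_obs = abs(scipy.stats.ttest_rel(during, before).statistic)
            count = 0
            n_perm = 2 ** 10
            for signs in itertools.product((1, -1), repeat=10):
                d = diffs * np.array(signs)
                t = abs(d.mean() / (d.std(ddof=1) / np.sqrt(10)))
                count += t >= t_obs - 1e-12
            perm_p = count / n_perm
            assert event_test(before, during) == pytest.approx(perm_p,
                                                               abs=0.02)


class TestGenerateEventEpisode:
    def test_core_hours_exceed_scaled_base(self):
        seg = generate_event_episode(34.0, 3.6, 6)
        assert (seg[:6] > 120.0).all()

    def test_magnitude_one_identity(self):
        seg = generate_event_episode(34.0, 1.0, 6)
        assert np.allclose(seg, 34.0)

    def test_detector_finds_constructed_episode(self):
        base = 34.0
        seg = generate_event_episode(base, 4.5, 6)
        x = np.full(120, base)
        x[50:50 + len(seg)] = seg
        events = detect_official_events(hourly(x))
        assert len(events) == 1
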