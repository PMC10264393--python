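import datetime as dt

import numpy as np
import pandas as pd
import pytest

from dragontherm.config import PipelineConfig
from dragontherm.solar import DaylightWindow
from dragontherm.telemetry import (
    aggregate_window,
    build_windows,
    filter_days,
    match_microhabitat,
    match_series,
    summarize_by_shade,
)

T0 = pd.Timestamp("2013-01-05 20:00:00")  # UTC; mid-morning local at +11


class TestAggregateWindow:
    def test_pulses_in_listening_window_averaged(self):
        raw = [(T0 + pd.Timedelta(seconds=10 * i), 60.0) for i in range(9)]
        out = aggregate_window(raw)
        assert len(out) == 1
        assert out["pulse_rate"].iloc[0] == pytest.approx(60.0)
        assert out["timestamp"].iloc[0] == T0

    def test_mean_of_varying_pulses(self):
        raw = [
            (T0, 58.0),
            (T0 + pd.Timedelta(seconds=30), 60.0),
            (T0 + pd.Timedelta(seconds=60), 62.0),
        ]
        out = aggregate_window(raw)
        assert out["pulse_rate"].iloc[0] == pytest.approx(60.0)

    def test_pulses_after_listening_window_ignored(self):
        raw = [(T0 + pd.Timedelta(seconds=9), 60.0),
               (T0 + pd.Timedelta(seconds=200), 90.0)]  # outside the 90-s window
        out = aggregate_window(raw)
        assert len(out) == 1
        assert out["pulse_rate"].iloc[0] == pytest.approx(60.0)

    def test_empty_slot_absent(self):
        raw = [(T0, 60.0), (T0 + pd.Timedelta(minutes=20), 64.0)]
        out = aggregate_window(raw)
        assert list(out["timestamp"]) == [T0, T0 + pd.Timedelta(minutes=20)]

    def test_nonpositive_pulse_rejected(self):
        with pytest.raises(ValueError):
            aggregate_window([(T0, -5.0)])


def _day_records(dragon, day, start_h, end_h, site, skip=()):
    """10-min records between local clock hours [start_h, end_h)."""
    offset = pd.Timedelta(hours=site.utc_offset)
    local0 = pd.Timestamp(dt.datetime.combine(day, dt.time()))
    rows = []
    k = 0
    t = local0 + pd.Timedelta(hours=start_h)
    while t < local0 + pd.Timedelta(hours=end_h):
        if k not in skip:
            rows.append((dragon, "canberra", t - offset, 25.0, 100.0))
        t += pd.Timedelta(minutes=10)
        k += 1
    return pd.DataFrame(
        rows, columns=["dragon_id", "site_id", "timestamp", "t_trans", "signal_strength"]
    )


class TestFilterDays:
    DAY = dt.date(2013, 1, 5)

    def _windows(self, site):
        return build_windows(site, [self.DAY])

    def test_full_day_retained(self, site, config):
        rec = _day_records("d01", self.DAY, 6, 20, site)
        kept, days = filter_days(rec, self._windows(site), config, site.utc_offset)
        assert len(days) == 1
        assert days["n_records"].iloc[0] == len(kept)
        assert not kept.empty

    def test_short_span_dropped(self, site, config):
        rec = _day_records("d01", self.DAY, 10, 17, site)  # 7 h
        kept, days = filter_days(rec, self._windows(site), config, site.utc_offset)
        assert days.empty and kept.empty

    def test_long_gap_dropped(self, site, config):
        skip = set(range(24, 37))  # 13 missing slots = 130 min
        rec = _day_records("d01", self.DAY, 6, 20, site, skip=skip)
        kept, days = filter_days(rec, self._windows(site), config, site.utc_offset)
        assert days.empty

    def test_sub_threshold_gap_retained(self, site, config):
        skip = set(range(24, 35))  # 11 missing slots = 110 min
        rec = _day_records("d01", self.DAY, 6, 20, site, skip=skip)
        kept, days = filter_days(rec, self._windows(site), config, site.utc_offset)
        assert len(days) == 1

    def test_nocturnal_records_excluded(self, site, config):
        rec = _day_records("d01", self.DAY, 0, 24, site)
        kept, _ = filter_days(rec, self._windows(site), config, site.utc_offset)
        win = self._windows(site)[self.DAY]
        assert kept["timestamp"].min() >= pd.Timestamp(win.sunrise)
        assert kept["timestamp"].max() <= pd.Timestamp(win.sunset)

    def test_filtering_monotone_in_added_records(self, site, config):
        # a retained day can never be dropped by adding more records
        base = _day_records("d01", self.DAY, 8, 19, site)
        kept_base, days_base = filter_days(base, self._windows(site), config, site.utc_offset)
        assert len(days_base) == 1
        more = _day_records("d01", self.DAY, 6, 20, site)
        kept_more, days_more = filter_days(more, self._windows(site), config, site.utc_offset)
        assert len(days_more) == 1
        assert days_more["n_records"].iloc[0] >= days_base["n_records"].iloc[0]


class TestMatching:
    def _micro(self, t_sun, t_shade, t_burrow):
        return pd.DataFrame(
            {
                "site_id": ["canberra"],
                "timestamp": [T0],
                "t_sun": [t_sun],
                "t_shade": [t_shade],
                "t_burrow": [t_burrow],
            }
        )

    @pytest.mark.parametrize(
        "t_trans,temps,expected,gap",
        [
            (25.0, (40.0, 26.0, 20.0), "shade", 1.0),
            (23.0, (40.0, 25.0, 21.0), "burrow", 2.0),  # tie: burrow preferred
            (65.0, (59.0, 38.0, 23.0), "sun", 6.0),
        ],
    )
    def test_nearest_habitat(self, t_trans, temps, expected, gap):
        rec = {"dragon_id": "d01", "site_id": "canberra", "timestamp": T0,
               "t_trans": t_trans}
        out = match_microhabitat(rec, self._micro(*temps))
        assert out["nearest"] == expected
        assert out["abs_gap"] == pytest.approx(gap)

    def test_missing_concurrent_record_raises(self):
        rec = {"dragon_id": "d01", "site_id": "canberra",
               "timestamp": T0 + pd.Timedelta(minutes=30), "t_trans": 25.0}
        with pytest.raises(ValueError, match="concurrent"):
            match_microhabitat(rec, self._micro(40.0, 26.0, 20.0))

    def test_match_series_agrees_with_single_record_matching(self):
        rng = np.random.default_rng(0)
        ts = pd.date_range(T0, periods=20, freq="10min")
        micro = pd.DataFrame(
            {
                "site_id": "canberra",
                "timestamp": ts,
                "t_sun": rng.uniform(30, 60, 20),
                "t_shade": rng.uniform(20, 35, 20),
                "t_burrow": rng.uniform(18, 28, 20),
            }
        )
        rec = pd.DataFrame(
            {
                "dragon_id": "d01",
                "site_id": "canberra",
                "timestamp": ts,
                "t_trans": rng.uniform(18, 50, 20),
            }
        )
        out = match_series(rec, micro)
        for i in range(len(rec)):
            single = match_microhabitat(rec.iloc[i].to_dict(), micro)
            assert out["nearest"].iloc[i] == single["nearest"]
            assert out["abs_gap"].iloc[i] == pytest.approx(single["abs_gap"])


class TestSummaries:
    def test_per_degree_mean(self):
        df = pd.DataFrame(
            {"t_shade": [20.1, 20.6, 20.9], "t_trans": [30.0, 30.0, 30.0],
             "t_sun": [40.0] * 3, "t_burrow": [18.0] * 3}
        )
        per_degree, _ = summarize_by_shade(df)
        assert per_degree.loc[per_degree["shade_degree"] == 20, "mean_t_trans"].iloc[0] == 30.0

    def test_bands_populated_left_closed(self):
        df = pd.DataFrame(
            {"t_shade": [14.0, 15.0, 16.0], "t_trans": [20.0, 21.0, 22.0],
             "t_sun": [30.0] * 3, "t_burrow": [15.0] * 3}
        )
        _, hist = summarize_by_shade(df)
        assert set(hist["band_mid"]) == {12.5, 17.5}

    def test_band_histograms_conserve_counts(self):
        rng = np.random.default_rng(1)
        n = 300
        df = pd.DataFrame(
            {
                "t_shade": rng.uniform(10, 40, n),
                "t_trans": rng.uniform(15, 45, n),
                "t_sun": rng.uniform(25, 65, n),
                "t_burrow": rng.uniform(12, 36, n),
            }
        )
        _, hist = summarize_by_shade(df)
        for var in ("t_trans", "t_sun", "t_burrow"):
            assert hist[hist["variable"] == var]["count"].sum() == n

    def test_uniform_values_give_flat_histogram(self):
        # evenly spread transmitter temps over [20, 25) -> equal 1-degC bins
        vals = np.repeat(np.arange(20, 25) + 0.5, 10)
        df = pd.DataFrame(
            {"t_shade": np.full(50, 22.0), "t_trans": vals,
             "t_sun": np.full(50, 35.0), "t_burrow": np.full(50, 20.0)}
        )
        _, hist = summarize_by_shade(df)
        counts = hist[hist["variable"] == "t_trans"]["count"]
        assert (counts == 10).all() and len(counts) == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_shade(pd.DataFrame(columns=["t_shade", "t_trans", "t_sun", "t_burrow"]))
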