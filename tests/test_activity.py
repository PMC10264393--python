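import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from dragontherm.activity import (
    classify_activity,
    daily_activity,
    fit_activity_quadratic,
    hourly_activity_by_band,
    predict_activity,
    wilson_interval,
)
from dragontherm.config import PipelineConfig
from conftest import make_slots


class TestClassifyActivity:
    def test_hand_traced_six_slot_day(self):
        # trace through both passes: (below-shade run at 5-6), (open at 2-4),
        # slot 1 satisfies nothing and defaults to inactive
        slots = make_slots([22, 34, 35, 36, 24, 23], t_shade=26, t_burrow=25)
        out = classify_activity(slots)
        assert list(out["state"]) == ["inactive", "active", "active", "active",
                                      "inactive", "inactive"]
        assert list(out["rule_fired"]) == [
            "carry_forward", "open_habitat", "open_habitat", "open_habitat",
            "cool_refuge_run", "cool_refuge_run",
        ]

    def test_stationary_run_overrides_open_habitat(self):
        # constant temperature above shade: stationary rule wins over "active"
        slots = make_slots([30.0, 30.1, 30.2, 30.1], t_shade=26, t_burrow=25)
        out = classify_activity(slots)
        assert (out["state"] == "inactive").all()
        assert (out["rule_fired"] == "stationary_run").all()

    def test_single_cool_slot_carries_forward_active_state(self):
        # one below-shade slot flanked by active slots: refuge run too short,
        # open rule fails, previous (active) state is inherited
        slots = make_slots([34, 36, 25, 35, 37], t_shade=26, t_burrow=24)
        out = classify_activity(slots)
        assert list(out["state"]) == ["active"] * 5
        assert out["rule_fired"].iloc[2] == "carry_forward"

    def test_flat_signal_marks_stationary_even_with_varying_temperature(self):
        slots = make_slots([30, 32, 34, 36], t_shade=26, t_burrow=24,
                           signal=[100.0, 100.5, 100.2, 100.4])
        out = classify_activity(slots)
        assert (out["state"] == "inactive").all()

    def test_runs_reset_at_slot_gaps(self):
        # two below-shade slots separated by a missing slot never form a run
        slots = make_slots([24.0, 34.0], t_shade=26, t_burrow=23)
        slots.loc[1, "timestamp"] = slots.loc[0, "timestamp"] + pd.Timedelta(minutes=20)
        extra = make_slots([24.0], t_shade=26, t_burrow=23,
                           start=slots.loc[0, "timestamp"] + pd.Timedelta(minutes=30))
        df = pd.concat([slots, extra], ignore_index=True)
        out = classify_activity(df)
        assert "cool_refuge_run" not in set(out["rule_fired"])

    def test_unmatched_slots_rejected(self):
        df = pd.DataFrame({"timestamp": pd.date_range("2013-01-05", periods=3, freq="10min"),
                           "t_trans": [30.0, 31.0, 32.0]})
        with pytest.raises(ValueError, match="matching"):
            classify_activity(df)

    def test_state_defined_for_every_slot(self):
        rng = np.random.default_rng(0)
        slots = make_slots(rng.uniform(18, 40, 60).tolist(), t_shade=26, t_burrow=24)
        out = classify_activity(slots)
        assert out["state"].isin(["active", "inactive"]).all()


class TestDailyActivity:
    @pytest.mark.parametrize("k,n,expected", [(30, 60, 0.5), (0, 40, 0.0), (48, 80, 0.6)])
    def test_proportion(self, k, n, expected):
        df = pd.DataFrame({"state": ["active"] * k + ["inactive"] * (n - k)})
        assert daily_activity(df) == pytest.approx(expected)

    def test_empty_day_rejected(self):
        with pytest.raises(ValueError):
            daily_activity(pd.DataFrame({"state": []}))


class TestWilsonInterval:
    def test_boundaries(self):
        lo, _ = wilson_interval(0, 10)
        _, hi = wilson_interval(10, 10)
        assert lo == 0.0 and hi == 1.0

    def test_frozen_closed_form_value(self):
        lo, hi = wilson_interval(5, 10, 0.95)
        assert lo == pytest.approx(0.2366, abs=2e-4)
        assert hi == pytest.approx(0.7634, abs=2e-4)

    def test_matches_statsmodels(self):
        for k, n in [(1, 7), (5, 10), (19, 20), (0, 3)]:
            lo, hi = wilson_interval(k, n, 0.95)
            ref_lo, ref_hi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(ref_lo, abs=1e-10)
            assert hi == pytest.approx(ref_hi, abs=1e-10)

    def test_equals_score_test_inversion(self):
        # independent oracle: root-find the score statistic's rejection boundary
        z = norm.ppf(0.975)

        def score(p, k, n):
            return (k / n - p) / np.sqrt(p * (1 - p) / n)

        for k, n in [(3, 12), (7, 15), (25, 50), (1, 50)]:
            lo, hi = wilson_interval(k, n, 0.95)
            root_lo = brentq(lambda p: score(p, k, n) - z, 1e-12, k / n) if k > 0 else 0.0
            root_hi = (
                brentq(lambda p: score(p, k, n) + z, k / n, 1 - 1e-12) if k < n else 1.0
            )
            assert lo == pytest.approx(root_lo, abs=1e-9)
            assert hi == pytest.approx(root_hi, abs=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilson_interval(1, 0)
        with pytest.raises(ValueError):
            wilson_interval(5, 3)

    @settings(max_examples=200, derandomize=True)
    @given(n=st.integers(1, 500), frac=st.floats(0, 1),
           conf=st.floats(0.5, 0.999))
    def test_interval_brackets_point_estimate_within_unit_range(self, n, frac, conf):
        k = round(frac * n)
        lo, hi = wilson_interval(k, n, conf)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestHourlyBands:
    def test_pooled_proportion_with_wilson_ci(self, site):
        slots = make_slots([30, 31, 32, 20], t_shade=26, t_burrow=24,
                           start="2013-01-05 00:00")
        slots["state"] = ["active", "active", "active", "inactive"]
        slots["date"] = pd.Timestamp("2013-01-05").date()
        table = hourly_activity_by_band(
            slots, {pd.Timestamp("2013-01-05").date(): 31.0}, utc_offset=site.utc_offset
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["band_mid"] == 32.5
        assert row["p_active"] == pytest.approx(0.75)
        lo, hi = wilson_interval(3, 4)
        assert row["ci_low"] == pytest.approx(lo)
        assert row["ci_high"] == pytest.approx(hi)

    def test_missing_tmax_rejected(self, site):
        slots = make_slots([30], t_shade=26, t_burrow=24)
        slots["state"] = ["active"]
        slots["date"] = pd.Timestamp("2013-01-05").date()
        with pytest.raises(ValueError, match="Tmax"):
            hourly_activity_by_band(slots, {}, utc_offset=site.utc_offset)


class TestQuadraticModel:
    def _days(self, tmax, prop):
        return pd.DataFrame({"tmax": tmax, "prop_active": prop})

    def test_noiseless_parabola_vertex_recovered(self):
        tmax = np.linspace(10, 42, 40)
        prop = np.clip(0.7 - 0.002 * (tmax - 26.0) ** 2, 0, 1)
        model = fit_activity_quadratic(self._days(tmax, prop))
        assert model.vertex == pytest.approx(26.0, abs=0.1)
        assert model.b2 < 0
        assert model.r2 > 0.999

    def test_constant_proportions_give_flat_fit(self):
        tmax = np.linspace(10, 42, 20)
        model = fit_activity_quadratic(self._days(tmax, np.full(20, 0.4)))
        assert model.b1 == pytest.approx(0.0, abs=1e-10)
        assert model.b2 == pytest.approx(0.0, abs=1e-12)

    def test_monte_carlo_vertex_recovery(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            tmax = rng.uniform(10, 42, 150)
            prop = 0.7 - 0.002 * (tmax - 26.0) ** 2 + rng.normal(0, 0.08, 150)
            model = fit_activity_quadratic(self._days(tmax, prop))
            hits += abs(model.vertex - 26.0) <= 1.5
        assert hits >= int(0.9 * n_seeds)

    def test_narrow_range_rejected(self):
        tmax = np.linspace(20, 25, 10)
        with pytest.raises(ValueError, match="narrow"):
            fit_activity_quadratic(self._days(tmax, np.full(10, 0.5)))

    def test_quadratic_r2_at_least_linear_r2(self, campaign):
        daily = campaign.daily_table
        quad = fit_activity_quadratic(daily)
        lin = np.polyfit(daily["tmax"], daily["prop_active"], 1)
        resid = daily["prop_active"] - np.polyval(lin, daily["tmax"])
        ss_tot = np.sum((daily["prop_active"] - daily["prop_active"].mean()) ** 2)
        r2_lin = 1 - np.sum(resid**2) / ss_tot
        assert quad.r2 >= r2_lin - 1e-12

    def test_prediction_clamps_to_floor_and_range(self):
        tmax = np.linspace(10, 40, 20)
        model = fit_activity_quadratic(self._days(tmax, np.zeros(20)))
        assert predict_activity(model, 25.0) == pytest.approx(model.activity_floor)
        val, flag = predict_activity(model, 44.0, with_flag=True)
        assert flag is True
        assert val == pytest.approx(predict_activity(model, 40.0))

    def test_vertex_prediction_is_maximum_for_hump(self):
        tmax = np.linspace(10, 42, 40)
        prop = np.clip(0.7 - 0.002 * (tmax - 26.0) ** 2, 0, 1)
        model = fit_activity_quadratic(self._days(tmax, prop))
        p_vertex = predict_activity(model, model.vertex)
        assert p_vertex <= 1.0
        grid = np.linspace(10, 42, 100)
        assert p_vertex >= predict_activity(model, grid).max() - 1e-9
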