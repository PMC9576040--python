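import numpy as np
import pandas as pd
import pytest

from matesite import season, segmentation as seg


def _visits(rows):
    return pd.DataFrame(
        [
            (sid, pd.Timestamp(a), pd.Timestamp(b), n,
             (pd.Timestamp(b) - pd.Timestamp(a)) / pd.Timedelta(hours=1))
            for sid, a, b, n in rows
        ],
        columns=["shark_id", "start", "end", "n_detections", "duration_h"],
    )


def _strings(rows):
    return pd.DataFrame(
        [
            (sid, pd.Timestamp(a), pd.Timestamp(b), n, False, False, False)
            for sid, a, b, n in rows
        ],
        columns=[
            "shark_id", "arrival", "departure", "n_detections",
            "excluded_tagging_bias", "left_censored", "right_censored",
        ],
    )


@pytest.fixture
def registry():
    return pd.DataFrame(
        {
            "shark_id": ["F1", "M1"],
            "sex": ["F", "M"],
            "tagging_date": pd.to_datetime(["2003-06-15", "2003-06-10"]),
            "tag_types": ["PIT+acoustic", "PIT+acoustic"],
        }
    )


class TestSeasonSummaries:
    def test_two_visit_arithmetic(self, registry):
        visits = _visits(
            [
                ("F1", "2004-06-10 00:00", "2004-06-10 02:00", 10),
                ("F1", "2004-07-01 00:00", "2004-07-01 06:00", 20),
            ]
        )
        strings = _strings([("F1", "2004-06-10 00:00", "2004-07-01 06:00", 30)])
        out = season.season_summaries(visits, strings, registry)
        row = out.iloc[0]
        assert row["n_visits"] == 2
        assert row["mean_visit_duration_h"] == pytest.approx(4.0)
        assert row["cumulative_days"] == pytest.approx(8 / 24)
        assert row["span_days"] == pytest.approx(21.25)

    def test_tagging_year_omitted(self, registry):
        visits = _visits([("F1", "2003-06-20 00:00", "2003-06-20 02:00", 5)])
        out = season.season_summaries(visits, _strings([]), registry)
        assert out.empty
        kept = season.season_summaries(
            visits, _strings([]), registry, exclude_tagging_year=False
        )
        assert len(kept) == 1

    def test_three_season_fixture_matches_hand_computation(self, registry):
        visits = _visits(
            [
                ("M1", "2004-06-05 00:00", "2004-06-05 01:00", 5),
                ("M1", "2004-06-06 00:00", "2004-06-06 03:00", 5),
                ("M1", "2005-06-05 00:00", "2005-06-05 02:00", 5),
                ("M1", "2006-07-05 00:00", "2006-07-05 04:00", 5),
                ("M1", "2006-07-06 00:00", "2006-07-06 06:00", 5),
            ]
        )
        out = season.season_summaries(visits, _strings([]), registry)
        got = out.set_index("season_year")
        assert got.loc[2004, "n_visits"] == 2
        assert got.loc[2004, "mean_visit_duration_h"] == pytest.approx(2.0)
        assert got.loc[2005, "cumulative_days"] == pytest.approx(2 / 24)
        assert got.loc[2006, "mean_visit_duration_h"] == pytest.approx(5.0)

    def test_visit_crossing_window_boundary_is_clipped(self, registry):
        visits = _visits([("F1", "2004-07-31 22:00", "2004-08-01 06:00", 9)])
        out = season.season_summaries(visits, _strings([]), registry)
        # only the 2 h inside July count
        assert out.iloc[0]["cumulative_days"] == pytest.approx(2 / 24)

    def test_row_order_invariance(self, registry):
        visits = _visits(
            [
                ("F1", "2004-06-10 00:00", "2004-06-10 02:00", 1),
                ("M1", "2004-06-11 00:00", "2004-06-11 01:00", 1),
                ("F1", "2004-07-02 00:00", "2004-07-02 03:00", 1),
            ]
        )
        a = season.season_summaries(visits, _strings([]), registry)
        b = season.season_summaries(
            visits.iloc[::-1].reset_index(drop=True), _strings([]), registry
        )
        pd.testing.assert_frame_equal(a, b)


class TestHourlyProfile:
    def _det(self, stamps, shark="F1"):
        return pd.DataFrame(
            {"shark_id": shark, "timestamp": pd.to_datetime(stamps),
             "station": "DTCMG"}
        )

    def test_single_hour_every_season(self, registry):
        det = self._det(
            ["2004-06-05 10:00", "2004-06-06 10:30", "2005-07-01 10:15"]
        )
        out = season.hourly_profile(det, registry)
        prof = out.set_index("hour_of_day")
        assert prof.loc[10, "mean_proportion"] == pytest.approx(1.0)
        assert prof.loc[10, "sd_proportion"] == pytest.approx(0.0)
        assert prof["mean_proportion"].sum() == pytest.approx(1.0)

    def test_uniform_detections(self, registry):
        stamps = [f"2004-06-05 {h:02d}:00" for h in range(24)]
        out = season.hourly_profile(self._det(stamps), registry)
        assert np.allclose(out["mean_proportion"], 1 / 24)

    def test_two_season_closed_form_sd(self, registry):
        det = self._det(["2004-06-05 10:00", "2005-06-05 14:00"])
        out = season.hourly_profile(det, registry).set_index("hour_of_day")
        assert out.loc[10, "mean_proportion"] == pytest.approx(0.5)
        assert out.loc[14, "mean_proportion"] == pytest.approx(0.5)
        # sample SD of {1, 0} over two seasons
        assert out.loc[10, "sd_proportion"] == pytest.approx(np.sqrt(0.5), abs=1e-12)

    def test_tagging_year_excluded(self, registry):
        det = self._det(["2003-06-20 09:00", "2004-06-05 10:00"])  # tagged 2003
        out = season.hourly_profile(det, registry).set_index("hour_of_day")
        assert out.loc[9, "mean_proportion"] == 0.0
        assert out.loc[10, "mean_proportion"] == pytest.approx(1.0)


class TestMonthlyEvents:
    def test_all_june_arrivals(self, registry):
        strings = _strings(
            [("F1", f"2004-06-{d:02d} 06:00", f"2004-06-{d + 1:02d} 06:00", 3)
             for d in range(10, 20)]
        )
        out = season.monthly_event_proportions(strings, registry)
        june_arr = out[(out.month == 6) & (out.event == "arrival") & (out.sex == "F")]
        assert june_arr["proportion"].iloc[0] == pytest.approx(1.0)

    def test_mixed_month_proportions(self, registry):
        strings = _strings(
            [
                ("F1", "2004-06-10", "2004-06-20", 5),
                ("F1", "2005-06-12", "2005-06-25", 5),
                ("F1", "2006-06-11", "2006-06-21", 5),
                ("F1", "2007-05-20", "2007-06-05", 5),
            ]
        )
        out = season.monthly_event_proportions(strings, registry)
        arr = out[(out.event == "arrival") & (out.sex == "F")].set_index("month")
        assert arr.loc[6, "proportion"] == pytest.approx(0.75)
        assert arr.loc[5, "proportion"] == pytest.approx(0.25)

    def test_excluded_and_censored_strings_not_counted(self, registry):
        strings = _strings([("F1", "2004-06-10", "2004-06-20", 5)])
        strings.loc[0, "excluded_tagging_bias"] = True
        out = season.monthly_event_proportions(strings, registry)
        assert out["n_events"].sum() == 0

    def test_simplex_per_sex_event(self, small_sim):
        strings = seg.strings_frame(
            small_sim["detections"], small_sim["registry"]
        )
        out = season.monthly_event_proportions(strings, small_sim["registry"])
        sums = out.groupby(["sex", "event"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)


class TestDailyBins:
    def test_many_detections_one_day(self, registry):
        det = pd.DataFrame(
            {
                "shark_id": "F1",
                "timestamp": pd.date_range("2004-09-03 00:00", periods=100,
                                           freq="5min"),
                "station": "DTCMG",
            }
        )
        days, monthly = season.daily_detection_bins(det, registry)
        assert len(days) == 1
        assert monthly.set_index(["sex", "month"]).loc[("F", 9),
                                                       "n_shark_days"] == 1

    def test_three_september_days(self, registry):
        det = pd.DataFrame(
            {
                "shark_id": "F1",
                "timestamp": pd.to_datetime(
                    ["2004-09-03 01:00", "2004-09-07 02:00", "2004-09-20 03:00"]
                ),
                "station": "DTCMG",
            }
        )
        _, monthly = season.daily_detection_bins(det, registry)
        assert monthly.set_index(["sex", "month"]).loc[("F", 9),
                                                       "n_shark_days"] == 3


class TestWeeklyTemperature:
    def test_constant_series(self):
        idx = pd.date_range("2004-06-01", periods=24 * 14, freq="h")
        df = pd.DataFrame({"timestamp": idx, "temp_c": 30.0})
        out = season.weekly_max_temperature(df)
        assert np.allclose(out["mean_daily_max_c"], 30.0)
        assert np.allclose(out["sd_daily_max_c"], 0.0)

    def test_two_day_closed_form(self):
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2004-06-07 12:00", "2004-06-08 12:00"]),
                "temp_c": [28.0, 32.0],
            }
        )
        out = season.weekly_max_temperature(df)
        assert len(out) == 1
        assert out.iloc[0]["mean_daily_max_c"] == pytest.approx(30.0)
        assert out.iloc[0]["sd_daily_max_c"] == pytest.approx(2 * np.sqrt(2), rel=1e-6)

    def test_empty(self):
        out = season.weekly_max_temperature(
            pd.DataFrame(columns=["timestamp", "temp_c"])
        )
        assert out.empty
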