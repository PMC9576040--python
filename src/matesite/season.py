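"""Within-season residency metrics, diel profiles, phenology bins, temperature.

Residency metrics follow the site-use conventions of the monitoring study:
visits are assigned to the June–July mating window of the year they touch
(clipped to the window when they cross its boundary), visit durations are
averaged within each shark-season so that seasons are equally weighted, and
the tagging-year season of each shark is dropped to avoid sampling bias.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .segmentation import mating_window_bounds

logger = logging.getLogger("matesite")


def _sex_lookup(registry: pd.DataFrame) -> pd.Series:
    return registry.set_index("shark_id")["sex"]


def _tag_year_lookup(registry: pd.DataFrame) -> pd.Series:
    return registry.set_index("shark_id")["tagging_date"].dt.year


def _clip_visits_to_window(visits: pd.DataFrame) -> pd.DataFrame:
    """Assign visits to mating-window seasons, clipping boundary-crossers.

    A visit contributes to a season if it overlaps [Jun 1, Aug 1) of that
    year. Visits wholly outside every window are dropped.
    """
    rows = []
    n_clipped = 0
    for row in visits.itertuples(index=False):
        for year in {row.start.year, row.end.year}:
            lo, hi = mating_window_bounds(year)
            start, end = max(row.start, lo), min(row.end, hi)
            if start >= hi or end < lo or start > end:
                continue
            if start != row.start or end != row.end:
                n_clipped += 1
            rows.append(
                (
                    row.shark_id,
                    year,
                    start,
                    end,
                    row.n_detections,
                    (end - start) / pd.Timedelta(hours=1),
                )
            )
    if n_clipped:
        logger.info("season_summaries: clipped %d visit(s) to the mating window",
                    n_clipped)
    return pd.DataFrame(
        rows,
        columns=["shark_id", "season_year", "start", "end", "n_detections",
                 "duration_h"],
    )


def season_summaries(
    visits: pd.DataFrame,
    strings: pd.DataFrame,
    registry: pd.DataFrame,
    exclude_tagging_year: bool = True,
) -> pd.DataFrame:
    """Per shark-season residency metrics for the mating window.

    Returns one row per (shark, season) with at least one mating-window
    visit: number of visits, mean visit duration (hours; equal weight per
    season), cumulative time on site (days, visit durations clipped to the
    window), and arrival→departure span (days) of the presence string
    overlapping that window (the longest-overlap string when several do).
    """
    if visits.empty:
        return pd.DataFrame(
            columns=["shark_id", "season_year", "n_visits", "mean_visit_duration_h",
                     "cumulative_days", "span_days"]
        )
    clipped = _clip_visits_to_window(visits)
    if exclude_tagging_year:
        tag_year = _tag_year_lookup(registry)
        keep = clipped["season_year"] != clipped["shark_id"].map(tag_year)
        clipped = clipped[keep.fillna(True)]
    if clipped.empty:
        return pd.DataFrame(
            columns=["shark_id", "season_year", "n_visits", "mean_visit_duration_h",
                     "cumulative_days", "span_days"]
        )
    agg = (
        clipped.groupby(["shark_id", "season_year"])
        .agg(
            n_visits=("duration_h", "size"),
            mean_visit_duration_h=("duration_h", "mean"),
            cumulative_days=("duration_h", lambda d: d.sum() / 24.0),
        )
        .reset_index()
    )
    spans = mating_spans(strings)
    if not spans.empty:
        # longest window-overlap string represents the season's span
        best = (
            spans.sort_values("overlap_days")
            .groupby(["shark_id", "season_year"])
            .tail(1)[["shark_id", "season_year", "span_days"]]
        )
        agg = agg.merge(best, on=["shark_id", "season_year"], how="left")
    else:
        agg["span_days"] = np.nan
    return agg


def mating_spans(strings: pd.DataFrame) -> pd.DataFrame:
    """Arrival→departure spans of presence strings overlapping mating windows.

    One row per (string, overlapped season): a presence string is the unit
    of arrival→departure, so each contributes one span observation per
    season it overlaps, never a sum. Tagging-biased strings and singletons
    are dropped.
    """
    rows = []
    if strings.empty:
        return pd.DataFrame(
            columns=["shark_id", "season_year", "span_days", "overlap_days"]
        )
    usable = strings[
        (~strings["excluded_tagging_bias"]) & (strings["n_detections"] >= 2)
    ]
    for row in usable.itertuples(index=False):
        for year in range(row.arrival.year, row.departure.year + 1):
            lo, hi = mating_window_bounds(year)
            overlap = (min(row.departure, hi) - max(row.arrival, lo)) / pd.Timedelta(
                days=1
            )
            if overlap < 0:
                continue
            rows.append(
                (
                    row.shark_id,
                    year,
                    (row.departure - row.arrival) / pd.Timedelta(days=1),
                    overlap,
                )
            )
    return pd.DataFrame(
        rows, columns=["shark_id", "season_year", "span_days", "overlap_days"]
    )


def hourly_profile(
    detections: pd.DataFrame,
    registry: pd.DataFrame,
    exclude_tagging_year: bool = True,
) -> pd.DataFrame:
    """Mean and SD of hourly detection proportions across mating seasons.

    For each (sex, season) the 24-bin hour-of-day proportion vector is
    computed from mating-window detections (a simplex), then the mean and
    sample SD are taken across seasons within each sex. Seasons with no
    detections contribute nothing; a sex observed in a single season gets
    SD 0 (no between-season variation observed).
    """
    det = detections.copy()
    det["season_year"] = det["timestamp"].dt.year
    in_window = det["timestamp"].dt.month.isin((6, 7))
    det = det[in_window]
    if exclude_tagging_year:
        tag_year = _tag_year_lookup(registry)
        det = det[det["season_year"] != det["shark_id"].map(tag_year)]
    det["sex"] = det["shark_id"].map(_sex_lookup(registry))
    det["hour"] = det["timestamp"].dt.hour
    out = []
    for sex, grp in det.groupby("sex"):
        vectors = []
        for _, season_grp in grp.groupby("season_year"):
            counts = np.bincount(season_grp["hour"], minlength=24).astype(float)
            vectors.append(counts / counts.sum())
        mat = np.vstack(vectors)
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1) if len(vectors) > 1 else np.zeros(24)
        for h in range(24):
            out.append((sex, h, mean[h], sd[h]))
    return pd.DataFrame(
        out, columns=["sex", "hour_of_day", "mean_proportion", "sd_proportion"]
    )


def monthly_event_proportions(
    strings: pd.DataFrame, registry: pd.DataFrame
) -> pd.DataFrame:
    """Monthly proportions of arrival and departure events per sex.

    Uses presence strings with >= 2 detections (an arrival and a departure
    event are distinct detections), dropping tagging-biased strings;
    left-censored strings contribute no arrival, right-censored strings no
    departure. Proportions sum to 1 within each (sex, event).
    """
    sex = _sex_lookup(registry)
    usable = strings[
        (~strings["excluded_tagging_bias"]) & (strings["n_detections"] >= 2)
    ].copy()
    usable["sex"] = usable["shark_id"].map(sex)
    rows = []
    for event, time_col, censor_col in (
        ("arrival", "arrival", "left_censored"),
        ("departure", "departure", "right_censored"),
    ):
        events = usable[~usable[censor_col]]
        for s, grp in events.groupby("sex"):
            counts = grp[time_col].dt.month.value_counts()
            total = counts.sum()
            for month in range(1, 13):
                n = int(counts.get(month, 0))
                rows.append((s, month, event, n / total if total else 0.0, n))
    return pd.DataFrame(
        rows, columns=["sex", "month", "event", "proportion", "n_events"]
    )


def daily_detection_bins(
    detections: pd.DataFrame, registry: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shark-day presence table and per-sex monthly shark-day totals.

    A shark-day is counted once regardless of how many detections occurred
    that day (all-year data, not restricted to the mating window).
    """
    days = (
        detections.assign(date=detections["timestamp"].dt.normalize())[
            ["shark_id", "date"]
        ]
        .drop_duplicates()
        .reset_index(drop=True)
    )
    days["sex"] = days["shark_id"].map(_sex_lookup(registry))
    monthly = (
        days.assign(month=days["date"].dt.month)
        .groupby(["sex", "month"])
        .size()
        .rename("n_shark_days")
        .reset_index()
    )
    return days, monthly


def weekly_max_temperature(temperature: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of the daily maximum temperature per ISO week, across years."""
    if temperature.empty:
        return pd.DataFrame(columns=["iso_week", "mean_daily_max_c", "sd_daily_max_c",
                                     "n_days"])
    t = temperature.copy()
    t["date"] = t["timestamp"].dt.normalize()
    daily = t.groupby("date")["temp_c"].max().reset_index()
    daily["iso_week"] = daily["date"].dt.isocalendar().week.astype(int)
    out = (
        daily.groupby("iso_week")["temp_c"]
        .agg(
            mean_daily_max_c="mean",
            sd_daily_max_c=lambda d: d.std(ddof=1) if len(d) > 1 else 0.0,
            n_days="size",
        )
        .reset_index()
    )
    return out
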