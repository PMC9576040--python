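"""Segmentation of per-shark detection streams into visits and presence bouts.

Two nested time scales are used throughout the analysis:

* a **visit** is a maximal run of detections with every internal gap shorter
  than 60 minutes — the unit of fine-scale, within-season site use;
* a **presence string** is a maximal run with every internal gap shorter
  than 30 days — an arrival→departure bout whose first detection is an
  arrival event and last detection a departure event.

Gap comparison is "gap >= threshold splits": a gap of exactly 60 minutes
(or exactly 30 days) starts a new segment. Strings adjacent to the edge of
the observed stream are flagged edge-censored because their bounding absence
is unobserved; strings that begin between tagging and the following April
are flagged so phenology consumers can drop the post-tagging disturbance
period. Singleton strings (one isolated detection) are kept but flagged via
``n_detections`` so consumers that require both an arrival and a departure
event can drop them without losing data here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Mating season window, inclusive: June 1 .. July 31.
MATING_WINDOW = ((6, 1), (7, 31))

DEFAULT_VISIT_GAP_MIN = 60.0
DEFAULT_STRING_GAP_DAYS = 30.0


@dataclass(frozen=True)
class Visit:
    """A maximal detection run with no internal gap >= the visit threshold."""

    shark_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_detections: int

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class PresenceString:
    """An arrival→departure bout bounded by >= 30-day absences.

    ``left_censored`` / ``right_censored`` mark bouts whose bounding absence
    is unobserved (stream edge); ``excluded_tagging_bias`` marks bouts that
    begin between tagging and the following April.
    """

    shark_id: str
    arrival: pd.Timestamp
    departure: pd.Timestamp
    n_detections: int
    excluded_tagging_bias: bool = False
    left_censored: bool = False
    right_censored: bool = False

    @property
    def singleton(self) -> bool:
        return self.n_detections == 1

    @property
    def span_days(self) -> float:
        return (self.departure - self.arrival) / pd.Timedelta(days=1)


def _as_datetime_array(timestamps) -> np.ndarray:
    ts = pd.DatetimeIndex(timestamps).values.astype("datetime64[ns]")
    if len(ts) > 1 and (np.diff(ts) < np.timedelta64(0, "ns")).any():
        raise ValueError("detections must be sorted ascending in time")
    return ts

def _split_runs(ts: np.ndarray, gap: np.timedelta64) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal runs whose internal gaps are < gap."""
    if len(ts) == 0:
        return []
    breaks = np.nonzero(np.diff(ts) >= gap)[0] + 1
    bounds = np.concatenate(([0], breaks, [len(ts)]))
    return [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:])]


def segment_visits(
    timestamps, shark_id: str = "", gap_minutes: float = DEFAULT_VISIT_GAP_MIN
) -> list[Visit]:
    """Split one shark's sorted detection times into visits.

    Splits exactly where an inter-detection gap is >= ``gap_minutes``. A
    single isolated detection forms a zero-duration visit. Raises
    ``ValueError`` on unsorted input.
    """
    ts = _as_datetime_array(timestamps)
    gap = np.timedelta64(int(round(gap_minutes * 60 * 1e9)), "ns")
    return [
        Visit(shark_id, pd.Timestamp(ts[a]), pd.Timestamp(ts[b - 1]), b - a)
        for a, b in _split_runs(ts, gap)
    ]


def extract_presence_strings(
    timestamps,
    shark_id: str = "",
    gap_days: float = DEFAULT_STRING_GAP_DAYS,
    stream_start: pd.Timestamp | None = None,
    stream_end: pd.Timestamp | None = None,
) -> list[PresenceString]:
    """Split one shark's sorted detection times into presence strings.

    ``stream_start`` / ``stream_end`` bound the period over which absences
    were observable (e.g. receiver deployment). A string whose bounding
    absence cannot be verified against these bounds (or when they are
    omitted) is flagged left-/right-censored.
    """
    ts = _as_datetime_array(timestamps)
    gap = np.timedelta64(int(round(gap_days * 24 * 3600 * 1e9)), "ns")
    runs = _split_runs(ts, gap)
    out: list[PresenceString] = []
    for i, (a, b) in enumerate(runs):
        arrival = pd.Timestamp(ts[a])
        departure = pd.Timestamp(ts[b - 1])
        left = i == 0 and (
            stream_start is None
            or (arrival - pd.Timestamp(stream_start)) < pd.Timedelta(days=gap_days)
        )
        right = i == len(runs) - 1 and (
            stream_end is None
            or (pd.Timestamp(stream_end) - departure) < pd.Timedelta(days=gap_days)
        )
        out.append(
            PresenceString(
                shark_id,
                arrival,
                departure,
                b - a,
                left_censored=left,
                right_censored=right,
            )
        )
    return out


def tagging_exclusion_cutoff(tagging_date: pd.Timestamp) -> pd.Timestamp:
    """Last day (inclusive) of the post-tagging exclusion window.

    Bouts beginning between tagging and the first April 30 after the tagging
    date are excluded from phenology to remove tagging disturbance; mating
    season arrivals typically begin in May.
    """
    tagging_date = pd.Timestamp(tagging_date)
    year = tagging_date.year if tagging_date.month <= 4 else tagging_date.year + 1
    return pd.Timestamp(year=year, month=4, day=30)


def apply_tagging_exclusion(
    strings: list[PresenceString], tagging_date: pd.Timestamp
) -> list[PresenceString]:
    """Flag strings arriving in [tagging_date, following April 30] (kept, flagged)."""
    tagging_date = pd.Timestamp(tagging_date)
    cutoff = tagging_exclusion_cutoff(tagging_date) + pd.Timedelta(days=1)
    return [
        replace(
            s,
            excluded_tagging_bias=bool(
                tagging_date.normalize() <= s.arrival < cutoff
            ),
        )
        for s in strings
    ]


def assign_season(instant) -> tuple[int, bool]:
    """Map an instant to (season_year, inside June 1 – July 31 inclusive)."""
    t = pd.Timestamp(instant)
    return t.year, (t.month, t.day) >= MATING_WINDOW[0] and (
        t.month,
        t.day,
    ) <= MATING_WINDOW[1]


def mating_window_bounds(year: int) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Half-open [June 1, August 1) bounds of the mating window for a year."""
    return pd.Timestamp(year=year, month=6, day=1), pd.Timestamp(
        year=year, month=8, day=1
    )


# ---------------------------------------------------------------------------
# Frame-level drivers (all sharks at once)

def visits_frame(
    detections: pd.DataFrame, gap_minutes: float = DEFAULT_VISIT_GAP_MIN
) -> pd.DataFrame:
    """Segment a full detection table into a tidy visit frame."""
    rows = []
    for shark_id, grp in detections.groupby("shark_id", sort=True):
        for v in segment_visits(grp["timestamp"], shark_id, gap_minutes):
            rows.append((v.shark_id, v.start, v.end, v.n_detections, v.duration_h))
    return pd.DataFrame(
        rows, columns=["shark_id", "start", "end", "n_detections", "duration_h"]
    )


def strings_frame(
    detections: pd.DataFrame,
    registry: pd.DataFrame | None = None,
    gap_days: float = DEFAULT_STRING_GAP_DAYS,
    stream_start: pd.Timestamp | None = None,
    stream_end: pd.Timestamp | None = None,
) -> pd.DataFrame:
    """Extract presence strings for every shark, applying tagging exclusion.

    When a registry is given, each shark's post-tagging bouts are flagged
    ``excluded_tagging_bias`` and the stream start defaults to its tagging
    date (absences before tagging are unobservable).
    """
    tagging = (
        registry.set_index("shark_id")["tagging_date"] if registry is not None else None
    )
    rows = []
    for shark_id, grp in detections.groupby("shark_id", sort=True):
        start = stream_start
        if start is None and tagging is not None and shark_id in tagging.index:
            start = tagging[shark_id]
        strings = extract_presence_strings(
            grp["timestamp"], shark_id, gap_days, start, stream_end
        )
        if tagging is not None and shark_id in tagging.index:
            strings = apply_tagging_exclusion(strings, tagging[shark_id])
        for s in strings:
            rows.append(
                (
                    s.shark_id,
                    s.arrival,
                    s.departure,
                    s.n_detections,
                    s.excluded_tagging_bias,
                    s.left_censored,
                    s.right_censored,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "shark_id",
            "arrival",
            "departure",
            "n_detections",
            "excluded_tagging_bias",
            "left_censored",
            "right_censored",
        ],
    )
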