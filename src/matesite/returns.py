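"""Multi-year return histories, reproductive-cycle classification, cohort stats.

A shark is "present" in a mating season (June 1 – July 31) if *any*
identification method — capture, PIT scan, visual resight, or acoustic
detection — records it inside the window that year. Return intervals are
whole-year differences between consecutive present seasons. Female
reproductive cycles are read off the interval sequence: 2-year and 3-year
intervals are biennial/triennial reproduction, intervals of four years or
longer may hide a missed mating year and are excluded from cycle statistics,
and 1-year female intervals are treated as identification noise by default
(post-mating females are nearly always absent the following season).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

#: Identification methods ordered most- to least-verifiable.
DEFAULT_METHOD_RANK = ("capture", "PIT_scan", "visual", "acoustic")


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (58.75% -> 59%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class ReturnHistory:
    """One shark's mating-season presence history across the study."""

    shark_id: str
    sex: str
    tag_season: int
    seasons_present: tuple[int, ...]
    time_at_large_years: int
    method_by_season: dict[int, str] = field(default_factory=dict)

    @property
    def n_seasons(self) -> int:
        return len(self.seasons_present)

    @property
    def intervals(self) -> list[int]:
        return return_intervals(self.seasons_present)

    @property
    def is_returning(self) -> bool:
        return self.n_seasons >= 2 or (
            self.n_seasons == 1 and self.seasons_present[0] > self.tag_season
        )


@dataclass
class CycleClassification:
    """Cycle composition and switching of one shark's interval sequence."""

    shark_id: str
    n_two_year: int
    n_three_year: int
    n_long: int          # intervals >= 4 y: a mating year may have been missed
    n_one_year: int      # female 1-y intervals: identification noise by default
    n_switches: int      # adjacent unequal values in the retained 2/3 sequence

    @property
    def switched_once(self) -> bool:
        return self.n_switches >= 1

    @property
    def switched_multiple(self) -> bool:
        return self.n_switches >= 2


def build_presence(
    sightings: pd.DataFrame,
    detections: pd.DataFrame,
    registry: pd.DataFrame,
    method_rank: tuple[str, ...] = DEFAULT_METHOD_RANK,
) -> list[ReturnHistory]:
    """Fuse all identification methods into per-shark return histories.

    Every identification (sighting rows plus acoustic detections) counts;
    a season is present iff any identification falls in its June–July
    window, and each present season also records the most-verifiable method
    per ``method_rank``. Time-at-large is the integer-year difference
    between the first and most recent identification of any kind.
    Identifications predating the tagging date are an error.
    """
    ids = []
    if len(sightings):
        ids.append(
            sightings.rename(columns={"date": "when"})[["shark_id", "when", "method"]]
        )
    if len(detections):
        ids.append(
            detections.rename(columns={"timestamp": "when"})[["shark_id", "when"]]
            .assign(method="acoustic")
        )
    all_ids = (
        pd.concat(ids, ignore_index=True)
        if ids
        else pd.DataFrame(columns=["shark_id", "when", "method"])
    )
    rank = {m: i for i, m in enumerate(method_rank)}
    tagging = registry.set_index("shark_id")["tagging_date"]
    histories = []
    for row in registry.itertuples(index=False):
        mine = all_ids[all_ids["shark_id"] == row.shark_id]
        if len(mine):
            early = mine["when"].dt.normalize() < tagging[row.shark_id].normalize()
            if early.any():
                raise ValueError(
                    f"{row.shark_id}: identification on "
                    f"{mine.loc[early.idxmax(), 'when']} predates tagging date "
                    f"{tagging[row.shark_id].date()}"
                )
        in_window = mine[mine["when"].dt.month.isin((6, 7))]
        method_by_season = {
            int(year): min(grp["method"], key=lambda m: rank.get(m, len(rank)))
            for year, grp in in_window.groupby(in_window["when"].dt.year)
        }
        seasons = tuple(sorted(method_by_season))
        if len(mine):
            years = mine["when"].dt.year
            time_at_large = int(years.max() - years.min())
        else:
            time_at_large = 0
        histories.append(
            ReturnHistory(
                shark_id=row.shark_id,
                sex=row.sex,
                tag_season=int(row.tagging_date.year),
                seasons_present=seasons,
                time_at_large_years=time_at_large,
                method_by_season=method_by_season,
            )
        )
    return histories


def return_intervals(seasons_present) -> list[int]:
    """Whole-year gaps between consecutive mating seasons present."""
    years = sorted(seasons_present)
    return [int(b - a) for a, b in zip(years[:-1], years[1:])]


def classify_cycles(
    intervals, shark_id: str = "", exclude_one_year: bool = True
) -> CycleClassification:
    """Classify an interval sequence into cycle counts and switches.

    The retained chronological sequence keeps only 2- and 3-year intervals;
    a switch is any adjacent unequal pair in that sequence, so a female with
    retained sequence (2, 3, 2) switched twice. When ``exclude_one_year`` is
    False, 1-year intervals are tallied but still cannot join the 2/3
    sequence (they are neither cycle length); the flag only controls whether
    they are reported as noise or as genuine presence in cohort reports.
    """
    intervals = list(intervals)
    retained = [i for i in intervals if i in (2, 3)]
    return CycleClassification(
        shark_id=shark_id,
        n_two_year=retained.count(2),
        n_three_year=retained.count(3),
        n_long=sum(1 for i in intervals if i >= 4),
        n_one_year=intervals.count(1),
        n_switches=sum(1 for a, b in zip(retained[:-1], retained[1:]) if a != b),
    )


def cohort_statistics(
    histories: list[ReturnHistory],
    min_tag_year: int,
    max_tag_year: int,
    as_of_season: int,
    monitored_gt_years: tuple[int, int] = (10, 20),
    switcher_min_tenure_years: int = 10,
) -> dict:
    """Cohort-level return and cycle statistics.

    Restricted to sharks tagged in [min_tag_year, max_tag_year]. "Monitored
    over 10 (20) years" means time-at-large strictly greater than 10 (20)
    integer years. Switch statistics pool returning females whose tag tenure
    (``as_of_season`` minus tag season) is at least ``switcher_min_tenure``.
    Percentages are rounded half-up to integers except the triennial share,
    which is left at full precision for downstream lifetime-output inputs.
    """
    cohort = [h for h in histories if min_tag_year <= h.tag_season <= max_tag_year]
    if not cohort:
        raise ValueError(
            f"empty cohort for tag years {min_tag_year}..{max_tag_year}"
        )
    returners = [h for h in cohort if h.is_returning]
    n_tagged, n_returning = len(cohort), len(returners)

    def _pct(num: int, den: int) -> int:
        return round_half_up(100.0 * num / den) if den else 0

    g10, g20 = monitored_gt_years
    n_gt10 = sum(1 for h in returners if h.time_at_large_years > g10)
    n_gt20 = sum(1 for h in returners if h.time_at_large_years > g20)

    per_sex = {}
    for sex in ("F", "M"):
        rs = [h for h in returners if h.sex == sex]
        per_sex[sex] = {
            "n_returning": len(rs),
            "median_n_seasons": (
                float(pd.Series([h.n_seasons for h in rs]).median()) if rs else None
            ),
            "median_time_at_large_y": (
                float(pd.Series([h.time_at_large_years for h in rs]).median())
                if rs
                else None
            ),
        }

    female_cls = [
        classify_cycles(h.intervals, h.shark_id)
        for h in returners
        if h.sex == "F"
    ]
    n_two = sum(c.n_two_year for c in female_cls)
    n_three = sum(c.n_three_year for c in female_cls)
    triennial_share_pct = 100.0 * n_three / (n_two + n_three) if n_two + n_three else None

    eligible = [
        (h, classify_cycles(h.intervals, h.shark_id))
        for h in returners
        if h.sex == "F" and (as_of_season - h.tag_season) >= switcher_min_tenure_years
    ]
    n_eligible = len(eligible)
    n_switch = sum(1 for _, c in eligible if c.switched_once)
    n_multi = sum(1 for _, c in eligible if c.switched_multiple)

    return {
        "n_tagged": n_tagged,
        "n_returning": n_returning,
        "pct_returning": _pct(n_returning, n_tagged),
        "n_monitored_gt10y": n_gt10,
        "pct_monitored_gt10y": _pct(n_gt10, n_returning),
        "n_monitored_gt20y": n_gt20,
        "pct_monitored_gt20y": _pct(n_gt20, n_returning),
        "per_sex": per_sex,
        "female_intervals_two_year": n_two,
        "female_intervals_three_year": n_three,
        "triennial_share_pct": triennial_share_pct,
        "n_switch_eligible_females": n_eligible,
        "n_switchers": n_switch,
        "pct_switchers": _pct(n_switch, n_eligible),
        "n_multi_switchers": n_multi,
        "pct_multi_switchers": _pct(n_multi, n_eligible),
        "as_of_season": as_of_season,
        "tag_years": [min_tag_year, max_tag_year],
    }
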