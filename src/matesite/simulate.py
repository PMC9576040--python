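"""Synthetic multi-decade mating-site monitoring datasets with ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: males return to the site nearly every year while females skip one
or two seasons between matings (each completed inter-mating interval is
drawn independently as 3 years with probability ``p_triennial``, else 2 —
cycle switching is therefore an emergent property of independent draws);
sex-specific arrival and departure phenology inside the June–July mating
season; within-season visit structure with males making many short visits
and females few long ones; an autumn (gestation) presence peak for females
in mating years with reduced August use when the water is above 30 degC;
diel suppression of afternoon detections above 29.6 degC; acoustic
transmissions every ~240 s (jittered) thinned by a per-transmission
detection probability and cut off at the 3650-day tag life; and per-season
PIT/visual resight draws during the mating-season field window.

Defaults are the conditions of the monitored population (89 females and 48
males tagged over a 30-year study starting 1992); every stage is seeded and
reproducible, and a :class:`GroundTruth` sidecar records the generating
cycle sequences, per-season presence, arrival/departure instants and visit
lists so recovery can be checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as msio

HOURS = pd.Timedelta(hours=1)


@dataclass
class SimConfig:
    """Generator configuration; defaults reproduce the study conditions."""

    n_females: int = 89
    n_males: int = 48
    start_year: int = 1992
    n_years: int = 30
    tag_first_year: int = 1993
    tag_last_year: int = 2014

    # reproductive cycling
    p_triennial: float = 0.32
    p_male_return: float = 0.85

    # phenology (month, day) anchors
    female_arrival_mean: tuple = (6, 24)
    female_arrival_sd_days: float = 5.0
    female_arrival_window: tuple = ((6, 12), (7, 8))
    male_arrival_window: tuple = ((5, 25), (6, 28))
    female_span_median_d: float = 11.43
    female_span_sigma: float = 0.35
    male_span_median_d: float = 27.14
    male_span_sigma: float = 0.25
    female_departure_latest: tuple = (7, 14)   # by the second week of July
    male_departure_latest: tuple = (7, 21)     # by the third week of July

    # within-season visit structure
    male_visits_median: float = 34.0
    female_visits_median: float = 12.5
    visit_count_dispersion: float = 8.0        # negative-binomial size
    male_visit_dur_median_h: float = 1.0
    male_visit_dur_sigma: float = 1.2
    female_visit_dur_median_h: float = 4.4
    female_visit_dur_sigma: float = 1.0
    visit_max_h: float = 48.0
    min_visit_gap_h: float = 1.05              # keeps true visits separable

    # autumn gestation presence (females in mating years)
    p_gestation_autumn: float = 0.8
    autumn_daily_presence: dict = field(
        default_factory=lambda: {8: 0.15, 9: 0.45, 10: 0.40, 11: 0.15}
    )
    heat_avoid_threshold_c: float = 30.0
    heat_avoid_keep: float = 0.4

    # diel suppression
    diel_temp_threshold_c: float = 29.6
    diel_hours: tuple = (15, 17)
    diel_keep: float = 0.5

    # acoustic process
    p_acoustic_tag: float = 0.55
    transmission_delay_s: float = 240.0
    transmission_jitter_s: tuple = (120.0, 360.0)
    detection_prob: float = 0.5
    tag_life_days: int = 3650

    # resighting process
    p_pit_per_season: float = 0.5
    p_visual_per_season: float = 0.5

    # temperature model
    temp_mean_c: float = 26.0
    temp_annual_amp_c: float = 4.3
    temp_annual_peak_doy: float = 218.0        # early August
    temp_diel_amp_c: float = 1.2
    temp_diel_peak_hour: float = 15.5
    temp_noise_sd_c: float = 0.3

    @property
    def end_year(self) -> int:
        return self.start_year + self.n_years - 1

    def validate(self) -> None:
        probs = (
            self.p_triennial, self.p_male_return, self.p_gestation_autumn,
            self.heat_avoid_keep, self.diel_keep, self.p_acoustic_tag,
            self.detection_prob, self.p_pit_per_season, self.p_visual_per_season,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.n_years < 1 or self.n_females < 0 or self.n_males < 0:
            raise ValueError("population sizes and span must be non-negative")


@dataclass
class GroundTruth:
    """Generating truth: cycles, presence, bout bounds, and visit lists."""

    cycles: dict            # female id -> list of intervals (years)
    seasons: dict           # shark id -> sorted list of present mating seasons
    arrivals: dict          # (shark id, year) -> Timestamp
    departures: dict        # (shark id, year) -> Timestamp
    visits: dict            # (shark id, year) -> list of (start, end)
    autumn_days: dict       # female id -> list of present autumn dates

    def n_true_visits(self) -> int:
        return sum(len(v) for v in self.visits.values())


def _date(year: int, md: tuple) -> pd.Timestamp:
    return pd.Timestamp(year=year, month=md[0], day=md[1])


def simulate_temperature(config: SimConfig, seed: int) -> pd.DataFrame:
    """Hourly on-site temperature: annual + diurnal sinusoids + noise.

    The annual component peaks in early August above 30 degC (the observed
    summer maximum) and the diurnal component peaks mid-afternoon.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    index = pd.date_range(
        start=pd.Timestamp(year=config.start_year, month=1, day=1),
        end=pd.Timestamp(year=config.end_year, month=12, day=31, hour=23),
        freq="h",
    )
    doy = index.dayofyear.to_numpy(dtype=float)
    hour = index.hour.to_numpy(dtype=float)
    temp = (
        config.temp_mean_c
        + config.temp_annual_amp_c
        * np.cos(2 * np.pi * (doy - config.temp_annual_peak_doy) / 365.25)
        + config.temp_diel_amp_c
        * np.cos(2 * np.pi * (hour - config.temp_diel_peak_hour) / 24.0)
        + rng.normal(0.0, config.temp_noise_sd_c, size=len(index))
    )
    return pd.DataFrame({"timestamp": index, "temp_c": np.round(temp, 3)})


def simulate_population(
    config: SimConfig, seed: int
) -> tuple[pd.DataFrame, GroundTruth]:
    """Registry plus generating cycle sequences and presence seasons.

    Females: tagged in their first present season; each later present
    season follows the previous after an independently drawn 2- or 3-year
    interval. Males: present in the tag year and in each later year
    independently with a high annual return probability. Tagging years are
    staggered uniformly over the tagging period, and the tagging date is
    the shark's arrival date in its first season.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    rows = []
    cycles: dict = {}
    seasons: dict = {}
    arrivals: dict = {}

    def _female_arrival(year: int) -> pd.Timestamp:
        lo = _date(year, config.female_arrival_window[0])
        hi = _date(year, config.female_arrival_window[1])
        mean = _date(year, config.female_arrival_mean)
        for _ in range(100):
            d = mean + pd.Timedelta(
                days=float(rng.normal(0.0, config.female_arrival_sd_days))
            )
            if lo <= d.normalize() <= hi:
                break
        else:
            d = mean
        return d.normalize() + pd.Timedelta(hours=float(rng.uniform(6, 18)))

    def _male_arrival(year: int) -> pd.Timestamp:
        lo = _date(year, config.male_arrival_window[0])
        hi = _date(year, config.male_arrival_window[1])
        span_d = (hi - lo).days
        d = lo + pd.Timedelta(days=float(rng.uniform(0, span_d + 1)))
        return d.normalize() + pd.Timedelta(hours=float(rng.uniform(6, 18)))

    for sex, count in (("F", config.n_females), ("M", config.n_males)):
        for i in range(count):
            sid = f"{sex}{i + 1:03d}"
            tag_year = int(
                rng.integers(config.tag_first_year, config.tag_last_year + 1)
            )
            if sex == "F":
                present = [tag_year]
                intervals = []
                year = tag_year
                while True:
                    step = 3 if rng.random() < config.p_triennial else 2
                    year += step
                    if year > config.end_year:
                        break
                    intervals.append(step)
                    present.append(year)
                cycles[sid] = intervals
            else:
                present = [tag_year] + [
                    y
                    for y in range(tag_year + 1, config.end_year + 1)
                    if rng.random() < config.p_male_return
                ]
            seasons[sid] = present
            first_arrival = (
                _female_arrival(tag_year) if sex == "F" else _male_arrival(tag_year)
            )
            arrivals[(sid, tag_year)] = first_arrival
            has_acoustic = rng.random() < config.p_acoustic_tag
            tags = "PIT+roto" + ("+acoustic" if has_acoustic else "")
            rows.append(
                (
                    sid,
                    sex,
                    first_arrival.normalize(),
                    msio.normalize_tag_types(tags),
                    round(float(rng.normal(250 if sex == "F" else 242, 10)), 1),
                )
            )
            # draw remaining arrivals now so phenology is a population property
            for year in present[1:]:
                arrivals[(sid, year)] = (
                    _female_arrival(year) if sex == "F" else _male_arrival(year)
                )
    registry = pd.DataFrame(
        rows,
        columns=["shark_id", "sex", "tagging_date", "tag_types", "total_length_cm"],
    )
    truth = GroundTruth(
        cycles=cycles, seasons=seasons, arrivals=arrivals,
        departures={}, visits={}, autumn_days={},
    )
    return registry, truth


def _place_visits(rng, arrival, departure, n_target, dur_median_h, dur_sigma,
                  max_h, min_gap_h):
    """Lay non-overlapping visits (gap >= min_gap_h) inside a presence bout.

    ``dur_median_h`` is the target median of the per-season *mean* visit
    duration (the reported residency metric), so individual visit durations
    are lognormal with median ``dur_median_h / exp(sigma^2 / 2)``. Idle time
    is split by uniform spacings, so the drawn visit count is realized
    exactly whenever the bout is long enough to hold it.
    """
    span_h = (departure - arrival) / HOURS
    mu = np.log(dur_median_h) - dur_sigma**2 / 2.0
    durs = np.minimum(rng.lognormal(mu, dur_sigma, size=n_target), max_h)
    # shed visits (shortest last) until they fit in the bout with min gaps
    n = n_target
    while n > 1 and durs[:n].sum() + (n - 1) * min_gap_h > span_h:
        n -= 1
    durs = np.minimum(durs[:n], span_h)
    free = max(span_h - durs.sum() - (n - 1) * min_gap_h, 0.0)
    spacings = np.diff(np.sort(np.concatenate([[0.0], rng.random(n), [1.0]])))
    visits = []
    t = arrival + pd.Timedelta(hours=float(spacings[0] * free))
    for k in range(n):
        if k > 0:
            t = t + pd.Timedelta(hours=min_gap_h + float(spacings[k] * free))
        end = min(t + pd.Timedelta(hours=float(durs[k])), departure)
        visits.append((t, end))
        t = end
    return visits


def _emit_transmissions(rng, visits, config):
    """Transmission instants within visits: jittered ~240 s coded pings."""
    lo, hi = config.transmission_jitter_s
    chunks = []
    for start, end in visits:
        dur_s = (end - start).total_seconds()
        n_max = int(dur_s / lo) + 2
        gaps = rng.uniform(lo, hi, size=n_max)
        offsets = np.cumsum(gaps) - gaps[0] * rng.random()
        offsets = offsets[offsets <= dur_s]
        if len(offsets) == 0:
            offsets = np.zeros(1)
        chunks.append(
            start.to_datetime64() + (offsets * 1e9).astype("timedelta64[ns]")
        )
    return np.concatenate(chunks) if chunks else np.array([], dtype="datetime64[ns]")


def simulate_detections(
    registry: pd.DataFrame,
    truth: GroundTruth,
    temperature: pd.DataFrame | None,
    config: SimConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Emit acoustic detections and sightings; fill in ground-truth bouts.

    For every present shark-season: departure is the arrival plus a
    sex-specific lognormal span (clipped to the sex's latest-departure
    rule); visits are placed per the sex's count/duration distributions;
    transmissions fire every ~240 s inside visits, are thinned by the
    per-transmission detection probability and by afternoon heat
    suppression, and stop at tag expiry. Each present mating season also
    draws PIT/visual sightings, plus the capture sighting at tagging.
    Gestating females receive autumn presence days with the August heat
    rule applied. When ``detection_prob`` is 0 the transmission process is
    skipped entirely (survey-only monitoring).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    temp_lookup = None
    if temperature is not None and len(temperature):
        tser = temperature.set_index("timestamp")["temp_c"]
        temp_index = tser.index.values
        temp_values = tser.to_numpy()

        def temp_lookup(ts_array):
            pos = np.clip(
                np.searchsorted(temp_index, ts_array, side="right") - 1,
                0, len(temp_values) - 1,
            )
            return temp_values[pos]

    det_ids: list[str] = []
    det_chunks: list[np.ndarray] = []
    sight_rows: list[tuple] = []
    reg = registry.set_index("shark_id")

    for sid, present in truth.seasons.items():
        sex = reg.loc[sid, "sex"]
        tagging_date = reg.loc[sid, "tagging_date"]
        has_acoustic = "acoustic" in msio.tag_type_set(reg.loc[sid, "tag_types"])
        tag_expiry = tagging_date + pd.Timedelta(days=config.tag_life_days)
        if sex == "F":
            span_med, span_sig = config.female_span_median_d, config.female_span_sigma
            latest = config.female_departure_latest
            n_med, dmed, dsig = (
                config.female_visits_median,
                config.female_visit_dur_median_h,
                config.female_visit_dur_sigma,
            )
        else:
            span_med, span_sig = config.male_span_median_d, config.male_span_sigma
            latest = config.male_departure_latest
            n_med, dmed, dsig = (
                config.male_visits_median,
                config.male_visit_dur_median_h,
                config.male_visit_dur_sigma,
            )
        for year in present:
            arrival = truth.arrivals[(sid, year)]
            span = float(rng.lognormal(np.log(span_med), span_sig))
            departure = min(
                arrival + pd.Timedelta(days=span),
                _date(year, latest) + pd.Timedelta(hours=23),
            )
            if departure <= arrival:
                departure = arrival + pd.Timedelta(hours=12)
            truth.departures[(sid, year)] = departure
            n_visits = max(
                1,
                int(
                    rng.negative_binomial(
                        config.visit_count_dispersion,
                        config.visit_count_dispersion
                        / (config.visit_count_dispersion + n_med),
                    )
                ),
            )
            visits = _place_visits(
                rng, arrival, departure, n_visits, dmed, dsig,
                config.visit_max_h, config.min_visit_gap_h,
            )
            truth.visits[(sid, year)] = visits

            # survey resights within the bout (mating-season field window)
            first_day = arrival.normalize()
            n_days = max((departure.normalize() - first_day).days, 0)
            for method, prob in (
                ("PIT_scan", config.p_pit_per_season),
                ("visual", config.p_visual_per_season),
            ):
                if rng.random() < prob:
                    d = first_day + pd.Timedelta(
                        days=int(rng.integers(0, n_days + 1))
                    )
                    sight_rows.append((sid, d, method))

            if has_acoustic and config.detection_prob > 0:
                times = _emit_transmissions(rng, visits, config)
                kept = _thin(rng, times, config, temp_lookup, tag_expiry)
                det_ids.append(sid)
                det_chunks.append(kept)

        # capture sighting at tagging
        sight_rows.append((sid, tagging_date, "capture"))

        # gestation autumn presence
        if sex == "F":
            autumn = []
            for year in present:
                if rng.random() >= config.p_gestation_autumn:
                    continue
                for month, p_day in sorted(config.autumn_daily_presence.items()):
                    days = pd.date_range(
                        _date(year, (month, 1)),
                        _date(year, (month, 1)) + pd.offsets.MonthEnd(0),
                        freq="D",
                    )
                    for day in days:
                        if rng.random() >= p_day:
                            continue
                        if temp_lookup is not None:
                            noon = day + pd.Timedelta(hours=14)
                            if (
                                temp_lookup(np.array([noon.to_datetime64()]))[0]
                                > config.heat_avoid_threshold_c
                                and rng.random() >= config.heat_avoid_keep
                            ):
                                continue
                        autumn.append(day)
                        start = day + pd.Timedelta(
                            hours=float(rng.uniform(0, 21))
                        )
                        end = start + pd.Timedelta(
                            hours=float(
                                np.minimum(rng.lognormal(np.log(2.0), 0.8), 20.0)
                            )
                        )
                        key = (sid, year)
                        truth.visits.setdefault(key, []).append((start, end))
                        if has_acoustic and config.detection_prob > 0:
                            times = _emit_transmissions(rng, [(start, end)], config)
                            kept = _thin(
                                rng, times, config, temp_lookup, tag_expiry
                            )
                            det_ids.append(sid)
                            det_chunks.append(kept)
            truth.autumn_days[sid] = autumn

    if det_chunks:
        detections = pd.DataFrame(
            {
                "shark_id": np.repeat(
                    det_ids, [len(c) for c in det_chunks]
                ),
                "timestamp": np.concatenate(det_chunks),
            }
        )
    else:
        detections = pd.DataFrame(
            {
                "shark_id": pd.Series(dtype=str),
                "timestamp": pd.Series(dtype="datetime64[ns]"),
            }
        )
    detections["station"] = msio.LOGICAL_STATION
    detections = detections.sort_values(
        ["shark_id", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    sightings = pd.DataFrame(sight_rows, columns=["shark_id", "date", "method"])
    sightings = sightings.sort_values(
        ["shark_id", "date"], kind="mergesort"
    ).reset_index(drop=True)
    return detections, sightings, truth


def _thin(rng, times, config, temp_lookup, tag_expiry):
    """Detection filter: per-transmission probability, heat/diel rule, tag life."""
    if len(times) == 0:
        return times
    ts = np.asarray(times, dtype="datetime64[ns]")
    keep = rng.random(len(ts)) < config.detection_prob
    keep &= ts <= tag_expiry.to_datetime64()
    if temp_lookup is not None:
        lo, hi = config.diel_hours
        hour = (ts.astype("datetime64[h]").astype(np.int64)) % 24
        afternoon = (hour >= lo) & (hour <= hi)
        hot = temp_lookup(ts) > config.diel_temp_threshold_c
        suppressed = afternoon & hot & (rng.random(len(ts)) >= config.diel_keep)
        keep &= ~suppressed
    return ts[keep].astype("datetime64[s]").astype("datetime64[ns]")


def simulate(config: SimConfig, seed: int):
    """Run the full generator: temperature, population, detection process."""
    root = np.random.default_rng(seed)
    s_temp, s_pop, s_det = (int(x) for x in root.integers(0, 2**31 - 1, size=3))
    temperature = simulate_temperature(config, s_temp)
    registry, truth = simulate_population(config, s_pop)
    detections, sightings, truth = simulate_detections(
        registry, truth, temperature, config, s_det
    )
    return registry, detections, sightings, temperature, truth


def write_dataset(
    directory,
    registry: pd.DataFrame,
    detections: pd.DataFrame,
    sightings: pd.DataFrame,
    temperature: pd.DataFrame,
    truth: GroundTruth,
) -> None:
    """Emit the four loader-compatible CSVs plus a ground-truth YAML sidecar."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    msio.write_table(registry, directory / "registry.csv")
    msio.write_table(detections, directory / "detections.csv")
    msio.write_table(sightings, directory / "sightings.csv")
    msio.write_table(temperature, directory / "temperature.csv")
    gt = {
        "cycles": {k: list(map(int, v)) for k, v in truth.cycles.items()},
        "seasons": {k: list(map(int, v)) for k, v in truth.seasons.items()},
        "arrivals": {
            f"{sid}:{year}": str(ts) for (sid, year), ts in truth.arrivals.items()
        },
        "departures": {
            f"{sid}:{year}": str(ts) for (sid, year), ts in truth.departures.items()
        },
        "n_true_visits": truth.n_true_visits(),
        "visits": {
            f"{sid}:{year}": [[str(a), str(b)] for a, b in vs]
            for (sid, year), vs in truth.visits.items()
        },
        "autumn_days": {
            k: [str(d.date()) for d in v] for k, v in truth.autumn_days.items()
        },
    }
    with open(directory / "ground_truth.yaml", "w") as fh:
        yaml.safe_dump(gt, fh, sort_keys=True)
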