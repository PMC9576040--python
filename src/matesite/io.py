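"""Readers and writers for the tabular inputs and outputs of the pipeline.

All tables are comma-delimited text with a header row. Timestamps are
ISO-8601 in local standard time (the site does not observe daylight saving;
diel analyses are only meaningful on a local clock). Column names are fixed:

=============  =====================================================
table          columns
=============  =====================================================
detections     shark_id, timestamp, station
registry       shark_id, sex, tagging_date, tag_types
               [, total_length_cm, acoustic_tag_end]
sightings      shark_id, date, method
temperature    timestamp, temp_c
=============  =====================================================

``tag_types`` is a ``+``-joined subset of ``{PIT, roto, acoustic}``.
All on-site receivers are collapsed to one logical station at load time;
the array is operated for detection redundancy, not spatial resolution.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("matesite")

#: Name of the single logical receiver station after collapsing.
LOGICAL_STATION = "DTCMG"

#: Maximum operating life of an acoustic transmitter, days.
TAG_LIFE_DAYS = 3650

#: Study window sanity bounds for detection timestamps.
STUDY_WINDOW = (pd.Timestamp("1990-01-01"), pd.Timestamp("2030-12-31 23:59:59"))

VALID_SEXES = frozenset({"F", "M"})
VALID_TAG_TYPES = frozenset({"PIT", "roto", "acoustic"})
VALID_METHODS = frozenset({"capture", "PIT_scan", "visual", "acoustic"})

TEMP_RANGE_C = (10.0, 40.0)


class TableFormatError(ValueError):
    """A delimited input file violates the documented schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")


def _parse_timestamps(series: pd.Series, path, column: str = "timestamp") -> pd.Series:
    parsed = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = parsed.isna() & series.notna()
    if bad.any():
        # +2: one for the header row, one for 0-based indexing
        row = int(bad.idxmax()) + 2
        raise TableFormatError(
            f"{path}: row {row}: unparseable {column} {series[bad.idxmax()]!r}"
        )
    if parsed.isna().any():
        row = int(parsed.isna().idxmax()) + 2
        raise TableFormatError(f"{path}: row {row}: missing {column}")
    return parsed


def normalize_tag_types(value: str) -> str:
    """Canonicalize a ``+``-joined tag-type set (sorted, validated)."""
    parts = {p.strip() for p in str(value).split("+") if p.strip()}
    bad = parts - VALID_TAG_TYPES
    if bad:
        raise TableFormatError(f"unknown tag type(s) {sorted(bad)}")
    return "+".join(sorted(parts))


def tag_type_set(value: str) -> frozenset[str]:
    return frozenset(p for p in str(value).split("+") if p)


def load_registry(path) -> pd.DataFrame:
    """Load the tag/shark registry.

    One row per shark. Raises on duplicate IDs, sexes outside {F, M}, or
    missing tagging dates. ``acoustic_tag_end`` is derived as
    ``tagging_date + 3650 d`` for acoustically tagged sharks when absent.
    """
    df = pd.read_csv(path, dtype=str, float_precision="round_trip")
    _require_columns(df, ["shark_id", "sex", "tagging_date", "tag_types"], path)
    if df.empty:
        return df.assign(
            tagging_date=pd.Series(dtype="datetime64[ns]"),
            total_length_cm=pd.Series(dtype=float),
            acoustic_tag_end=pd.Series(dtype="datetime64[ns]"),
        )
    dup = df["shark_id"].duplicated()
    if dup.any():
        raise TableFormatError(
            f"{path}: duplicate shark_id {df.loc[dup.idxmax(), 'shark_id']!r}"
        )
    bad_sex = ~df["sex"].isin(VALID_SEXES)
    if bad_sex.any():
        row = int(bad_sex.idxmax()) + 2
        raise TableFormatError(
            f"{path}: row {row}: sex {df.loc[bad_sex.idxmax(), 'sex']!r} not in F/M"
        )
    df["tagging_date"] = _parse_timestamps(df["tagging_date"], path, "tagging_date")
    df["tag_types"] = df["tag_types"].map(normalize_tag_types)
    if "total_length_cm" in df.columns:
        df["total_length_cm"] = pd.to_numeric(df["total_length_cm"], errors="raise")
        if (df["total_length_cm"].dropna() <= 0).any():
            raise TableFormatError(f"{path}: non-positive total_length_cm")
    else:
        df["total_length_cm"] = np.nan
    has_acoustic = df["tag_types"].str.contains("acoustic")
    if "acoustic_tag_end" in df.columns:
        df["acoustic_tag_end"] = pd.to_datetime(df["acoustic_tag_end"], errors="coerce")
    else:
        df["acoustic_tag_end"] = pd.NaT
    derive = has_acoustic & df["acoustic_tag_end"].isna()
    df.loc[derive, "acoustic_tag_end"] = df.loc[derive, "tagging_date"] + pd.Timedelta(
        days=TAG_LIFE_DAYS
    )
    return df.reset_index(drop=True)


def load_detections(
    path,
    registry: pd.DataFrame | None = None,
    collapse_stations: bool = True,
    deduplicate: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load an acoustic detection table.

    Returns ``(detections, orphans)``: rows whose ``shark_id`` is absent from
    the registry are split off into the orphan frame rather than silently
    dropped (conservation: input rows = detections + orphans + logged
    duplicates). Both frames are sorted ascending by (shark_id, timestamp).
    """
    df = pd.read_csv(path, dtype={"shark_id": str, "station": str})
    _require_columns(df, ["shark_id", "timestamp", "station"], path)
    if df.empty:
        df["timestamp"] = pd.Series(dtype="datetime64[ns]")
        return df, df.copy()
    if (df["shark_id"].isna() | (df["shark_id"].str.strip() == "")).any():
        bad = (df["shark_id"].isna() | (df["shark_id"].str.strip() == "")).idxmax()
        raise TableFormatError(f"{path}: row {int(bad) + 2}: empty shark_id")
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    out = (df["timestamp"] < STUDY_WINDOW[0]) | (df["timestamp"] > STUDY_WINDOW[1])
    if out.any():
        row = int(out.idxmax()) + 2
        raise TableFormatError(
            f"{path}: row {row}: timestamp {df.loc[out.idxmax(), 'timestamp']} "
            f"outside study window {STUDY_WINDOW[0].date()}..{STUDY_WINDOW[1].date()}"
        )
    if deduplicate:
        n0 = len(df)
        df = df.drop_duplicates()
        if len(df) < n0:
            logger.info("load_detections: dropped %d duplicate rows", n0 - len(df))
    if collapse_stations:
        df = df.assign(station=LOGICAL_STATION)
    df = df.sort_values(["shark_id", "timestamp"], kind="mergesort").reset_index(
        drop=True
    )
    if registry is None:
        return df, df.iloc[0:0].copy()
    known = df["shark_id"].isin(set(registry["shark_id"]))
    orphans = df[~known].reset_index(drop=True)
    if len(orphans):
        logger.warning(
            "load_detections: %d detections from %d unregistered transmitter(s)",
            len(orphans),
            orphans["shark_id"].nunique(),
        )
    return df[known].reset_index(drop=True), orphans


def load_sightings(path, registry: pd.DataFrame | None = None) -> pd.DataFrame:
    """Load the multi-method sighting table (capture / PIT_scan / visual)."""
    df = pd.read_csv(path, dtype={"shark_id": str, "method": str})
    _require_columns(df, ["shark_id", "date", "method"], path)
    if df.empty:
        df["date"] = pd.Series(dtype="datetime64[ns]")
        return df
    bad = ~df["method"].isin(VALID_METHODS)
    if bad.any():
        row = int(bad.idxmax()) + 2
        raise TableFormatError(
            f"{path}: row {row}: unknown method {df.loc[bad.idxmax(), 'method']!r}"
        )
    df["date"] = _parse_timestamps(df["date"], path, "date")
    if registry is not None:
        tagged = registry.set_index("shark_id")["tagging_date"]
        merged = df["shark_id"].map(tagged)
        early = df["date"].dt.normalize() < merged.dt.normalize()
        if early.any():
            row = int(early.idxmax()) + 2
            raise TableFormatError(
                f"{path}: row {row}: sighting predates tagging date"
            )
    return df.sort_values(["shark_id", "date"], kind="mergesort").reset_index(drop=True)


def load_temperature(path) -> pd.DataFrame:
    """Load the on-site water-temperature series.

    Non-numeric temperatures are a hard error; values outside the plausible
    10-40 degC band are kept but flagged (``out_of_range``) with a warning.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["timestamp", "temp_c"], path)
    if df.empty:
        df["timestamp"] = pd.Series(dtype="datetime64[ns]")
        df["temp_c"] = pd.Series(dtype=float)
        df["out_of_range"] = pd.Series(dtype=bool)
        return df
    df["timestamp"] = _parse_timestamps(df["timestamp"], path)
    try:
        df["temp_c"] = pd.to_numeric(df["temp_c"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise TableFormatError(f"{path}: non-numeric temperature: {exc}") from exc
    df["out_of_range"] = (df["temp_c"] < TEMP_RANGE_C[0]) | (
        df["temp_c"] > TEMP_RANGE_C[1]
    )
    if df["out_of_range"].any():
        logger.warning(
            "load_temperature: %d reading(s) outside %s degC",
            int(df["out_of_range"].sum()),
            TEMP_RANGE_C,
        )
    return df.sort_values("timestamp", kind="mergesort").reset_index(drop=True)


def write_table(df: pd.DataFrame, path) -> None:
    """Write any pipeline frame as CSV that the matching loader round-trips.

    Datetime columns are serialized as ISO-8601; floats use shortest
    round-trip representation (pandas default), so numeric columns re-read
    bit-identically.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            s = out[col]
            if (s.dropna() == s.dropna().dt.normalize()).all():
                out[col] = s.dt.strftime("%Y-%m-%d")
            else:
                out[col] = s.dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
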