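"""Reading, validating and filtering raw badge logs.

The raw detection log is delimited text with columns receiver_id, sender_id,
rssi_dbm (integer), timestamp_unix_s (integer); the battery log has badge_id,
timestamp_unix_s, level_pct.  Cleaning applies, in order: exact-duplicate
removal, weekend removal, out-of-hours removal (outside [08:00, 20:00) local
time), and an RSSI proximity threshold (strictly below -75 dBm removed; -75
itself is kept).  Each removed record is attributed to the first rule that
removes it, so the per-rule counts partition the input.

Badge active time on a day is the sum of consecutive same-badge battery-ping
intervals, capped at ``max_gap`` (default 450 s = 1.5 battery periods) so that
long off-body gaps do not count as wear time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wardsense.errors import FormatError

DETECTION_COLUMNS = ["receiver_id", "sender_id", "rssi_dbm", "timestamp_unix_s"]
BATTERY_COLUMNS = ["badge_id", "timestamp_unix_s", "level_pct"]

DEFAULT_RSSI_MIN = -75
DEFAULT_BATTERY_MAX_GAP = 450.0


@dataclass(frozen=True)
class FilterConfig:
    """Record-level cleaning rules.

    rssi_min is the proximity threshold: records with rssi strictly below it
    are discarded (the threshold value itself survives).  Day boundaries are
    half-open [day_start, day_end) in the configured time zone.
    """

    rssi_min: int = DEFAULT_RSSI_MIN
    day_start: str = "08:00"
    day_end: str = "20:00"
    exclude_weekends: bool = True
    tz: str = "UTC"

    def __post_init__(self) -> None:
        if self._minutes(self.day_start) >= self._minutes(self.day_end):
            raise ValueError(f"day_start ({self.day_start}) must be before day_end ({self.day_end})")

    @staticmethod
    def _minutes(clock: str) -> int:
        h, m = clock.split(":")
        return int(h) * 60 + int(m)


@dataclass
class FilterCounts:
    """Per-rule removal tally; input = output + sum of removals."""

    duplicate: int = 0
    weekend: int = 0
    out_of_hours: int = 0
    rssi: int = 0

    def total(self) -> int:
        return self.duplicate + self.weekend + self.out_of_hours + self.rssi


def _read_log(path, columns: list[str], int_columns: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    raw = pd.read_csv(path, dtype=str, sep=",", skipinitialspace=True)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    raw = raw[columns]
    bad = pd.Series(False, index=raw.index)
    parsed = {}
    for c in columns:
        if c in int_columns:
            v = pd.to_numeric(raw[c], errors="coerce")
            bad |= v.isna() | (v != np.floor(v.fillna(0)))
            parsed[c] = v
        else:
            bad |= raw[c].isna() | (raw[c].str.strip() == "")
            parsed[c] = raw[c].astype(str).str.strip() if raw[c].notna().all() else raw[c]
    df = pd.DataFrame(parsed)
    rejects = raw[bad].copy()
    df = df[~bad].copy()
    for c in int_columns:
        df[c] = df[c].astype(np.int64)
    return df.reset_index(drop=True), rejects.reset_index(drop=True)


def read_detection_log(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a detection log; returns (records, rejects).

    Malformed lines (non-integer rssi or timestamp, blank ids) are collected
    into the rejects frame rather than silently dropped.
    """
    return _read_log(path, DETECTION_COLUMNS, ["rssi_dbm", "timestamp_unix_s"])


def read_battery_log(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Parse a battery log; returns (records, rejects)."""
    df, rejects = _read_log(path, BATTERY_COLUMNS, ["timestamp_unix_s", "level_pct"])
    out_of_range = (df["level_pct"] < 0) | (df["level_pct"] > 100)
    if out_of_range.any():
        rejects = pd.concat([rejects, df[out_of_range].astype(str)], ignore_index=True)
        df = df[~out_of_range].reset_index(drop=True)
    return df, rejects


def check_roster_ids(records: pd.DataFrame, roster: pd.DataFrame) -> list[str]:
    """Ids appearing in the records but not in the roster (warning list)."""
    known = set(roster["participant"])
    seen = set()
    for col in ("receiver_id", "sender_id", "badge_id"):
        if col in records.columns:
            seen |= set(records[col].unique())
    return sorted(seen - known)


def filter_records(
    records: pd.DataFrame, config: FilterConfig | None = None
) -> tuple[pd.DataFrame, FilterCounts]:
    """Apply the cleaning rules to parsed detection records.

    Rules are applied in the order duplicate -> weekend -> out-of-hours ->
    RSSI, and each removal is attributed to the first rule that fires, so the
    counts partition the input.  Record order is preserved.  Filtering is
    idempotent.
    """
    config = config or FilterConfig()
    counts = FilterCounts()
    if records.empty:
        return records.copy(), counts

    dup = records.duplicated(subset=DETECTION_COLUMNS, keep="first")
    counts.duplicate = int(dup.sum())

    local = (
        pd.to_datetime(records["timestamp_unix_s"], unit="s", utc=True)
        .dt.tz_convert(config.tz)
    )
    weekend = (local.dt.dayofweek >= 5) & ~dup if config.exclude_weekends else pd.Series(False, index=records.index)
    counts.weekend = int(weekend.sum())

    minutes = local.dt.hour * 60 + local.dt.minute
    lo, hi = FilterConfig._minutes(config.day_start), FilterConfig._minutes(config.day_end)
    hours = ((minutes < lo) | (minutes >= hi)) & ~dup & ~weekend
    counts.out_of_hours = int(hours.sum())

    weak = (records["rssi_dbm"] < config.rssi_min) & ~dup & ~weekend & ~hours
    counts.rssi = int(weak.sum())

    keep = ~(dup | weekend | hours | weak)
    return records[keep].reset_index(drop=True), counts


def active_time(
    battery: pd.DataFrame,
    badge: str,
    day: str,
    max_gap: float = DEFAULT_BATTERY_MAX_GAP,
    tz: str = "UTC",
) -> float:
    """Seconds a badge was active on one day: summed battery-ping intervals.

    Consecutive same-badge timestamps on the given local calendar day
    contribute their difference when it is at most ``max_gap``; fewer than two
    records give 0.
    """
    b = battery[battery["badge_id"] == badge]
    if b.empty:
        return 0.0
    local_day = (
        pd.to_datetime(b["timestamp_unix_s"], unit="s", utc=True)
        .dt.tz_convert(tz)
        .dt.strftime("%Y-%m-%d")
    )
    t = np.sort(b.loc[local_day == day, "timestamp_unix_s"].to_numpy())
    if t.size < 2:
        return 0.0
    gaps = np.diff(t).astype(float)
    return float(gaps[gaps <= max_gap].sum())


def active_time_table(
    battery: pd.DataFrame, max_gap: float = DEFAULT_BATTERY_MAX_GAP, tz: str = "UTC"
) -> pd.DataFrame:
    """Active seconds for every (badge, local day) with battery data."""
    if battery.empty:
        return pd.DataFrame(columns=["participant", "day", "active_s"])
    b = battery.sort_values(["badge_id", "timestamp_unix_s"], kind="stable")
    day = (
        pd.to_datetime(b["timestamp_unix_s"], unit="s", utc=True)
        .dt.tz_convert(tz)
        .dt.strftime("%Y-%m-%d")
    )
    g = pd.DataFrame(
        {"participant": b["badge_id"].to_numpy(), "day": day.to_numpy(), "t": b["timestamp_unix_s"].to_numpy()}
    )
    gaps = g.groupby(["participant", "day"], sort=True)["t"].diff()
    g["gap"] = gaps.where(gaps <= max_gap, 0.0).fillna(0.0)
    out = g.groupby(["participant", "day"], sort=True, as_index=False)["gap"].sum()
    return out.rename(columns={"gap": "active_s"})
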