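"""Reconstructing dyadic interaction events from directional detections.

A detection of badge X by badge Y at time t means X was within conversational
range of Y for at least the beacon period, so it contributes the interval
[t, t + beacon_period] to the directional stream Y<-X.  Gaps of up to 75 s
between contributions are bridged (sensing dropout, not a broken contact).
An interaction event between X and Y is, by default, the intersection of the
two directional streams — the period during which *both* badges detected each
other — re-bridged with the same gap rule; a union mode is available for
asymmetric packet loss.

Daily summaries per participant: relative interaction time (union of the
person's event intervals divided by badge active time), mean common log of
event durations in minutes, totals split by partner role, and event counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wardsense.errors import ConfigError

DEFAULT_GAP_MAX = 75.0


@dataclass(frozen=True)
class ReconstructionConfig:
    """Event-reconstruction parameters.

    gap_max: largest sensing gap (seconds) bridged as a continuing contact;
        the bound is inclusive ("gaps of up to 75 s").
    mode: 'intersection' requires mutual detection; 'union' accepts either
        direction.
    """

    gap_max: float = DEFAULT_GAP_MAX
    beacon_period: float = 4.0
    mode: str = "intersection"

    def __post_init__(self) -> None:
        if self.gap_max < self.beacon_period:
            raise ConfigError(
                f"gap_max ({self.gap_max}) must be >= beacon_period ({self.beacon_period})"
            )
        if self.mode not in ("intersection", "union"):
            raise ConfigError(f"mode must be 'intersection' or 'union', got {self.mode!r}")


# ---------------------------------------------------------------------------
# interval algebra (half-open semantics are not needed; endpoints carry
# positive measure from the beacon-period extension)


def merge_intervals(intervals: np.ndarray, gap_max: float = 0.0) -> np.ndarray:
    """Merge a (n, 2) array of intervals, bridging gaps <= gap_max (inclusive).

    Returns a sorted, disjoint (m, 2) array.
    """
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if iv.shape[0] == 0:
        return iv
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s - out[-1][1] <= gap_max:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


def intersect_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise intersection of two disjoint sorted interval lists."""
    a = np.asarray(a, dtype=float).reshape(-1, 2)
    b = np.asarray(b, dtype=float).reshape(-1, 2)
    out = []
    i = j = 0
    while i < a.shape[0] and j < b.shape[0]:
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if e > s:
            out.append((s, e))
        if a[i, 1] < b[j, 1]:
            i += 1
        else:
            j += 1
    return np.array(out).reshape(-1, 2)


def union_intervals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Union of two interval lists (touching intervals merge)."""
    both = np.vstack([np.asarray(a, dtype=float).reshape(-1, 2), np.asarray(b, dtype=float).reshape(-1, 2)])
    return merge_intervals(both, gap_max=0.0)


def total_length(intervals: np.ndarray) -> float:
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    return float((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0.0


def directional_intervals(
    records: pd.DataFrame, receiver: str, sender: str, config: ReconstructionConfig | None = None
) -> np.ndarray:
    """Detection intervals of `sender` as seen by `receiver`.

    Each detection at t contributes [t, t + beacon_period]; contributions
    whose gap (next start minus previous end) is <= gap_max are merged.
    """
    config = config or ReconstructionConfig()
    t = records.loc[
        (records["receiver_id"] == receiver) & (records["sender_id"] == sender), "timestamp_unix_s"
    ].to_numpy(dtype=float)
    if t.size == 0:
        return np.empty((0, 2))
    t = np.sort(t)
    iv = np.column_stack([t, t + config.beacon_period])
    return merge_intervals(iv, gap_max=config.gap_max)


def _ticks_to_intervals(t: np.ndarray, config: ReconstructionConfig) -> np.ndarray:
    t = np.sort(np.asarray(t, dtype=float))
    if t.size == 0:
        return np.empty((0, 2))
    return merge_intervals(np.column_stack([t, t + config.beacon_period]), gap_max=config.gap_max)


def reconstruct_interactions(
    records: pd.DataFrame, config: ReconstructionConfig | None = None, tz: str = "UTC"
) -> pd.DataFrame:
    """Reconstruct interaction events from filtered detection records.

    Groups records by local calendar day and unordered badge pair; in
    intersection mode an event interval is the overlap of the two directional
    streams (then re-bridged with gap_max), in union mode their union.
    Returns a frame with columns day, a, b, start, end, duration_s
    (a < b canonically), sorted by (day, a, b, start).
    """
    config = config or ReconstructionConfig()
    cols = ["day", "a", "b", "start", "end", "duration_s"]
    if records.empty:
        return pd.DataFrame(columns=cols)

    r = records.copy()
    r["day"] = (
        pd.to_datetime(r["timestamp_unix_s"], unit="s", utc=True)
        .dt.tz_convert(tz)
        .dt.strftime("%Y-%m-%d")
    )
    a = np.minimum(r["receiver_id"], r["sender_id"])
    b = np.maximum(r["receiver_id"], r["sender_id"])
    r["a"], r["b"] = a, b
    r["forward"] = r["receiver_id"] == r["a"]  # direction a<-b

    rows = []
    for (day, pa, pb), grp in r.groupby(["day", "a", "b"], sort=True):
        fwd = _ticks_to_intervals(grp.loc[grp["forward"], "timestamp_unix_s"].to_numpy(), config)
        rev = _ticks_to_intervals(grp.loc[~grp["forward"], "timestamp_unix_s"].to_numpy(), config)
        if config.mode == "intersection":
            iv = intersect_intervals(fwd, rev)
            iv = merge_intervals(iv, gap_max=config.gap_max) if iv.size else iv
        else:
            iv = union_intervals(fwd, rev)
        for s, e in iv:
            if e > s:
                rows.append((day, pa, pb, s, e, e - s))
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["day", "a", "b", "start"], kind="stable", ignore_index=True)


def daily_summary(
    events: pd.DataFrame,
    active: pd.DataFrame,
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Per participant-day interaction summaries.

    ``events`` as returned by :func:`reconstruct_interactions`; ``active`` as
    from :func:`wardsense.ingest.active_time_table`; ``roster`` maps
    participants to roles.  For each (participant, day) with badge activity:

    * total_interaction_s: length of the union of that person's event
      intervals (simultaneous partners count once);
    * with_staff_s / with_patient_s: union restricted to events whose partner
      has that role (splits may exceed the overall total);
    * n_interactions / mean_log_duration: event count and mean log10 of event
      durations in minutes (every event counts, even when overlapping);
    * relative_interaction_time: total_interaction_s / active_s, missing when
      active_s is 0.

    Participant-days with events but zero active time are kept and flagged
    (``inconsistent`` = True) rather than dropped.
    """
    role_of = dict(zip(roster["participant"], roster["role"]))
    ev_by_pd: dict[tuple[str, str], list[tuple[float, float, str]]] = {}
    if not events.empty:
        for row in events.itertuples(index=False):
            ev_by_pd.setdefault((row.a, row.day), []).append((row.start, row.end, role_of.get(row.b, "unknown")))
            ev_by_pd.setdefault((row.b, row.day), []).append((row.start, row.end, role_of.get(row.a, "unknown")))

    keys = set(ev_by_pd)
    active_map: dict[tuple[str, str], float] = {}
    if not active.empty:
        for row in active.itertuples(index=False):
            active_map[(row.participant, row.day)] = float(row.active_s)
            keys.add((row.participant, row.day))

    rows = []
    for participant, day in sorted(keys):
        evs = ev_by_pd.get((participant, day), [])
        act = active_map.get((participant, day), 0.0)
        iv = np.array([(s, e) for s, e, _ in evs]).reshape(-1, 2)
        total = total_length(merge_intervals(iv)) if iv.size else 0.0
        by_role = {}
        for role in ("staff", "patient"):
            sub = np.array([(s, e) for s, e, r in evs if r == role]).reshape(-1, 2)
            by_role[role] = total_length(merge_intervals(sub)) if sub.size else 0.0
        durations_min = np.array([(e - s) / 60.0 for s, e, _ in evs])
        mld = float(np.mean(np.log10(durations_min))) if durations_min.size else np.nan
        rel = total / act if act > 0 else np.nan  # undefined without active time
        rows.append(
            {
                "participant": participant,
                "day": day,
                "role": role_of.get(participant, "unknown"),
                "active_s": act,
                "total_interaction_s": total,
                "with_staff_s": by_role["staff"],
                "with_patient_s": by_role["patient"],
                "n_interactions": len(evs),
                "mean_log_duration": mld,
                "relative_interaction_time": rel,
                "inconsistent": bool(evs) and act == 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "day",
            "role",
            "active_s",
            "total_interaction_s",
            "with_staff_s",
            "with_patient_s",
            "n_interactions",
            "mean_log_duration",
            "relative_interaction_time",
            "inconsistent",
        ],
    )
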