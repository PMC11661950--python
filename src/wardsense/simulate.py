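"""Synthetic ward: ground-truth contact schedules, noisy badge logs, assessments.

The simulator emulates a small open psychiatric ward (7 patients, 18 staff by
default) whose residents wear proximity badges on weekdays between 08:00 and
20:00.  Badges advertise every 4 s; a receiving badge logs (sender, RSSI,
Unix timestamp), and every 5 min it logs its battery level.  Social structure
is generated in two layers:

* scheduled group events (shared meals, team meeting) at fixed clock times,
  rendered as clique contacts within small "tables" of attendees, producing
  the characteristic peaks in the interaction start-time histogram;
* background dyadic contacts with truncated-power-law durations, producing
  the long-tailed duration distribution typical of face-to-face contact data.

RSSI follows a log-distance path-loss model with Gaussian noise, calibrated
so that the expected RSSI at 2 m is -75 dBm, the operating point at which a
single threshold separates conversational proximity from bystanders.

Weekly symptom scores are generated from the windowed interaction features by
a linear mixed model with known coefficients, so that the downstream model
suite can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from wardsense.errors import ConfigError, ValidationError

# Feature names understood by the assessment generator; the first four are
# produced by the measurement pipeline, the last by the questionnaire module.
FEATURE_COLUMNS = (
    "relative_interaction_time",
    "mean_log_duration",
    "eigenvector_centrality",
    "clustering",
)


@dataclass(frozen=True)
class GroupEvent:
    """A scheduled ward activity at a fixed clock time.

    attendance is the per-person probability of joining on any given day.
    """

    name: str
    clock: str  # "HH:MM"
    duration_s: float
    attendance: float


@dataclass(frozen=True)
class DurationDist:
    """Truncated power law (Pareto with hard bounds) for contact durations."""

    exponent: float = 1.7
    min_s: float = 20.0
    max_s: float = 10_000.0


@dataclass(frozen=True)
class RssiModel:
    """Log-distance path loss: RSSI(d) = intercept - 10 * slope * log10(d) + noise.

    The default intercept of -69 dBm at 1 m with slope 2.0 puts the expected
    RSSI at 2 m at -75 dBm.
    """

    path_loss_exponent: float = 2.0
    intercept_dbm: float = -69.0
    noise_sd: float = 4.0

    def expected_rssi(self, distance_m: np.ndarray | float) -> np.ndarray | float:
        return self.intercept_dbm - 10.0 * self.path_loss_exponent * np.log10(distance_m)


DEFAULT_EVENTS = (
    GroupEvent("breakfast", "08:30", 2700.0, 0.70),
    GroupEvent("lunch", "12:30", 3600.0, 0.80),
    GroupEvent("team_meeting", "14:00", 2700.0, 0.50),
    GroupEvent("dinner", "18:00", 2700.0, 0.60),
)


@dataclass(frozen=True)
class WardConfig:
    """Everything needed to simulate one study.

    Defaults describe the reference ward: 7 patients and 18 staff observed
    over 50 weekdays (ten working weeks), 4-s beacons, 5-min battery pings,
    wear window 08:00-20:00 on weekdays only.
    """

    n_patients: int = 7
    n_staff: int = 18
    study_days: int = 50
    start_date: str = "2024-01-08"  # a Monday
    day_start: str = "08:00"
    day_end: str = "20:00"
    tz: str = "UTC"
    beacon_period: float = 4.0
    battery_period: float = 300.0
    event_schedule: Sequence[GroupEvent] = DEFAULT_EVENTS
    table_size: int = 6
    background_rate: float = 14.0  # mean background contacts per person per day
    homophily: float = 3.0  # same-role partner preference (odds multiplier)
    duration_dist: DurationDist = field(default_factory=DurationDist)
    rssi_model: RssiModel = field(default_factory=RssiModel)
    contact_distance_max: float = 2.0
    spurious_rate: float = 40.0  # out-of-range sightings per day, whole ward
    packet_drop_prob: float = 0.10
    wear_prob_patients: float = 0.80
    wear_prob_staff: float = 0.50
    wear_start_jitter_s: float = 5400.0  # badge picked up within 1.5 h of 08:00
    wear_end_jitter_s: float = 9000.0  # badge returned up to 2.5 h before 20:00
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("packet_drop_prob", "wear_prob_patients", "wear_prob_staff"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for ev in self.event_schedule:
            if not 0.0 <= ev.attendance <= 1.0:
                raise ConfigError(
                    f"event_schedule[{ev.name}].attendance must be in [0, 1], got {ev.attendance}"
                )
        if not self.beacon_period < self.battery_period:
            raise ConfigError(
                f"beacon_period ({self.beacon_period}) must be < battery_period ({self.battery_period})"
            )
        if not self.duration_dist.min_s < self.duration_dist.max_s:
            raise ConfigError(
                f"duration_dist.min_s ({self.duration_dist.min_s}) must be < max_s ({self.duration_dist.max_s})"
            )
        if self.n_patients < 3:
            raise ConfigError(
                f"n_patients must be >= 3 to record patient-patient contacts, got {self.n_patients}"
            )
        if self.study_days < 1:
            raise ConfigError(f"study_days must be >= 1, got {self.study_days}")
        if _clock_to_seconds(self.day_start) >= _clock_to_seconds(self.day_end):
            raise ConfigError(f"day_start ({self.day_start}) must be before day_end ({self.day_end})")


@dataclass
class GroundTruthSchedule:
    """Simulation ground truth: who was in contact when, and who wore a badge.

    contacts: DataFrame with columns a, b, start, end, distance_m
        (a < b canonically, start/end Unix seconds).
    wear: DataFrame with columns participant, day, wear_start, wear_end
        (day is an ISO date string; one row per worn participant-day).
    roster: DataFrame with columns participant, role.
    """

    contacts: pd.DataFrame
    wear: pd.DataFrame
    roster: pd.DataFrame
    config: WardConfig


def _clock_to_seconds(clock: str) -> int:
    h, m = clock.split(":")
    return int(h) * 3600 + int(m) * 60


def make_roster(config: WardConfig) -> pd.DataFrame:
    """Participant ids P01.. for patients, S01.. for staff."""
    ids = [f"P{i:02d}" for i in range(1, config.n_patients + 1)] + [
        f"S{i:02d}" for i in range(1, config.n_staff + 1)
    ]
    roles = ["patient"] * config.n_patients + ["staff"] * config.n_staff
    return pd.DataFrame({"participant": ids, "role": roles})


def study_weekdays(config: WardConfig) -> pd.DatetimeIndex:
    """Timezone-aware midnights of the study's weekdays."""
    return pd.bdate_range(config.start_date, periods=config.study_days, tz=config.tz)


def sample_truncated_power_law(
    rng: np.random.Generator, exponent: float, min_s: float, max_s: float, size: int
) -> np.ndarray:
    """Inverse-CDF sampling of a power law p(x) ~ x^-a on [min_s, max_s]."""
    u = rng.random(size)
    a = exponent
    if abs(a - 1.0) < 1e-9:
        return min_s * (max_s / min_s) ** u
    lo, hi = min_s ** (1.0 - a), max_s ** (1.0 - a)
    return (lo + u * (hi - lo)) ** (1.0 / (1.0 - a))


def fit_power_law_exponent(x: np.ndarray, min_s: float, max_s: float) -> float:
    """Maximum-likelihood exponent of a bounded power law, by 1-D optimisation."""
    from scipy.optimize import minimize_scalar

    x = np.asarray(x, dtype=float)
    x = x[(x >= min_s) & (x <= max_s)]
    if x.size == 0:
        raise ValueError("no observations inside [min_s, max_s]")
    slog = np.log(x).sum()
    n = x.size

    def nll(a: float) -> float:
        if abs(a - 1.0) < 1e-9:
            logc = -np.log(np.log(max_s / min_s))
        else:
            z = (max_s ** (1.0 - a) - min_s ** (1.0 - a)) / (1.0 - a)
            logc = -np.log(z)
        return -(n * logc - a * slog)

    res = minimize_scalar(nll, bounds=(0.05, 6.0), method="bounded")
    return float(res.x)


def _sample_partners(
    rng: np.random.Generator, worn_ids: np.ndarray, worn_roles: np.ndarray, homophily: float, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample n dyads: first member uniform, second weighted toward same role."""
    a_idx = rng.integers(0, worn_ids.size, size=n)
    b_idx = np.empty(n, dtype=int)
    for k in range(n):
        w = np.where(worn_roles == worn_roles[a_idx[k]], homophily, 1.0)
        w[a_idx[k]] = 0.0
        b_idx[k] = rng.choice(worn_ids.size, p=w / w.sum())
    return a_idx, b_idx


def generate_contact_schedule(config: WardConfig) -> GroundTruthSchedule:
    """Draw the ground-truth contact schedule for one simulated study.

    Contacts arise from (i) scheduled group events, rendered as cliques within
    tables of at most ``table_size`` attendees, and (ii) background dyadic
    contacts with truncated-power-law durations and role-homophilous partner
    choice.  Every contact lies within the badge-wear intervals of both
    members, hence inside weekday 08:00-20:00 windows.  Deterministic given
    the config seed.
    """
    rng = np.random.default_rng(config.seed)
    roster = make_roster(config)
    ids = roster["participant"].to_numpy()
    roles = roster["role"].to_numpy()
    n = ids.size
    days = study_weekdays(config)
    day_start_s = _clock_to_seconds(config.day_start)
    day_end_s = _clock_to_seconds(config.day_end)

    wear_rows = []
    contact_rows = []
    wear_p = np.where(roles == "patient", config.wear_prob_patients, config.wear_prob_staff)

    for day in days:
        midnight = int(day.timestamp())
        t0, t1 = midnight + day_start_s, midnight + day_end_s
        worn_mask = rng.random(n) < wear_p
        worn = np.flatnonzero(worn_mask)
        if worn.size < 2:
            continue
        ws = t0 + rng.uniform(0.0, config.wear_start_jitter_s, size=worn.size)
        we = t1 - rng.uniform(0.0, config.wear_end_jitter_s, size=worn.size)
        ws, we = np.floor(ws), np.ceil(we)
        ok = we - ws > 600.0  # a badge worn under 10 min contributes nothing
        worn, ws, we = worn[ok], ws[ok], we[ok]
        if worn.size < 2:
            continue
        day_str = day.strftime("%Y-%m-%d")
        wear_start = dict(zip(worn, ws))
        wear_end = dict(zip(worn, we))
        for i, s, e in zip(worn, ws, we):
            wear_rows.append((ids[i], day_str, int(s), int(e)))

        # -- scheduled group events: table cliques among sampled attendees
        for ev in config.event_schedule:
            ev_start = midnight + _clock_to_seconds(ev.clock)
            attendees = worn[rng.random(worn.size) < ev.attendance]
            if attendees.size < 2:
                continue
            # seating is role-assortative: patients tend to share tables,
            # as on the real ward where patients eat together
            att_pat = rng.permutation(attendees[roles[attendees] == "patient"])
            att_sta = rng.permutation(attendees[roles[attendees] == "staff"])
            attendees = np.concatenate([att_pat, att_sta])
            for lo in range(0, attendees.size, config.table_size):
                table = attendees[lo : lo + config.table_size]
                if table.size < 2:
                    continue
                for ii in range(table.size):
                    for jj in range(ii + 1, table.size):
                        p, q = int(table[ii]), int(table[jj])
                        start = ev_start + rng.uniform(-300.0, 300.0)
                        dur = ev.duration_s * rng.uniform(0.80, 1.0)
                        start = max(start, wear_start[p], wear_start[q], t0)
                        end = min(start + dur, wear_end[p], wear_end[q], t1)
                        if end - start >= 1.0:
                            contact_rows.append(
                                (p, q, int(start), int(end),
                                 rng.uniform(0.5, config.contact_distance_max), ev.name)
                            )

        # -- background dyadic contacts
        n_bg = rng.poisson(config.background_rate * worn.size / 2.0)
        if n_bg > 0:
            worn_roles = roles[worn]
            a_idx, b_idx = _sample_partners(rng, worn, worn_roles, config.homophily, n_bg)
            durs = sample_truncated_power_law(
                rng,
                config.duration_dist.exponent,
                config.duration_dist.min_s,
                config.duration_dist.max_s,
                n_bg,
            )
            for k in range(n_bg):
                p, q = int(worn[a_idx[k]]), int(worn[b_idx[k]])
                lo = max(wear_start[p], wear_start[q])
                hi = min(wear_end[p], wear_end[q])
                if hi - lo < 60.0:
                    continue
                start = rng.uniform(lo, hi - 30.0)
                end = min(start + durs[k], hi)
                if end - start >= 1.0:
                    clipped = end < start + durs[k]
                    contact_rows.append(
                        (p, q, int(start), int(end),
                         rng.uniform(0.5, config.contact_distance_max),
                         "background_clipped" if clipped else "background")
                    )

    if contact_rows:
        arr = pd.DataFrame(contact_rows, columns=["ia", "ib", "start", "end", "distance_m", "kind"])
        a = np.minimum(arr["ia"], arr["ib"])
        b = np.maximum(arr["ia"], arr["ib"])
        contacts = pd.DataFrame(
            {
                "a": ids[a],
                "b": ids[b],
                "start": arr["start"].astype(np.int64),
                "end": arr["end"].astype(np.int64),
                "distance_m": arr["distance_m"],
                "kind": arr["kind"],
            }
        ).sort_values(["start", "a", "b"], kind="stable", ignore_index=True)
    else:
        contacts = pd.DataFrame(columns=["a", "b", "start", "end", "distance_m", "kind"])
    wear = pd.DataFrame(wear_rows, columns=["participant", "day", "wear_start", "wear_end"])
    return GroundTruthSchedule(contacts=contacts, wear=wear, roster=roster, config=config)


def validate_schedule(schedule: GroundTruthSchedule) -> None:
    """Raise ValidationError if a contact lies outside either member's wear intervals."""
    c, w = schedule.contacts, schedule.wear
    if c.empty:
        return
    if (c["a"] == c["b"]).any():
        raise ValidationError("contact with identical members (a == b)")
    if (c["start"] >= c["end"]).any():
        raise ValidationError("contact with start >= end")
    tz = schedule.config.tz
    day = pd.to_datetime(c["start"], unit="s", utc=True).dt.tz_convert(tz).dt.strftime("%Y-%m-%d")
    wk = w.set_index(["participant", "day"])
    for col in ("a", "b"):
        keys = pd.MultiIndex.from_arrays([c[col], day])
        missing = ~keys.isin(wk.index)
        if missing.any():
            bad = c.loc[missing.to_numpy().nonzero()[0][0]]
            raise ValidationError(
                f"contact {bad['a']}-{bad['b']} at {bad['start']} on a day participant {bad[col]} wore no badge"
            )
        sub = wk.loc[keys]
        if ((c["start"].to_numpy() < sub["wear_start"].to_numpy()) | (c["end"].to_numpy() > sub["wear_end"].to_numpy())).any():
            raise ValidationError(f"contact outside wear interval of participant column {col}")


def _beacon_ticks(start: np.ndarray, end: np.ndarray, phase: np.ndarray, period: float):
    """Per-contact beacon times: first tick >= start on the sender's phase grid.

    Returns (tick_times, row_index) flattened over all contacts.
    """
    first_k = np.ceil((start - phase) / period)
    counts = np.maximum(np.floor((end - phase) / period) - first_k + 1, 0).astype(int)
    rows = np.repeat(np.arange(start.size), counts)
    offsets = np.concatenate([np.arange(c) for c in counts]) if rows.size else np.array([], dtype=int)
    ticks = phase[rows] + (first_k[rows] + offsets) * period
    return ticks, rows


def render_badge_logs(
    schedule: GroundTruthSchedule, config: WardConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a ground-truth schedule into noisy detection and battery logs.

    For every beacon tick of badge X inside a contact with Y, badge Y logs a
    detection of X with probability 1 - packet_drop_prob, with RSSI drawn from
    the path-loss model at the contact distance.  Additional out-of-range
    sightings (beyond ``contact_distance_max``) are injected so that the RSSI
    filter downstream has something to remove.  Battery status is logged every
    ``battery_period`` seconds while the badge is worn.

    Returns (detections, battery): detections has columns receiver_id,
    sender_id, rssi_dbm, timestamp_unix_s; battery has badge_id,
    timestamp_unix_s, level_pct.
    """
    config = config or schedule.config
    validate_schedule(schedule)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    roster = schedule.roster
    ids = roster["participant"].to_numpy()
    idx_of = {p: i for i, p in enumerate(ids)}
    phases = rng.uniform(0.0, config.beacon_period, size=ids.size)

    det_parts = []
    c = schedule.contacts
    if not c.empty:
        ai = c["a"].map(idx_of).to_numpy()
        bi = c["b"].map(idx_of).to_numpy()
        start = c["start"].to_numpy(dtype=float)
        end = c["end"].to_numpy(dtype=float)
        dist = c["distance_m"].to_numpy()
        for sender_idx, receiver_idx in ((ai, bi), (bi, ai)):
            ticks, rows = _beacon_ticks(start, end, phases[sender_idx], config.beacon_period)
            if ticks.size == 0:
                continue
            keep = rng.random(ticks.size) >= config.packet_drop_prob
            ticks, rows = ticks[keep], rows[keep]
            rssi = (
                config.rssi_model.expected_rssi(dist[rows])
                + rng.normal(0.0, config.rssi_model.noise_sd, size=rows.size)
            )
            det_parts.append(
                pd.DataFrame(
                    {
                        "receiver_id": ids[receiver_idx[rows]],
                        "sender_id": ids[sender_idx[rows]],
                        "rssi_dbm": np.round(rssi).astype(int),
                        "timestamp_unix_s": np.floor(ticks).astype(np.int64),
                    }
                )
            )

    # out-of-range sightings: isolated far-field packets the RSSI filter removes
    w = schedule.wear
    if not w.empty and config.spurious_rate > 0:
        for day_str, wd in w.groupby("day", sort=True):
            n_sp = rng.poisson(config.spurious_rate)
            if n_sp == 0 or len(wd) < 2:
                continue
            pick = rng.integers(0, len(wd), size=(n_sp, 2))
            ok = pick[:, 0] != pick[:, 1]
            pick = pick[ok]
            if pick.size == 0:
                continue
            recv = wd.iloc[pick[:, 0]]
            send = wd.iloc[pick[:, 1]]
            lo = np.maximum(recv["wear_start"].to_numpy(), send["wear_start"].to_numpy())
            hi = np.minimum(recv["wear_end"].to_numpy(), send["wear_end"].to_numpy())
            okt = hi > lo
            if not okt.any():
                continue
            t = rng.uniform(lo[okt], hi[okt])
            d = rng.uniform(config.contact_distance_max + 0.5, 8.0, size=okt.sum())
            rssi = config.rssi_model.expected_rssi(d) + rng.normal(
                0.0, config.rssi_model.noise_sd, size=d.size
            )
            det_parts.append(
                pd.DataFrame(
                    {
                        "receiver_id": recv["participant"].to_numpy()[okt],
                        "sender_id": send["participant"].to_numpy()[okt],
                        "rssi_dbm": np.round(rssi).astype(int),
                        "timestamp_unix_s": np.floor(t).astype(np.int64),
                    }
                )
            )

    if det_parts:
        detections = pd.concat(det_parts, ignore_index=True).sort_values(
            ["timestamp_unix_s", "receiver_id", "sender_id"], kind="stable", ignore_index=True
        )
    else:
        detections = pd.DataFrame(columns=["receiver_id", "sender_id", "rssi_dbm", "timestamp_unix_s"])

    bat_rows = []
    for _, row in w.iterrows():
        t = np.arange(row["wear_start"], row["wear_end"] + 1, config.battery_period)
        level = np.clip(
            100.0 - 40.0 * (t - t[0]) / 43200.0 + rng.normal(0.0, 0.5, size=t.size), 0, 100
        )
        bat_rows.append(
            pd.DataFrame(
                {
                    "badge_id": row["participant"],
                    "timestamp_unix_s": t.astype(np.int64),
                    "level_pct": np.round(level).astype(int),
                }
            )
        )
    battery = (
        pd.concat(bat_rows, ignore_index=True).sort_values(
            ["timestamp_unix_s", "badge_id"], kind="stable", ignore_index=True
        )
        if bat_rows
        else pd.DataFrame(columns=["badge_id", "timestamp_unix_s", "level_pct"])
    )
    return detections, battery


# ---------------------------------------------------------------------------
# assessments


@dataclass(frozen=True)
class AssessmentConfig:
    """Generator for weekly symptom scores with known links to interaction.

    PANSS_ij = gamma0 + sum_f gammas[f] * (feature_fij - feature_refs[f])
               + b_i + eps_ij,

    with b_i ~ N(0, random_intercept_sd^2) and eps ~ N(0, residual_sd^2).
    ``feature_refs`` anchor the intercept: gamma0 is the expected score of a
    person at the reference feature values, so changing a slope does not
    shift the whole score distribution.

    ``self_report_fidelity`` controls how much the Likert self-report index
    tracks true relative interaction time; 0 (the default) makes it pure
    noise, mirroring the empirical finding that self-reports and sensor
    measurements were unrelated.
    """

    gamma0: float = 45.0
    gammas: dict = field(
        default_factory=lambda: {
            "relative_interaction_time": -60.0,
            "mean_log_duration": -20.0,
            "eigenvector_centrality": 0.0,
            "clustering": -40.0,
            "self_report_index": 0.0,
        }
    )
    feature_refs: dict = field(
        default_factory=lambda: {
            # typical values of a simulated ward resident, so gamma0 is the
            # expected score of an average person
            "relative_interaction_time": 0.30,
            "mean_log_duration": 0.80,
            "eigenvector_centrality": 0.27,
            "clustering": 0.60,
            "self_report_index": 4.0,
        }
    )
    random_intercept_sd: float = 8.0
    residual_sd: float = 4.0
    assessment_period: int = 7
    self_report_fidelity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise ConfigError("random_intercept_sd and residual_sd must be >= 0")
        if self.assessment_period < 1:
            raise ConfigError(f"assessment_period must be >= 1, got {self.assessment_period}")
        if not -1.0 <= self.self_report_fidelity <= 1.0:
            raise ConfigError("self_report_fidelity must be in [-1, 1]")


def _likert(rng: np.random.Generator, latent: np.ndarray) -> np.ndarray:
    """Map a latent standard-normal-ish score to a neutral-heavy 7-point item."""
    raw = 4.0 + 1.1 * latent + rng.normal(0.0, 0.5, size=latent.size)
    return np.clip(np.round(raw), 1, 7).astype(int)


def generate_assessments(features: pd.DataFrame, config: AssessmentConfig) -> pd.DataFrame:
    """Generate a weekly assessment table from windowed interaction features.

    ``features`` must have columns participant, date, and the feature columns
    named in ``config.gammas`` (``self_report_index`` is generated here and
    may appear in gammas without being a column).  Returns one row per
    (participant, date) with panss_total, subscale scores, bdi, the two Likert
    items, self_report_index, and olanzapine-equivalent doses at study start
    and end (person constants).
    """
    for name in config.gammas:
        if name != "self_report_index" and name not in features.columns:
            raise ConfigError(f"gammas names feature '{name}' absent from features table")
    rng = np.random.default_rng(config.seed)
    out = features.copy().sort_values(["participant", "date"], ignore_index=True)
    participants = out["participant"].unique()
    b = dict(zip(participants, rng.normal(0.0, config.random_intercept_sd, size=participants.size)))

    # self-report: fidelity-weighted mixture of true interaction and noise
    rel = out.get("relative_interaction_time")
    if rel is not None and np.nanstd(rel.to_numpy(dtype=float)) > 0:
        z = (rel - np.nanmean(rel)) / np.nanstd(rel.to_numpy(dtype=float))
        z = z.fillna(0.0).to_numpy()
    else:
        z = np.zeros(len(out))
    f = config.self_report_fidelity
    latent = f * z + np.sqrt(max(0.0, 1.0 - f * f)) * rng.normal(size=len(out))
    item2 = _likert(rng, latent)
    item1 = _likert(rng, -latent)  # "time alone in room", reverse-coded downstream
    out["item1"] = item1
    out["item2"] = item2
    out["self_report_index"] = ((8 - item1) + item2) / 2.0

    lin = np.full(len(out), config.gamma0, dtype=float)
    for name, g in config.gammas.items():
        if g == 0.0:
            continue
        ref = config.feature_refs.get(name, 0.0)
        lin += g * (out[name].to_numpy(dtype=float) - ref)
    lin += out["participant"].map(b).to_numpy()
    eps = rng.normal(0.0, config.residual_sd, size=len(out))
    out["panss_total"] = np.round(lin + eps).astype(int)

    # subscales: proportional split of the above-floor score plus item noise
    excess = np.maximum(out["panss_total"] - 30, 0).astype(float)
    pos = np.round(7 + 0.25 * excess + rng.normal(0, 1.0, len(out)))
    neg = np.round(7 + 0.30 * excess + rng.normal(0, 1.0, len(out)))
    gen = np.round(16 + 0.45 * excess + rng.normal(0, 1.5, len(out)))
    out["panss_positive"] = np.clip(pos, 7, 49).astype(int)
    out["panss_negative"] = np.clip(neg, 7, 49).astype(int)
    out["panss_general"] = np.clip(gen, 16, 112).astype(int)
    bdi = np.round(0.45 * excess + 8 + rng.normal(0, 3.0, len(out)))
    out["bdi"] = np.clip(bdi, 0, 63).astype(int)

    olz_start = {p: float(np.round(min(rng.exponential(12.0), 42.0), 1)) for p in participants}
    olz_end = {p: float(np.round(olz_start[p] * rng.uniform(0.4, 1.1), 1)) for p in participants}
    out["olanzapine_mg_start"] = out["participant"].map(olz_start)
    out["olanzapine_mg_end"] = out["participant"].map(olz_end)
    return out


def structural_from_marginal(
    features: pd.DataFrame, marginal: dict[str, float]
) -> dict[str, float]:
    """Structural slopes that realise given *marginal* (univariate) slopes.

    The analysis models are univariate: each regresses the outcome on a
    single group-mean-centered feature, so when features are correlated
    within person, a structural coefficient of zero on one feature does not
    make its univariate slope zero — correlated features leak in.  Given the
    realised feature table, this solves C a = diag(C) g (C the pooled
    within-person covariance of the features, g the marginal targets) for the
    structural coefficient vector a, so that generating the outcome with
    ``gammas = a`` makes the expected univariate slope of feature f equal
    marginal[f].  With uncorrelated features a == g.
    """
    names = [k for k in marginal if k in features.columns]
    centered = features[names] - features.groupby(features["participant"])[names].transform("mean")
    C = np.cov(centered.to_numpy(dtype=float), rowvar=False)
    C = np.atleast_2d(C)
    g = np.array([marginal[k] for k in names])
    a = np.linalg.solve(C, np.diag(C) * g)
    out = dict(zip(names, a.astype(float)))
    for k in marginal:
        out.setdefault(k, marginal[k])
    return out


def simulate_feature_table(
    n_participants: int,
    n_assessments: int,
    rng: np.random.Generator,
    means: dict | None = None,
    within_sds: dict | None = None,
    between_sds: dict | None = None,
    start_date: str = "2024-01-12",
    period_days: int = 7,
) -> pd.DataFrame:
    """Directly draw a windowed-feature table without running the sensor pipeline.

    Features are independent within person (Gaussian around person-level
    means), which is the controlled setting for slope-recovery and
    null-calibration experiments on the model suite.
    """
    means = means or {
        "relative_interaction_time": 0.25,
        "mean_log_duration": 0.6,
        "eigenvector_centrality": 0.20,
        "clustering": 0.30,
    }
    within_sds = within_sds or {
        "relative_interaction_time": 0.05,
        "mean_log_duration": 0.12,
        "eigenvector_centrality": 0.05,
        "clustering": 0.08,
    }
    between_sds = between_sds or {k: v for k, v in within_sds.items()}
    dates = pd.date_range(start_date, periods=n_assessments, freq=f"{period_days}D")
    rows = {"participant": [], "date": []}
    for k in means:
        rows[k] = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        person_mean = {k: means[k] + rng.normal(0.0, between_sds[k]) for k in means}
        for d in dates:
            rows["participant"].append(pid)
            rows["date"].append(d.strftime("%Y-%m-%d"))
            for k in means:
                rows[k].append(person_mean[k] + rng.normal(0.0, within_sds[k]))
    return pd.DataFrame(rows)


def with_seed(config: WardConfig, seed: int) -> WardConfig:
    """Convenience: same ward, different random seed."""
    return replace(config, seed=seed)
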