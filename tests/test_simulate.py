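"""The synthetic ward: schedules, rendered logs, assessment generation."""

import numpy as np
import pandas as pd
import pytest

from wardsense.errors import ConfigError
from wardsense.simulate import (
    AssessmentConfig,
    DurationDist,
    GroupEvent,
    RssiModel,
    WardConfig,
    fit_power_law_exponent,
    generate_assessments,
    generate_contact_schedule,
    make_roster,
    render_badge_logs,
    sample_truncated_power_law,
    simulate_feature_table,
    structural_from_marginal,
    validate_schedule,
    with_seed,
)


@pytest.mark.parametrize(
    "kwargs, named",
    [
        ({"packet_drop_prob": 1.5}, "packet_drop_prob"),
        ({"wear_prob_staff": -0.1}, "wear_prob_staff"),
        ({"beacon_period": 400.0}, "beacon_period"),
        ({"duration_dist": DurationDist(min_s=100.0, max_s=10.0)}, "duration_dist"),
        ({"n_patients": 2}, "n_patients"),
        ({"day_start": "21:00"}, "day_start"),
    ],
)
def test_invalid_config_names_the_field(kwargs, named):
    with pytest.raises(ConfigError, match=named):
        WardConfig(**kwargs)


def test_empty_schedule_without_contact_sources():
    cfg = WardConfig(background_rate=0.0, event_schedule=(), study_days=3, seed=1)
    schedule = generate_contact_schedule(cfg)
    assert len(schedule.contacts) == 0


def test_contacts_lie_within_wear_and_day_windows(small_logs):
    schedule, _, _ = small_logs
    validate_schedule(schedule)  # raises on any violation
    local = pd.to_datetime(schedule.contacts["start"], unit="s", utc=True)
    assert (local.dt.dayofweek < 5).all()
    assert (local.dt.hour >= 8).all()
    ends = pd.to_datetime(schedule.contacts["end"], unit="s", utc=True)
    assert (ends.dt.hour * 60 + ends.dt.minute <= 20 * 60).all()


def test_start_time_histogram_peaks_at_scheduled_events():
    """Meal-time activity shows as local maxima of the start-time histogram."""
    cfg = WardConfig(
        event_schedule=(
            GroupEvent("breakfast", "08:30", 2700.0, 0.8),
            GroupEvent("lunch", "12:30", 3600.0, 0.8),
        ),
        study_days=10,
        background_rate=6.0,
        seed=3,
    )
    schedule = generate_contact_schedule(cfg)
    hours = pd.to_datetime(schedule.contacts["start"], unit="s", utc=True).dt.hour
    counts = hours.value_counts().reindex(range(8, 20), fill_value=0)
    assert counts[8] > counts[10]
    assert counts[12] > counts[10] and counts[12] > counts[15]


def test_power_law_mle_recovers_exponent(rng):
    x = sample_truncated_power_law(rng, 2.0, 10.0, 10_000.0, 20_000)
    assert abs(fit_power_law_exponent(x, 10.0, 10_000.0) - 2.0) < 0.1


def test_schedule_and_logs_deterministic_given_seed(small_ward):
    s1 = generate_contact_schedule(small_ward)
    s2 = generate_contact_schedule(small_ward)
    pd.testing.assert_frame_equal(s1.contacts, s2.contacts)
    d1, b1 = render_badge_logs(s1, small_ward)
    d2, b2 = render_badge_logs(s2, small_ward)
    assert d1.to_csv(index=False) == d2.to_csv(index=False)
    assert b1.to_csv(index=False) == b2.to_csv(index=False)
    s3 = generate_contact_schedule(with_seed(small_ward, 99))
    assert s3.contacts.to_csv(index=False) != s1.contacts.to_csv(index=False)


def _single_contact_schedule(cfg, duration_s=60, distance=1.0):
    roster = make_roster(cfg)
    t0 = int(pd.Timestamp("2024-01-08 09:00", tz="UTC").timestamp())
    contacts = pd.DataFrame(
        {"a": ["P01"], "b": ["P02"], "start": [t0], "end": [t0 + duration_s], "distance_m": [distance]}
    )
    wear = pd.DataFrame(
        {
            "participant": ["P01", "P02"],
            "day": ["2024-01-08"] * 2,
            "wear_start": [t0 - 3600] * 2,
            "wear_end": [t0 + 7200] * 2,
        }
    )
    from wardsense.simulate import GroundTruthSchedule

    return GroundTruthSchedule(contacts=contacts, wear=wear, roster=roster, config=cfg)


def test_lossless_render_gives_one_detection_per_beacon_tick():
    cfg = WardConfig(packet_drop_prob=0.0, spurious_rate=0.0, rssi_model=RssiModel(noise_sd=0.0))
    sched = _single_contact_schedule(cfg, duration_s=60)
    det, _ = render_badge_logs(sched, cfg)
    per_direction = det.groupby(["receiver_id", "sender_id"]).size()
    assert set(per_direction.index) == {("P01", "P02"), ("P02", "P01")}
    # 60 s of 4-s beacons: 15 ticks, one boundary tick may fall either side
    assert (per_direction.isin([15, 16])).all()
    # at 1 m the noiseless path-loss model gives the intercept: -69 dBm
    assert (det["rssi_dbm"] == -69).all()


def test_packet_drop_thins_detections_binomially():
    """Mean per-direction count over 200 seeds within 3 SE of n*p = 7.5."""
    counts = []
    for seed in range(200):
        cfg = WardConfig(
            packet_drop_prob=0.5, spurious_rate=0.0, rssi_model=RssiModel(noise_sd=0.0), seed=seed
        )
        det, _ = render_badge_logs(_single_contact_schedule(cfg, duration_s=60), cfg)
        counts.append((det["receiver_id"] == "P01").sum())
        counts.append((det["receiver_id"] == "P02").sum())
    n, p = 15, 0.5
    se = np.sqrt(n * p * (1 - p) / len(counts))
    assert abs(np.mean(counts) - n * p) < 3 * se + 0.5  # +0.5 for the boundary tick


def test_unworn_participant_appears_in_no_record():
    cfg = WardConfig(n_patients=3, n_staff=3, wear_prob_staff=0.0, study_days=4, seed=2)
    schedule = generate_contact_schedule(cfg)
    det, bat = render_badge_logs(schedule, cfg)
    staff = {f"S{i:02d}" for i in range(1, 4)}
    assert not (set(det["receiver_id"]) | set(det["sender_id"])) & staff
    assert not set(bat["badge_id"]) & staff


def test_rssi_model_operating_point():
    m = RssiModel()
    assert m.expected_rssi(2.0) == pytest.approx(-75.0, abs=0.1)


# -- assessments -------------------------------------------------------------


def _flat_features(n_part=4, n_dates=3):
    return simulate_feature_table(n_part, n_dates, np.random.default_rng(0))


def test_degenerate_assessments_equal_gamma0():
    cfg = AssessmentConfig(
        gammas={k: 0.0 for k in ["relative_interaction_time", "clustering"]},
        random_intercept_sd=0.0,
        residual_sd=0.0,
        seed=1,
    )
    out = generate_assessments(_flat_features(), cfg)
    assert (out["panss_total"] == cfg.gamma0).all()


def test_unknown_gamma_feature_raises():
    cfg = AssessmentConfig(gammas={"no_such_feature": 1.0})
    with pytest.raises(ConfigError, match="no_such_feature"):
        generate_assessments(_flat_features(), cfg)


def test_assessments_deterministic_and_likert_in_range():
    cfg = AssessmentConfig(seed=9)
    a1 = generate_assessments(_flat_features(), cfg)
    a2 = generate_assessments(_flat_features(), cfg)
    pd.testing.assert_frame_equal(a1, a2)
    for col in ("item1", "item2"):
        assert a1[col].between(1, 7).all()
    assert a1["self_report_index"].between(1, 7).all()


def test_self_report_tracks_interaction_only_through_fidelity():
    feats = simulate_feature_table(10, 12, np.random.default_rng(3))
    null = generate_assessments(feats, AssessmentConfig(self_report_fidelity=0.0, seed=4))
    tight = generate_assessments(feats, AssessmentConfig(self_report_fidelity=0.95, seed=4))
    r_null = np.corrcoef(null["relative_interaction_time"], null["self_report_index"])[0, 1]
    r_tight = np.corrcoef(tight["relative_interaction_time"], tight["self_report_index"])[0, 1]
    assert abs(r_null) < 0.25
    assert r_tight > 0.6


def test_structural_from_marginal_inverts_feature_correlation(rng):
    """Generating with converted slopes makes univariate slopes hit the targets."""
    n = 4000
    g = np.repeat(np.arange(200), n // 200)
    z = rng.normal(size=n)
    x1 = z + 0.5 * rng.normal(size=n)
    x2 = 0.8 * z + 0.6 * rng.normal(size=n)  # strongly correlated with x1
    feats = pd.DataFrame({"participant": g, "f1": x1, "f2": x2})
    target = {"f1": -2.0, "f2": 0.0}
    a = structural_from_marginal(feats, target)
    y = a["f1"] * x1 + a["f2"] * x2
    for name, x in (("f1", x1), ("f2", x2)):
        slope = np.cov(y, x)[0, 1] / np.var(x)
        assert slope == pytest.approx(target[name], abs=0.15)
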