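"""Event reconstruction: interval algebra, mutual detection, daily summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wardsense.errors import ConfigError
from wardsense.interactions import (
    ReconstructionConfig,
    daily_summary,
    directional_intervals,
    intersect_intervals,
    merge_intervals,
    reconstruct_interactions,
    total_length,
    union_intervals,
)
from tests.conftest import detection_frame

BASE = int(pd.Timestamp("2024-01-08 10:00", tz="UTC").timestamp())
CFG = ReconstructionConfig()


def _det(pairs_ts, receiver="A", sender="B"):
    return detection_frame([(receiver, sender, -60, BASE + t) for t in pairs_ts])


def test_config_invariant():
    with pytest.raises(ConfigError):
        ReconstructionConfig(gap_max=2.0, beacon_period=4.0)
    with pytest.raises(ConfigError):
        ReconstructionConfig(mode="nonsense")


@pytest.mark.parametrize(
    "ticks, expected",
    [
        ([0, 4, 8], [[0, 12]]),  # contiguous chain of beacons
        ([0, 100], [[0, 4], [100, 104]]),  # 96-s gap exceeds the 75-s bridge
        ([0, 79], [[0, 83]]),  # gap of exactly 75 s is bridged ("up to 75 s")
    ],
)
def test_directional_intervals(ticks, expected):
    iv = directional_intervals(_det(ticks), "A", "B", CFG)
    np.testing.assert_allclose(iv - BASE, np.array(expected, dtype=float))


def _two_direction_records(fwd_ticks, rev_ticks):
    return pd.concat([_det(fwd_ticks, "A", "B"), _det(rev_ticks, "B", "A")], ignore_index=True)


def test_intersection_mode_requires_mutual_detection():
    # A hears B over [0,100], B hears A over [50,150] -> event [50,100]
    records = _two_direction_records(range(0, 97, 4), range(50, 147, 4))
    events = reconstruct_interactions(records, CFG)
    assert len(events) == 1
    ev = events.iloc[0]
    assert (ev["start"] - BASE, ev["end"] - BASE) == (50, 100)
    assert ev["duration_s"] == 50


def test_union_mode_accepts_either_direction():
    records = _two_direction_records(range(0, 97, 4), range(50, 147, 4))
    events = reconstruct_interactions(records, ReconstructionConfig(mode="union"))
    assert len(events) == 1
    assert (events.iloc[0]["start"] - BASE, events.iloc[0]["end"] - BASE) == (0, 150)


def test_dead_badge_yields_no_intersection_events():
    records = _det(range(0, 97, 4), "A", "B")  # B never logs A
    assert reconstruct_interactions(records, CFG).empty


def test_event_symmetry_under_direction_relabelling():
    rec1 = _two_direction_records(range(0, 40, 4), range(8, 60, 4))
    rec2 = rec1.rename(columns={"receiver_id": "sender_id", "sender_id": "receiver_id"})
    pd.testing.assert_frame_equal(reconstruct_interactions(rec1, CFG), reconstruct_interactions(rec2, CFG))


# -- brute-force boolean-timeline oracle -------------------------------------


def _oracle_events(fwd_ticks, rev_ticks, cfg: ReconstructionConfig):
    """Second-by-second reconstruction on a dense boolean timeline."""

    def timeline(ticks):
        horizon = int(max(list(fwd_ticks) + list(rev_ticks), default=0) + cfg.beacon_period + 2)
        line = np.zeros(horizon, dtype=bool)
        for t in ticks:
            line[int(t) : int(t + cfg.beacon_period)] = True
        return line

    def bridge(line):
        out = line.copy()
        idx = np.flatnonzero(line)
        for a, b in zip(idx[:-1], idx[1:]):
            if b - a - 1 <= cfg.gap_max:
                out[a:b] = True
        return out

    fwd, rev = bridge(timeline(fwd_ticks)), bridge(timeline(rev_ticks))
    both = bridge(fwd & rev) if cfg.mode == "intersection" else (fwd | rev)
    # extract maximal runs
    padded = np.concatenate([[False], both, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    return [(s, e) for s, e in zip(starts, ends)]


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    fwd=st.lists(st.integers(0, 500), max_size=25),
    rev=st.lists(st.integers(0, 500), max_size=25),
    mode=st.sampled_from(["intersection", "union"]),
    gap=st.sampled_from([4.0, 20.0, 75.0]),
)
def test_reconstruction_matches_boolean_timeline_oracle(fwd, rev, mode, gap):
    cfg = ReconstructionConfig(gap_max=gap, mode=mode)
    records = _two_direction_records(sorted(fwd), sorted(rev))
    events = reconstruct_interactions(records, cfg)
    got = [(int(r.start - BASE), int(r.end - BASE)) for r in events.itertuples(index=False)]
    assert got == _oracle_events(fwd, rev, cfg)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(
    fwd=st.lists(st.integers(0, 400), min_size=1, max_size=20),
    rev=st.lists(st.integers(0, 400), min_size=1, max_size=20),
)
def test_union_dominates_intersection(fwd, rev):
    records = _two_direction_records(sorted(fwd), sorted(rev))
    inter = reconstruct_interactions(records, ReconstructionConfig(mode="intersection"))
    union = reconstruct_interactions(records, ReconstructionConfig(mode="union"))
    assert union["duration_s"].sum() >= inter["duration_s"].sum()


def test_interval_primitives_agree_with_sets(rng):
    for _ in range(50):
        a = np.sort(rng.integers(0, 200, size=(4, 2)), axis=1)
        b = np.sort(rng.integers(0, 200, size=(4, 2)), axis=1)
        a, b = a[a[:, 0] != a[:, 1]], b[b[:, 0] != b[:, 1]]
        am, bm = merge_intervals(a), merge_intervals(b)
        sa = set().union(*[range(int(s), int(e)) for s, e in am]) if am.size else set()
        sb = set().union(*[range(int(s), int(e)) for s, e in bm]) if bm.size else set()
        assert total_length(intersect_intervals(am, bm)) == len(sa & sb)
        assert total_length(union_intervals(am, bm)) == len(sa | sb)


# -- daily summaries ---------------------------------------------------------

ROSTER = pd.DataFrame(
    {"participant": ["P01", "P02", "S01"], "role": ["patient", "patient", "staff"]}
)


def _events(rows):
    return pd.DataFrame(rows, columns=["day", "a", "b", "start", "end", "duration_s"])


def _active(rows):
    return pd.DataFrame(rows, columns=["participant", "day", "active_s"])


def test_daily_summary_relative_time_and_log_duration():
    ev = _events(
        [
            ("2024-01-08", "P01", "P02", 0, 600, 600),
            ("2024-01-08", "P01", "S01", 1000, 2200, 1200),
        ]
    )
    act = _active([("P01", "2024-01-08", 36_000.0)])
    row = daily_summary(ev, act, ROSTER).set_index("participant").loc["P01"]
    assert row["relative_interaction_time"] == pytest.approx(0.05)
    # (log10 10 + log10 20) / 2, minutes convention
    assert row["mean_log_duration"] == pytest.approx(1.1505, abs=1e-4)
    assert row["with_patient_s"] == 600 and row["with_staff_s"] == 1200


def test_daily_summary_no_events():
    act = _active([("P01", "2024-01-08", 36_000.0)])
    row = daily_summary(_events([]), act, ROSTER).iloc[0]
    assert row["relative_interaction_time"] == 0.0
    assert np.isnan(row["mean_log_duration"])


def test_overlapping_partners_count_once_toward_time_but_twice_as_events():
    ev = _events(
        [
            ("2024-01-08", "P01", "P02", 0, 600, 600),
            ("2024-01-08", "P01", "S01", 0, 600, 600),
        ]
    )
    act = _active([("P01", "2024-01-08", 36_000.0)])
    row = daily_summary(ev, act, ROSTER).set_index("participant").loc["P01"]
    assert row["total_interaction_s"] == 600
    assert row["n_interactions"] == 2
    # role splits may sum to more than the overall total
    assert row["with_patient_s"] + row["with_staff_s"] > row["total_interaction_s"]


def test_events_without_active_time_are_flagged():
    ev = _events([("2024-01-08", "P01", "P02", 0, 600, 600)])
    out = daily_summary(ev, _active([]), ROSTER).set_index("participant")
    assert bool(out.loc["P01", "inconsistent"])
    assert np.isnan(out.loc["P01", "relative_interaction_time"])


# -- recovery on lossless synthetic logs -------------------------------------


def test_lossless_logs_recover_ground_truth_contacts(noiseless_ward):
    from wardsense.ingest import filter_records
    from wardsense.simulate import generate_contact_schedule, render_badge_logs

    schedule = generate_contact_schedule(noiseless_ward)
    detections, _ = render_badge_logs(schedule, noiseless_ward)
    filtered, _ = filter_records(detections)
    events = reconstruct_interactions(filtered, CFG)
    truth = schedule.contacts
    # merge ground-truth contacts per dyad as reconstruction cannot split
    # contacts closer than the bridging gap
    for (a, b), grp in truth.groupby(["a", "b"]):
        tiv = merge_intervals(grp[["start", "end"]].to_numpy(float), gap_max=CFG.gap_max)
        got = events[(events["a"] == a) & (events["b"] == b)][["start", "end"]].to_numpy(float)
        got = merge_intervals(got, gap_max=CFG.gap_max) if got.size else got
        assert got.shape == tiv.shape
        assert np.abs(got - tiv).max() <= CFG.beacon_period
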