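"""Clean the raw logs and reconstruct dyadic interaction events.

Applies the cleaning funnel (duplicates, weekends, out-of-hours, RSSI below
-75 dBm), derives badge active time from battery pings, reconstructs
mutual-detection events with 75-s gap bridging, and summarises each
participant-day.  Reads results/study/raw/, writes results/study/.
"""

from pathlib import Path

import pandas as pd

from wardsense.ingest import FilterConfig, active_time_table, filter_records, read_detection_log
from wardsense.interactions import ReconstructionConfig, daily_summary, reconstruct_interactions

RAW = Path("results/study/raw")
OUT = Path("results/study")


def main() -> None:
    detections, rejects = read_detection_log(RAW / "detections.csv")
    battery = pd.read_csv(RAW / "battery.csv")
    roster = pd.read_csv(RAW / "roster.csv")

    filtered, counts = filter_records(detections, FilterConfig())
    print(f"filter funnel: {len(detections)} in -> {len(filtered)} kept "
          f"(dup {counts.duplicate}, weekend {counts.weekend}, "
          f"hours {counts.out_of_hours}, weak-signal {counts.rssi}; parse rejects {len(rejects)})")

    active = active_time_table(battery)
    events = reconstruct_interactions(filtered, ReconstructionConfig())
    summaries = daily_summary(events, active, roster)

    filtered.to_csv(OUT / "detections_filtered.csv", index=False)
    active.to_csv(OUT / "active_time.csv", index=False)
    events.to_csv(OUT / "events.csv", index=False)
    summaries.to_csv(OUT / "daily_summaries.csv", index=False)

    pat = summaries[summaries["role"] == "patient"]
    print(f"{len(events)} interaction events over {summaries['day'].nunique()} days")
    print(f"patients: {pat['total_interaction_s'].mean() / 3600:.2f} h/day interacting "
          f"({pat['with_staff_s'].mean() / 3600:.2f} h with staff, "
          f"{pat['with_patient_s'].mean() / 3600:.2f} h with patients), "
          f"badge active {pat['active_s'].mean() / 3600:.1f} h/day")


if __name__ == "__main__":
    main()
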