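"""Simulate the reference ward and render its raw badge logs.

Generates the ground-truth contact schedule for a 7-patient / 18-staff ward
observed over 50 weekdays (scheduled meals and meetings plus power-law
background contacts), renders it into noisy detection and battery logs, and
writes everything under results/study/raw/.
"""

import sys
from pathlib import Path

from wardsense.simulate import WardConfig, generate_contact_schedule, render_badge_logs

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results/study/raw")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = WardConfig(seed=SEED)
    schedule = generate_contact_schedule(cfg)
    detections, battery = render_badge_logs(schedule, cfg)

    schedule.contacts.to_csv(OUT / "ground_truth_contacts.csv", index=False)
    schedule.wear.to_csv(OUT / "wear_log.csv", index=False)
    schedule.roster.to_csv(OUT / "roster.csv", index=False)
    detections.to_csv(OUT / "detections.csv", index=False)
    battery.to_csv(OUT / "battery.csv", index=False)

    n_meal = (schedule.contacts["kind"] != "background").sum()
    print(f"ward: {cfg.n_patients} patients, {cfg.n_staff} staff, {cfg.study_days} weekdays")
    print(f"ground truth: {len(schedule.contacts)} contacts "
          f"({n_meal} from scheduled events), {len(schedule.wear)} worn participant-days")
    print(f"rendered: {len(detections)} detections, {len(battery)} battery pings -> {OUT}")


if __name__ == "__main__":
    main()
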