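"""Validation experiments: oracles, recovery, calibration, pattern detection.

Re-derives the pipeline's critical computations through independent routes
(dense eigendecomposition, exhaustive triple enumeration, ground-truth
comparison, Monte-Carlo simulation) and writes the agreement summary to
results/validation.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from wardsense.experiments import (
    metric_oracle_errors,
    reconstruction_recovery,
    sign_pattern_experiment,
    slope_recovery_experiment,
    type1_error_experiment,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
OUT = Path("results")


def main() -> None:
    report = {
        "metric_oracles": metric_oracle_errors(n_graphs=500, seed=SEED),
        "reconstruction": reconstruction_recovery(seed=SEED),
        "slope_recovery": slope_recovery_experiment(n_reps=200, seed=SEED),
        "type1_error": type1_error_experiment(n_reps=500, seed=SEED),
    }
    feats_path = OUT / "study" / "windowed_features.csv"
    if feats_path.exists():
        feats = pd.read_csv(feats_path)
        feats = feats[["participant", "date", "relative_interaction_time",
                       "mean_log_duration", "eigenvector_centrality", "clustering"]].dropna()
        report["sign_pattern"] = sign_pattern_experiment(feats, n_reps=50, seed=SEED)

    OUT.mkdir(exist_ok=True)
    with open(OUT / "validation.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    print(json.dumps(report, indent=2, default=float))


if __name__ == "__main__":
    main()
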