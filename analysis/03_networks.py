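"""Build daily weighted graphs and compute node metrics.

One undirected graph per day (edge when a dyad's summed interaction exceeds
10 min; weight log10 minutes), then eigenvector centrality and the
max-normalised Saramäki clustering coefficient per node, and windowed
per-assessment feature means for the patients.
"""

from pathlib import Path

import pandas as pd

from wardsense.longitudinal import window_features
from wardsense.networks import daily_graphs_from_events, metrics_table
from wardsense.pipeline import default_assessment_dates
from wardsense.simulate import WardConfig

OUT = Path("results/study")


def main() -> None:
    events = pd.read_csv(OUT / "events.csv")
    active = pd.read_csv(OUT / "active_time.csv")
    roster = pd.read_csv(OUT / "raw" / "roster.csv")
    summaries = pd.read_csv(OUT / "daily_summaries.csv")

    graphs = daily_graphs_from_events(events, active)
    metrics = metrics_table(graphs)
    metrics.to_csv(OUT / "node_metrics.csv", index=False)
    edges = pd.concat([g.edge_table() for g in graphs if g.graph.number_of_edges()],
                      ignore_index=True)
    edges.to_csv(OUT / "edges.csv", index=False)
    print(f"{len(graphs)} daily graphs, {len(edges)} edges "
          f"({len(edges) / len(graphs):.1f}/day), weight range "
          f"{edges['weight'].min():.2f}-{edges['weight'].max():.2f} (log10 min)")

    daily = summaries.merge(metrics, on=["participant", "day"], how="left")
    daily.to_csv(OUT / "daily_metrics.csv", index=False)

    patients = roster.loc[roster["role"] == "patient", "participant"]
    dates = default_assessment_dates(WardConfig())
    frame = pd.DataFrame([(p, d) for p in patients for d in dates],
                         columns=["participant", "date"])
    feats = window_features(daily[daily["participant"].isin(patients)], frame)
    feats.to_csv(OUT / "windowed_features.csv", index=False)
    print(f"windowed features: {len(feats)} patient-assessments "
          f"({feats['n_days_used'].mean():.1f} days each)")


if __name__ == "__main__":
    main()
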