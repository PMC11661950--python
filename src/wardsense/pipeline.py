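"""One-command orchestration: raw logs (or a simulation) to the model report.

Stages: ingest -> interactions -> networks -> longitudinal, optionally
preceded by the synthetic-ward simulator.  Every intermediate table is
written as delimited text under the output directory, a structured run report
records per-stage record counts (the cleaning funnel, events reconstructed,
edges per day, model n), and summary figures mirror the descriptive plots of
the analysis (interaction start-time histogram, log-log duration histogram,
daily graph snapshots, per-model scatter with the fitted fixed effect).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wardsense import ingest, interactions, networks, simulate
from wardsense.errors import ConfigError
from wardsense.longitudinal import (
    assemble_analysis_table,
    run_model_suite,
    run_subscale_suite,
    window_features,
)


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of simulation mode (``simulate=True``) or real-data mode
    (detection/battery/roster/assessment paths) must be active.
    """

    outdir: str = "results/run"
    simulate: bool = True
    seed: int = 0
    ward: simulate.WardConfig = None
    assessment: simulate.AssessmentConfig = None
    detections_path: str | None = None
    battery_path: str | None = None
    roster_path: str | None = None
    assessments_path: str | None = None
    filter: ingest.FilterConfig = field(default_factory=ingest.FilterConfig)
    reconstruction: interactions.ReconstructionConfig = field(
        default_factory=interactions.ReconstructionConfig
    )
    min_edge_minutes: float = networks.DEFAULT_MIN_EDGE_MINUTES
    window_days: int = 7
    omit_staff: bool = False
    medication: bool = False
    cooks_threshold: float | None = None
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.ward is None:
            self.ward = simulate.WardConfig(seed=self.seed)
        if self.assessment is None:
            self.assessment = simulate.AssessmentConfig(seed=self.seed + 1)
        paths = [self.detections_path, self.battery_path]
        if self.simulate and any(p is not None for p in paths):
            raise ConfigError("provide either simulation mode or log paths, not both")
        if not self.simulate:
            for name in ("detections_path", "battery_path", "roster_path", "assessments_path"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigError(f"real-data mode requires {name}")
                if not Path(p).exists():
                    raise ConfigError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        ward = raw.pop("ward", None)
        assessment = raw.pop("assessment", None)
        flt = raw.pop("filter", None)
        recon = raw.pop("reconstruction", None)
        kw = dict(raw)
        if ward:
            if "event_schedule" in ward:
                ward["event_schedule"] = tuple(
                    simulate.GroupEvent(**e) for e in ward["event_schedule"]
                )
            if "duration_dist" in ward:
                ward["duration_dist"] = simulate.DurationDist(**ward["duration_dist"])
            if "rssi_model" in ward:
                ward["rssi_model"] = simulate.RssiModel(**ward["rssi_model"])
            kw["ward"] = simulate.WardConfig(**ward)
        if assessment:
            kw["assessment"] = simulate.AssessmentConfig(**assessment)
        if flt:
            kw["filter"] = ingest.FilterConfig(**flt)
        if recon:
            kw["reconstruction"] = interactions.ReconstructionConfig(**recon)
        return cls(**kw)


def default_assessment_dates(ward: simulate.WardConfig, period_days: int = 7) -> list[str]:
    """Weekly assessment dates: every ``period_days`` days from the first Friday."""
    days = simulate.study_weekdays(ward)
    first = days[0] + pd.Timedelta(days=4)  # study starts on a Monday
    dates = []
    d = first
    while d <= days[-1]:
        dates.append(d.strftime("%Y-%m-%d"))
        d += pd.Timedelta(days=period_days)
    return dates


def validate_inputs(
    detections: pd.DataFrame,
    battery: pd.DataFrame,
    roster: pd.DataFrame,
    assessments: pd.DataFrame | None = None,
) -> list[str]:
    """Cross-table consistency report (warnings only, nothing is mutated)."""
    warnings = []
    for name, frame in (("detections", detections), ("battery", battery)):
        for pid in ingest.check_roster_ids(frame, roster):
            warnings.append(f"{name}: id '{pid}' not in roster")
    if len(detections):
        if (detections["rssi_dbm"] > 0).any():
            warnings.append("detections: positive RSSI values (dBm expected to be negative)")
        tmin, tmax = detections["timestamp_unix_s"].min(), detections["timestamp_unix_s"].max()
        if assessments is not None and len(assessments):
            ad = pd.to_datetime(assessments["date"]).astype("int64") // 10**9
            if (ad < tmin - 14 * 86400).any() or (ad > tmax + 14 * 86400).any():
                warnings.append("assessments: date(s) far outside the detection log range")
    if assessments is not None and len(assessments):
        unknown = set(assessments["participant"]) - set(roster["participant"])
        for pid in sorted(unknown):
            warnings.append(f"assessments: id '{pid}' not in roster")
    return warnings


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"mode": "simulation" if config.simulate else "real", "stages": {}}

    # -- stage 0: obtain raw logs
    if config.simulate:
        schedule = simulate.generate_contact_schedule(config.ward)
        detections_raw, battery_raw = simulate.render_badge_logs(schedule, config.ward)
        roster = schedule.roster
        _write(detections_raw, out / "raw" / "detections.csv")
        _write(battery_raw, out / "raw" / "battery.csv")
        _write(schedule.contacts, out / "raw" / "ground_truth_contacts.csv")
        _write(roster, out / "raw" / "roster.csv")
        report["stages"]["simulate"] = {
            "ground_truth_contacts": int(len(schedule.contacts)),
            "worn_participant_days": int(len(schedule.wear)),
        }
    else:
        detections_raw, det_rejects = ingest.read_detection_log(config.detections_path)
        battery_raw, bat_rejects = ingest.read_battery_log(config.battery_path)
        roster = pd.read_csv(config.roster_path)
        _write(det_rejects, out / "ingest" / "detection_rejects.csv")
        _write(bat_rejects, out / "ingest" / "battery_rejects.csv")
        report["stages"]["read"] = {
            "detections": int(len(detections_raw)),
            "detection_rejects": int(len(det_rejects)),
            "battery": int(len(battery_raw)),
            "battery_rejects": int(len(bat_rejects)),
        }

    report["warnings"] = validate_inputs(detections_raw, battery_raw, roster)

    # -- stage 1: ingest / filter
    filtered, counts = ingest.filter_records(detections_raw, config.filter)
    _write(filtered, out / "ingest" / "detections_filtered.csv")
    report["stages"]["filter"] = {
        "input": int(len(detections_raw)),
        "kept": int(len(filtered)),
        "removed_duplicate": counts.duplicate,
        "removed_weekend": counts.weekend,
        "removed_out_of_hours": counts.out_of_hours,
        "removed_rssi": counts.rssi,
    }
    active = ingest.active_time_table(battery_raw, tz=config.filter.tz)
    _write(active, out / "ingest" / "active_time.csv")

    # -- stage 2: interactions
    events = interactions.reconstruct_interactions(
        filtered, config.reconstruction, tz=config.filter.tz
    )
    _write(events, out / "interactions" / "events.csv")
    summaries = interactions.daily_summary(events, active, roster)
    _write(summaries, out / "interactions" / "daily_summaries.csv")
    report["stages"]["interactions"] = {
        "events": int(len(events)),
        "participant_days": int(len(summaries)),
    }
    if events.empty:
        report["warnings"].append("no interaction events reconstructed")

    # -- stage 3: networks
    graphs = networks.daily_graphs_from_events(
        events, active, config.min_edge_minutes,
        omit_staff=config.omit_staff, roster=roster,
    )
    metrics = networks.metrics_table(graphs)
    _write(metrics, out / "networks" / "node_metrics.csv")
    edge_rows = [g.edge_table() for g in graphs if g.graph.number_of_edges()]
    edges = pd.concat(edge_rows, ignore_index=True) if edge_rows else pd.DataFrame(
        columns=["day", "a", "b", "minutes", "weight"]
    )
    _write(edges, out / "networks" / "edges.csv")
    report["stages"]["networks"] = {
        "days": len(graphs),
        "edges": int(len(edges)),
        "mean_edges_per_day": float(len(edges) / len(graphs)) if graphs else 0.0,
    }

    # -- stage 4: longitudinal
    daily = summaries.merge(metrics, on=["participant", "day"], how="left")
    _write(daily, out / "longitudinal" / "daily_metrics.csv")
    patients = roster.loc[roster["role"] == "patient", "participant"]
    daily_pat = daily[daily["participant"].isin(patients)]

    if config.simulate:
        assessment_dates = default_assessment_dates(config.ward, config.assessment.assessment_period)
        frame = pd.DataFrame(
            [(p, d) for p in patients for d in assessment_dates], columns=["participant", "date"]
        )
        features = window_features(daily_pat, frame, window_days=config.window_days)
        assessments = simulate.generate_assessments(features, config.assessment)
        _write(assessments, out / "longitudinal" / "assessments.csv")
    else:
        assessments = pd.read_csv(config.assessments_path)
        if "self_report_index" not in assessments.columns:
            assessments["self_report_index"] = ((8 - assessments["item1"]) + assessments["item2"]) / 2.0
        frame = assessments[["participant", "date"]]
        features = window_features(daily_pat, frame, window_days=config.window_days)
    _write(features, out / "longitudinal" / "windowed_features.csv")

    data = assemble_analysis_table(
        features[["participant", "date", "n_days_used", *[m for m in features.columns if m in
                  ("relative_interaction_time", "mean_log_duration", "eigenvector_centrality", "clustering")]]],
        assessments.drop(columns=[c for c in ("relative_interaction_time", "mean_log_duration",
                                              "eigenvector_centrality", "clustering")
                                  if c in assessments.columns and config.simulate]),
    )
    _write(data, out / "longitudinal" / "analysis_table.csv")

    if len(data) and data["participant"].nunique() >= 2:
        results, fits = run_model_suite(
            data, medication=config.medication, cooks_threshold=config.cooks_threshold
        )
        subscales = run_subscale_suite(data, config.cooks_threshold)
    else:
        results, fits = pd.DataFrame(), {}
        subscales = pd.DataFrame()
        report["warnings"].append("not enough assessment data to fit models")
    _write(results, out / "longitudinal" / "model_results.csv")
    _write(subscales, out / "longitudinal" / "model_results_subscales.csv")
    report["stages"]["models"] = {
        "fitted": int(len(fits)),
        "n_obs": int(len(data)),
        "n_participants": int(data["participant"].nunique()) if len(data) else 0,
    }

    if config.make_figures:
        try:
            figures(events, graphs, data, fits, out / "figures", tz=config.filter.tz)
            report["stages"]["figures"] = {"written": True}
        except Exception as err:  # figures are best-effort summaries
            report["warnings"].append(f"figure generation failed: {err}")

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def figures(events, graphs, data, fits, figdir: Path, tz: str = "UTC") -> None:
    """Descriptive summary plots for one run."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import networkx as nx

    figdir = Path(figdir)
    figdir.mkdir(parents=True, exist_ok=True)

    if len(events):
        start_local = pd.to_datetime(events["start"], unit="s", utc=True).dt.tz_convert(tz)
        hours = start_local.dt.hour + start_local.dt.minute / 60.0
        fig, ax = plt.subplots(figsize=(6, 3.5))
        ax.hist(hours, bins=np.arange(8, 20.25, 0.25), color="#33658a")
        ax.set_xlabel("interaction start time (h of day)")
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(figdir / "start_time_histogram.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(4.5, 3.5))
        d = events["duration_s"].to_numpy(float)
        bins = np.logspace(np.log10(max(d.min(), 1.0)), np.log10(d.max()), 30)
        ax.hist(d, bins=bins, color="#33658a")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("interaction duration (s)")
        ax.set_ylabel("count")
        fig.tight_layout()
        fig.savefig(figdir / "duration_histogram_loglog.png", dpi=120)
        plt.close(fig)

    snapshots = [g for g in graphs if g.graph.number_of_edges() > 0][:2]
    for g in snapshots:
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        pos = nx.spring_layout(g.graph, seed=3)
        widths = [2.5 * d["weight"] for _, _, d in g.graph.edges(data=True)]
        colors = ["#2f4858" if v.startswith("P") else "#f6ae2d" for v in g.graph.nodes]
        nx.draw_networkx(g.graph, pos, ax=ax, node_color=colors, width=widths,
                         node_size=220, font_size=6)
        ax.set_title(f"daily graph {g.day}")
        ax.axis("off")
        fig.tight_layout()
        fig.savefig(figdir / f"graph_{g.day}.png", dpi=120)
        plt.close(fig)

    for key, mf in fits.items():
        if mf.fit is None or mf.predictor not in data.columns or mf.outcome not in data.columns:
            continue
        sub = data[["participant", mf.outcome, mf.predictor]].dropna()
        xc = sub[mf.predictor] - sub.groupby("participant")[mf.predictor].transform("mean")
        fig, ax = plt.subplots(figsize=(4, 3.2))
        ax.scatter(xc, sub[mf.outcome], s=14, alpha=0.6, color="#33658a")
        xr = np.linspace(xc.min(), xc.max(), 20)
        ax.plot(xr, sub[mf.outcome].mean() + mf.beta1 * xr, color="black")
        ax.set_xlabel(f"{mf.predictor} (within-person centered)")
        ax.set_ylabel(mf.outcome)
        ax.set_title(f"model {key}: F={mf.F:.2f}, p={mf.p_value:.3f}", fontsize=9)
        fig.tight_layout()
        fig.savefig(figdir / f"model_{key}.png", dpi=120)
        plt.close(fig)
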